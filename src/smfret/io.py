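"""File formats: tabular traces, ground truth, TIFF movies, YAML configs.

The tabular trace format is the pipeline's interchange format: delimited
text, one row per (molecule, frame) with a mandatory header::

    molecule_id  frame  time_s  donor_counts  acceptor_counts  [ex488_counts]  [flags]

Ground truth is one record per molecule; configs are nested YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .traces import GroundTruth, IntensityTrace, MoleculeTruth

__all__ = [
    "traces_to_frame",
    "write_traces",
    "read_traces",
    "write_ground_truth",
    "read_ground_truth",
    "write_movie",
    "read_movie",
    "load_config",
    "save_config",
    "write_table",
]

_FLOAT_FMT = "%.6f"


def traces_to_frame(traces: list[IntensityTrace]) -> pd.DataFrame:
    rows = []
    for trace in traces:
        n = trace.n_frames
        data = {
            "molecule_id": np.full(n, trace.molecule_id),
            "frame": np.arange(n),
            "time_s": trace.times,
            "donor_counts": trace.donor,
            "acceptor_counts": trace.acceptor,
        }
        if trace.ex488 is not None:
            ex = np.full(n, np.nan)
            ex[: len(trace.ex488)] = trace.ex488
            data["ex488_counts"] = ex
        rows.append(pd.DataFrame(data))
    return pd.concat(rows, ignore_index=True)


def write_traces(traces: list[IntensityTrace], path) -> None:
    frame = traces_to_frame(traces)
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_traces(path, excitation_scheme: str = "single") -> list[IntensityTrace]:
    frame = pd.read_csv(path, sep="\t")
    required = {"molecule_id", "frame", "time_s", "donor_counts", "acceptor_counts"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"trace table missing columns: {sorted(missing)}")
    traces = []
    for mol_id, group in frame.groupby("molecule_id", sort=True):
        group = group.sort_values("frame")
        times = group["time_s"].to_numpy()
        frame_time = float(np.median(np.diff(times))) if len(times) > 1 else 1.0
        ex488 = None
        if "ex488_counts" in group:
            ex = group["ex488_counts"].to_numpy()
            if np.isfinite(ex).any():
                ex488 = ex[np.isfinite(ex)]
        traces.append(IntensityTrace(
            molecule_id=int(mol_id),
            frame_time=frame_time,
            donor=group["donor_counts"].to_numpy(),
            acceptor=group["acceptor_counts"].to_numpy(),
            ex488=ex488,
            excitation_scheme=excitation_scheme,
        ))
    return traces


def _opt(value):
    return -1 if value is None else int(value)


def write_ground_truth(truth: GroundTruth, path) -> None:
    """One record per molecule; the state path is run-length encoded."""
    rows = []
    for mol in truth.molecules:
        rows.append({
            "molecule_id": mol.molecule_id,
            "subpopulation": mol.subpopulation,
            "static": int(mol.static),
            "static_state": _opt(mol.static_state),
            "acceptor_bleach_frame": _opt(mol.acceptor_bleach_frame),
            "donor_bleach_frame": _opt(mol.donor_bleach_frame),
            "dissociation_frame": _opt(mol.dissociation_frame),
            "mot1_labeled": int(mol.mot1_labeled),
            "state_path_rle": _rle_encode(mol.state_path),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ground_truth(path) -> GroundTruth:
    frame = pd.read_csv(path, sep="\t")
    molecules = []
    for _, row in frame.iterrows():
        path_arr = _rle_decode(row["state_path_rle"])
        molecules.append(MoleculeTruth(
            molecule_id=int(row["molecule_id"]),
            state_path=path_arr,
            apparent_e=np.full(len(path_arr), np.nan),
            subpopulation=str(row["subpopulation"]),
            static=bool(row["static"]),
            static_state=None if row["static_state"] < 0 else int(row["static_state"]),
            acceptor_bleach_frame=(None if row["acceptor_bleach_frame"] < 0
                                   else int(row["acceptor_bleach_frame"])),
            donor_bleach_frame=(None if row["donor_bleach_frame"] < 0
                                else int(row["donor_bleach_frame"])),
            dissociation_frame=(None if row["dissociation_frame"] < 0
                                else int(row["dissociation_frame"])),
            mot1_labeled=bool(row["mot1_labeled"]),
        ))
    return GroundTruth(molecules=molecules)


def _rle_encode(path: np.ndarray) -> str:
    path = np.asarray(path)
    if len(path) == 0:
        return ""
    changes = np.flatnonzero(np.diff(path) != 0)
    bounds = np.concatenate([[0], changes + 1, [len(path)]])
    parts = [f"{path[bounds[i]]}x{bounds[i + 1] - bounds[i]}"
             for i in range(len(bounds) - 1)]
    return ";".join(parts)


def _rle_decode(encoded: str) -> np.ndarray:
    if not isinstance(encoded, str) or not encoded:
        return np.array([], dtype=np.int64)
    out = []
    for part in encoded.split(";"):
        state, count = part.split("x")
        out.extend([int(state)] * int(count))
    return np.array(out, dtype=np.int64)


def write_movie(stack: np.ndarray, path) -> None:
    """Multi-page TIFF, one page per frame, dual-view chip layout."""
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32),
                     photometric="minisblack")


def read_movie(path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg


def save_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def write_table(frame: pd.DataFrame, path, float_format: str = _FLOAT_FMT) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, float_format=float_format)


def write_json(obj: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
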