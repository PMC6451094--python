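"""In-memory containers for per-molecule time traces and ground truth."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IntensityTrace",
    "BleachAnnotation",
    "FretTrace",
    "MoleculeTruth",
    "GroundTruth",
]


@dataclass
class IntensityTrace:
    """Per-frame two-channel intensities of one molecule.

    ``donor`` and ``acceptor`` are counts recorded under donor (532 nm)
    excitation.  ``ex488`` holds the green-channel counts recorded in
    488 nm excitation frames for three-color measurements (empty for
    single-excitation traces).
    """

    molecule_id: int
    frame_time: float
    donor: np.ndarray
    acceptor: np.ndarray
    ex488: np.ndarray | None = None
    excitation_scheme: str = "single"

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.ex488 is not None:
            self.ex488 = np.asarray(self.ex488, dtype=float)
        if self.donor.shape != self.acceptor.shape:
            raise ValueError("donor and acceptor traces must have equal length")
        if not (np.isfinite(self.donor).all() and np.isfinite(self.acceptor).all()):
            raise ValueError("intensity traces must be finite")

    @property
    def n_frames(self) -> int:
        return len(self.donor)

    @property
    def total(self) -> np.ndarray:
        return self.donor + self.acceptor

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_time


@dataclass
class BleachAnnotation:
    """Detected photobleaching structure of a trace.

    ``order`` is ``"acceptor_first"`` when the acceptor bleaches while the
    donor still emits (the configuration that permits per-molecule
    correction-factor estimation), ``"donor_or_total"`` when the donor or
    the whole complex disappears first, or ``"none"``.
    """

    acceptor_frame: int | None = None
    donor_frame: int | None = None
    order: str = "none"

    @property
    def window_end(self) -> int | None:
        """Last frame (exclusive) usable for FRET, i.e. first bleach event."""
        candidates = [f for f in (self.acceptor_frame, self.donor_frame) if f is not None]
        return min(candidates) if candidates else None


@dataclass
class FretTrace:
    """Corrected FRET-efficiency time series of one molecule.

    ``efficiency`` is kept unclamped; ``window`` is the ``(first, last)``
    frame range (half-open) inside which FRET is meaningful, ending at the
    first bleach event or the end of the trace.
    """

    molecule_id: int
    frame_time: float
    efficiency: np.ndarray
    window: tuple = (0, 0)
    bleach: BleachAnnotation = field(default_factory=BleachAnnotation)
    mot1_present: bool | None = None
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.efficiency = np.asarray(self.efficiency, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.efficiency)
        first, last = self.window
        if not 0 <= first <= last <= len(self.efficiency):
            raise ValueError("analysis window out of bounds")

    @property
    def windowed(self) -> np.ndarray:
        """Finite efficiencies inside the analysis window."""
        first, last = self.window
        e = self.efficiency[first:last]
        return e[np.isfinite(e)]

    @property
    def n_usable(self) -> int:
        return len(self.windowed)


@dataclass
class MoleculeTruth:
    """Ground truth for a single simulated molecule."""

    molecule_id: int
    state_path: np.ndarray
    apparent_e: np.ndarray
    subpopulation: str
    static: bool
    static_state: int | None = None
    acceptor_bleach_frame: int | None = None
    donor_bleach_frame: int | None = None
    dissociation_frame: int | None = None
    mot1_labeled: bool = False
    position: tuple | None = None


@dataclass
class GroundTruth:
    """Ground truth for a simulated population."""

    molecules: list
    mixture: list = field(default_factory=list)
    rates: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.molecules)

    def __len__(self) -> int:
        return len(self.molecules)

    @property
    def static_fraction(self) -> float:
        flags = [m.static for m in self.molecules]
        return float(np.mean(flags)) if flags else float("nan")

    def label_counts(self) -> dict:
        counts: dict = {}
        for mol in self.molecules:
            counts[mol.subpopulation] = counts.get(mol.subpopulation, 0) + 1
        return counts
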