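"""Channel registration, spot detection and trace extraction.

The dual-view detection records both spectral channels side by side on one
camera chip.  A geometric transform between the channels is estimated from
bead images; single molecules are detected on a time-averaged image of the
donor channel; and per-frame intensities are extracted by aperture
photometry at the detected position and its mapped counterpart in the
acceptor channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.transform import (
    EuclideanTransform,
    estimate_transform,
)

from .config import ConfigurationError
from .traces import IntensityTrace

__all__ = [
    "ChannelMap",
    "Spot",
    "estimate_channel_map",
    "detect_spots",
    "extract_traces",
    "split_channels",
]

log = logging.getLogger(__name__)


@dataclass
class ChannelMap:
    """Geometric transform from channel-1 to channel-2 pixel coordinates."""

    transform_kind: str
    transform: object
    residual: float = 0.0

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        return self.transform(coords)

    @classmethod
    def identity(cls) -> "ChannelMap":
        return cls("translation", EuclideanTransform(translation=(0.0, 0.0)), 0.0)

    @classmethod
    def translation(cls, dx: float, dy: float) -> "ChannelMap":
        return cls("translation", EuclideanTransform(translation=(dx, dy)), 0.0)


_MIN_POINTS = {"translation": 1, "affine": 3, "polynomial": 6}


def estimate_channel_map(
    points1: np.ndarray,
    points2: np.ndarray,
    transform_kind: str = "affine",
) -> ChannelMap:
    """Least-squares transform mapping channel-1 control points onto channel-2.

    ``points1``/``points2`` are matched ``(n, 2)`` coordinate arrays, e.g.
    bead centroids localized in both channels.
    """
    points1 = np.atleast_2d(np.asarray(points1, dtype=float))
    points2 = np.atleast_2d(np.asarray(points2, dtype=float))
    if points1.shape != points2.shape:
        raise ConfigurationError("control point sets must have matching shapes")
    if transform_kind not in _MIN_POINTS:
        raise ConfigurationError(f"unknown transform kind {transform_kind!r}")
    n = len(points1)
    if n < _MIN_POINTS[transform_kind]:
        raise ConfigurationError(
            f"{transform_kind} estimation needs >= {_MIN_POINTS[transform_kind]} "
            f"bead pairs, got {n}"
        )
    if transform_kind == "translation":
        offset = (points2 - points1).mean(axis=0)
        tform = EuclideanTransform(translation=offset)
    elif transform_kind == "affine":
        if n >= 3 and _collinear(points1):
            raise ConfigurationError("bead layout is collinear; affine is degenerate")
        tform = estimate_transform("affine", points1, points2)
    else:
        tform = estimate_transform("polynomial", points1, points2, order=2)
    residual = float(np.sqrt(np.mean(np.sum((tform(points1) - points2) ** 2, axis=1))))
    return ChannelMap(transform_kind, tform, residual)


def _collinear(points: np.ndarray, tol: float = 1e-8) -> bool:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return bool(s[-1] < tol * max(s[0], 1.0))


@dataclass
class Spot:
    """A detected single-molecule candidate in the reference channel."""

    x: float
    y: float
    peak: float
    background: float = 0.0

    @property
    def position(self) -> tuple:
        return (self.x, self.y)


def detect_spots(
    image: np.ndarray,
    min_separation: float = 4.0,
    threshold: float | None = None,
    smooth_sigma: float = 1.0,
) -> list[Spot]:
    """Detect local maxima above threshold with non-maximum suppression.

    The image is Gaussian-smoothed, local maxima closer than
    ``min_separation`` are suppressed (the brighter one wins; overlapping
    pairs therefore yield at most one spot), and positions are refined to
    sub-pixel precision by an intensity-weighted centroid in a small
    window.  ``threshold`` defaults to median + 5 MAD-sigma of the
    smoothed image.
    """
    image = np.asarray(image, dtype=float)
    if not np.isfinite(image).all():
        raise ValueError("image must be finite")
    smoothed = ndimage.gaussian_filter(image, smooth_sigma)
    bg = float(np.median(smoothed))
    if threshold is None:
        mad = float(np.median(np.abs(smoothed - bg)))
        threshold = bg + 5 * 1.4826 * mad
    peaks = peak_local_max(
        smoothed,
        min_distance=max(int(round(min_separation)), 1),
        threshold_abs=threshold,
        exclude_border=2,
    )
    spots = []
    r = 2
    for row, col in peaks:
        y0, y1 = max(row - r, 0), min(row + r + 1, image.shape[0])
        x0, x1 = max(col - r, 0), min(col + r + 1, image.shape[1])
        window = image[y0:y1, x0:x1] - bg
        window = np.clip(window, 0, None)
        total = window.sum()
        if total <= 0:
            x, y = float(col), float(row)
        else:
            ys, xs = np.mgrid[y0:y1, x0:x1]
            x = float((xs * window).sum() / total)
            y = float((ys * window).sum() / total)
        spots.append(Spot(x=x, y=y, peak=float(smoothed[row, col]), background=bg))
    return spots


def detect_molecules(
    stack: np.ndarray,
    channel_map: ChannelMap,
    n_avg: int = 10,
    min_separation: float = 4.0,
    threshold: float | None = None,
    channel_width: int | None = None,
) -> list[Spot]:
    """Detect molecules on the time-averaged first frames of both channels.

    Detection runs independently in the donor and acceptor halves of the
    chip (a molecule in a high-FRET state is dim in the donor channel but
    bright in the acceptor channel); acceptor detections are mapped back
    to reference-channel coordinates and merged, suppressing duplicates
    closer than ``min_separation``.  Positions are reported in the
    reference (donor) channel.
    """
    donor_stack, acceptor_stack = split_channels(stack, channel_width)
    donor_avg = donor_stack[:n_avg].mean(axis=0)
    acceptor_avg = acceptor_stack[:n_avg].mean(axis=0)
    spots = detect_spots(donor_avg, min_separation, threshold)
    acc_spots = detect_spots(acceptor_avg, min_separation, threshold)
    if acc_spots:
        pos2 = np.array([s.position for s in acc_spots])
        pos1 = channel_map.transform.inverse(pos2)
        existing = (np.array([s.position for s in spots])
                    if spots else np.empty((0, 2)))
        for spot, (x, y) in zip(acc_spots, pos1):
            if existing.size and np.linalg.norm(
                    existing - [x, y], axis=1).min() < min_separation:
                continue
            spots.append(Spot(x=float(x), y=float(y), peak=spot.peak,
                              background=spot.background))
            existing = np.vstack([existing, [x, y]]) if existing.size \
                else np.array([[x, y]])
    return spots


def pair_spots(
    spots1: list[Spot],
    spots2: list[Spot],
    max_distance: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy nearest-neighbour pairing of spots across channels.

    Suitable for bead fields whose channel offset is small compared to the
    bead spacing; returns matched ``(n, 2)`` coordinate arrays.
    """
    p1 = np.array([s.position for s in spots1], dtype=float)
    p2 = np.array([s.position for s in spots2], dtype=float)
    if p1.size == 0 or p2.size == 0:
        return np.empty((0, 2)), np.empty((0, 2))
    used = np.zeros(len(p2), dtype=bool)
    out1, out2 = [], []
    for a in p1:
        d = np.linalg.norm(p2 - a, axis=1)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= max_distance:
            used[j] = True
            out1.append(a)
            out2.append(p2[j])
    return np.array(out1), np.array(out2)


def split_channels(stack: np.ndarray, channel_width: int | None = None):
    """Split a side-by-side dual-view stack into (donor, acceptor) halves."""
    if channel_width is None:
        channel_width = stack.shape[-1] // 2
    return stack[..., :channel_width], stack[..., channel_width:]


def _aperture_masks(shape: tuple, x: float, y: float, radius: float,
                    annulus: tuple) -> tuple:
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    r2 = (xs - x) ** 2 + (ys - y) ** 2
    inner = r2 <= radius**2
    ring = (r2 >= annulus[0] ** 2) & (r2 <= annulus[1] ** 2)
    return inner, ring


def extract_traces(
    stack: np.ndarray,
    spots: list[Spot],
    channel_map: ChannelMap,
    frame_time: float,
    aperture_radius: float = 3.0,
    annulus: tuple = (5.0, 7.0),
    excitation_scheme: str = "single",
    channel_width: int | None = None,
) -> list[IntensityTrace]:
    """Aperture photometry at each spot in both channels for every frame.

    Per frame and channel the trace value is the aperture sum minus the
    local background (annulus median times the aperture pixel count).
    Spots whose aperture (directly or after mapping) leaves the channel
    are dropped with a logged reason.  With the alternating excitation
    scheme, even frames are routed to the donor-excitation series and odd
    frames to the 488-excitation series.
    """
    donor_stack, acceptor_stack = split_channels(stack, channel_width)
    h, w = donor_stack.shape[1:]
    traces: list[IntensityTrace] = []
    pad = annulus[1]
    for i, spot in enumerate(spots):
        x1, y1 = spot.x, spot.y
        (x2, y2) = channel_map.apply([(x1, y1)])[0]
        if not (pad <= x1 < w - pad and pad <= y1 < h - pad):
            log.info("molecule %d dropped: aperture outside donor channel", i)
            continue
        if not (pad <= x2 < w - pad and pad <= y2 < h - pad):
            log.info("molecule %d dropped: mapped aperture outside acceptor channel", i)
            continue
        in1, ring1 = _aperture_masks((h, w), x1, y1, aperture_radius, annulus)
        in2, ring2 = _aperture_masks((h, w), x2, y2, aperture_radius, annulus)
        donor = (
            donor_stack[:, in1].sum(axis=1)
            - np.median(donor_stack[:, ring1], axis=1) * in1.sum()
        )
        acceptor = (
            acceptor_stack[:, in2].sum(axis=1)
            - np.median(acceptor_stack[:, ring2], axis=1) * in2.sum()
        )
        ex488 = None
        if excitation_scheme == "alternating_488_532":
            ex488 = donor[1::2]
            donor = donor[0::2]
            acceptor = acceptor[0::2]
            n = min(len(donor), len(ex488))
            donor, acceptor, ex488 = donor[:n], acceptor[:n], ex488[:n]
            frame_time_out = 2 * frame_time
        else:
            frame_time_out = frame_time
        traces.append(
            IntensityTrace(
                molecule_id=i,
                frame_time=frame_time_out,
                donor=donor,
                acceptor=acceptor,
                ex488=ex488,
                excitation_scheme=excitation_scheme,
            )
        )
    return traces
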