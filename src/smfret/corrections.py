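"""Photobleaching-step detection, crosstalk/γ estimation and FRET calculation.

Acceptor-first photobleaching is the anchor of the per-molecule correction
scheme: when the acceptor dye bleaches while the donor still emits, the
acceptor channel drops to background in a single step and the donor rises
to the full photon budget.  The residual acceptor-channel signal after the
step measures spectral crosstalk ``alpha``, and the ratio of the acceptor
drop to the donor rise measures the relative detection efficiency
``gamma``.  Corrected FRET efficiency is then::

    E = (I_A - alpha * I_D - bg_A) / ((I_A - alpha * I_D - bg_A) + gamma * (I_D - bg_D))
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .traces import BleachAnnotation, FretTrace, IntensityTrace

__all__ = [
    "CorrectionFactors",
    "CorrectionUnavailable",
    "detect_bleach_steps",
    "estimate_crosstalk",
    "estimate_gamma",
    "compute_fret",
    "correct_direct_excitation",
    "call_mot1_presence",
    "estimate_population_factors",
]


class CorrectionUnavailable(RuntimeError):
    """No qualifying acceptor-first bleach window; fall back to population/config."""


@dataclass
class CorrectionFactors:
    """Crosstalk/detection-efficiency corrections applied to one molecule."""

    alpha: float
    gamma: float
    direct_excitation_fraction: float = 0.0
    source: str = "config"  # per_molecule | population_median | config

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must lie in [0, 1)")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if not 0.0 <= self.direct_excitation_fraction < 1.0:
            raise ValueError("direct_excitation_fraction must lie in [0, 1)")


def _noise_sd(x: np.ndarray) -> float:
    """Robust per-frame noise SD from first differences."""
    d = np.diff(x)
    return max(float(np.median(np.abs(d)) * 1.4826 / np.sqrt(2)), 1e-12)


def _changepoint_drop(x: np.ndarray) -> tuple[int, float, float]:
    """Best single downward mean-shift: (frame, drop, z).

    Least-squares change point on the full segments; ``z`` is the CUSUM
    statistic in units of the per-frame noise SD.
    """
    n = len(x)
    c = np.concatenate([[0.0], np.cumsum(x)])
    t = np.arange(2, n - 1)
    m1 = c[t] / t
    m2 = (c[n] - c[t]) / (n - t)
    stat = (m1 - m2) * np.sqrt(t * (n - t) / n)
    i = int(np.argmax(stat))
    z = float(stat[i] / _noise_sd(x))
    return int(t[i]), float(m1[i] - m2[i]), z


def _stays_low(x: np.ndarray, frame: int, window: int) -> bool:
    """Post-step signal never recovers above the pre/post midpoint."""
    pre = x[:frame].mean()
    post_seg = x[frame:]
    post = post_seg.mean()
    if len(post_seg) < window:
        return True
    kernel = np.ones(window) / window
    rolling = np.convolve(post_seg, kernel, mode="valid")
    midpoint = post + 0.5 * (pre - post)
    return bool(rolling.max() < midpoint)


def detect_bleach_steps(
    trace: IntensityTrace,
    window: int = 5,
    threshold_sd: float = 5.0,
    background: tuple = (0.0, 0.0),
    max_post_ratio: float = 0.15,
) -> BleachAnnotation:
    """Locate single-step bleach events by two-segment change-point search.

    A candidate acceptor bleach must drop significantly (CUSUM statistic
    above ``threshold_sd`` noise SDs), stay at the low level for the rest
    of the trace, and leave a post-step proximity ratio below
    ``max_post_ratio`` — the crosstalk-level signature that separates a
    real acceptor bleach from a transition into a low-FRET state.  A
    concurrent two-channel drop is classified as donor/total loss instead.
    """
    if trace.n_frames < 10:
        raise ValueError("bleach detection needs at least 10 frames")
    w = min(window, max(trace.n_frames // 4, 2))
    donor, acceptor = trace.donor, trace.acceptor
    bg_d, bg_a = background

    ta, drop_a, z_a = _changepoint_drop(acceptor)
    td, drop_d, z_d = _changepoint_drop(donor)

    ann = BleachAnnotation()
    acc_ok = z_a > threshold_sd and drop_a > 0 and _stays_low(acceptor, ta, w)
    don_ok = z_d > threshold_sd and drop_d > 0 and _stays_low(donor, td, w)
    if acc_ok:
        a_post = acceptor[ta:].mean() - bg_a
        d_post = donor[ta:].mean() - bg_d
        ratio = a_post / (a_post + d_post) if (a_post + d_post) > 0 else 1.0
        if don_ok and abs(td - ta) <= 2:
            ann.donor_frame = td
            ann.order = "donor_or_total"
            return ann
        if ratio < max_post_ratio:
            d_pre = donor[:ta].mean()
            if donor[ta:].mean() > d_pre:
                ann.acceptor_frame = ta
                ann.order = "acceptor_first"
                # subsequent donor loss inside the donor-only tail
                tail = donor[ta + 2:]
                if len(tail) > 10:
                    t2, drop2, z2 = _changepoint_drop(tail)
                    if z2 > threshold_sd and drop2 > 0 and _stays_low(tail, t2, w):
                        ann.donor_frame = ta + 2 + t2
                return ann
    if don_ok:
        ann.donor_frame = td
        ann.order = "donor_or_total"
    return ann


def _acceptor_first_windows(
    trace: IntensityTrace,
    bleach: BleachAnnotation,
    min_frames: int = 5,
    guard: int = 2,
) -> tuple[slice, slice]:
    """(pre, post) frame windows around an acceptor-first bleach step."""
    if bleach.order != "acceptor_first" or bleach.acceptor_frame is None:
        raise CorrectionUnavailable("no acceptor-first bleach event")
    fa = bleach.acceptor_frame
    end = bleach.donor_frame if bleach.donor_frame is not None else trace.n_frames
    pre = slice(max(fa - guard - min_frames, 0), max(fa - guard, 0))
    post = slice(fa + guard, end - guard if end < trace.n_frames else end)
    if (pre.stop - pre.start) < min_frames or (post.stop - post.start) < min_frames:
        raise CorrectionUnavailable("too few frames around the bleach step")
    return pre, post


def estimate_crosstalk(
    trace: IntensityTrace,
    bleach: BleachAnnotation,
    background: tuple = (0.0, 0.0),
    min_frames: int = 5,
) -> float:
    """Crosstalk ``alpha`` from the post-acceptor-bleach window.

    After the acceptor is dark, any background-corrected acceptor-channel
    signal is donor leakage; its ratio to the donor signal is ``alpha``.
    """
    _pre, post = _acceptor_first_windows(trace, bleach, min_frames)
    bg_d, bg_a = background
    donor = float(np.mean(trace.donor[post])) - bg_d
    acceptor = float(np.mean(trace.acceptor[post])) - bg_a
    if donor <= 0:
        raise CorrectionUnavailable("no donor signal after acceptor bleach")
    return max(acceptor / donor, 0.0)


def estimate_gamma(
    trace: IntensityTrace,
    bleach: BleachAnnotation,
    alpha: float = 0.0,
    background: tuple = (0.0, 0.0),
    min_frames: int = 5,
) -> float:
    """Detection-efficiency ratio ``gamma`` from the bleach-step amplitudes.

    ``gamma`` is the crosstalk- and background-corrected acceptor drop
    divided by the donor rise across the acceptor bleach step.
    """
    pre, post = _acceptor_first_windows(trace, bleach, min_frames)
    bg_d, bg_a = background
    d_pre = float(np.mean(trace.donor[pre])) - bg_d
    d_post = float(np.mean(trace.donor[post])) - bg_d
    a_pre = float(np.mean(trace.acceptor[pre])) - bg_a - alpha * d_pre
    a_post = float(np.mean(trace.acceptor[post])) - bg_a - alpha * d_post
    rise = d_post - d_pre
    if rise <= 0:
        raise CorrectionUnavailable("donor does not rise across the step")
    drop = a_pre - a_post
    if drop <= 0:
        raise CorrectionUnavailable("acceptor does not drop across the step")
    return drop / rise


def compute_fret(
    trace: IntensityTrace,
    factors: CorrectionFactors,
    background: tuple = (0.0, 0.0),
    bleach: BleachAnnotation | None = None,
    mot1_present: bool | None = None,
) -> FretTrace:
    """Corrected per-frame FRET efficiency, truncated at the first bleach.

    Frames with a vanishing denominator are flagged invalid rather than
    producing infinities; efficiencies are left unclamped so fits see the
    true shot-noise wings.
    """
    if bleach is None:
        bleach = BleachAnnotation()
    bg_d, bg_a = background
    acceptor = trace.acceptor - factors.alpha * (trace.donor - bg_d) - bg_a
    donor = factors.gamma * (trace.donor - bg_d)
    denom = acceptor + donor
    valid = np.abs(denom) > 1e-9
    eff = np.full(trace.n_frames, np.nan)
    eff[valid] = acceptor[valid] / denom[valid]
    end = bleach.window_end
    window = (0, end if end is not None else trace.n_frames)
    return FretTrace(
        molecule_id=trace.molecule_id,
        frame_time=trace.frame_time,
        efficiency=eff,
        window=window,
        bleach=bleach,
        mot1_present=mot1_present,
        valid=valid,
    )


def correct_direct_excitation(
    trace: IntensityTrace,
    fraction: float,
) -> np.ndarray:
    """Remove donor direct excitation from the 488-excitation green series.

    Subtracts ``fraction`` of the temporally adjacent donor-excitation
    green signal from each 488-excitation frame.
    """
    if trace.ex488 is None:
        raise ValueError("trace has no 488-excitation series")
    return trace.ex488 - fraction * trace.donor[: len(trace.ex488)]


def call_mot1_presence(
    series: np.ndarray,
    threshold: float | None = None,
    background_mean: float = 0.0,
    background_sd: float | None = None,
    min_run: int = 3,
) -> bool:
    """Presence call for a 488-excited cofactor label.

    True iff the corrected 488-excitation signal stays above threshold
    (default: background mean + 3 SD) for at least ``min_run`` consecutive
    frames, which rejects single-frame spikes.
    """
    series = np.asarray(series, dtype=float)
    if threshold is None:
        if background_sd is None:
            raise ValueError("either threshold or background_sd is required")
        threshold = background_mean + 3.0 * background_sd
    above = series > threshold
    run = 0
    for flag in above:
        run = run + 1 if flag else 0
        if run >= min_run:
            return True
    return False


def estimate_population_factors(
    traces: list[IntensityTrace],
    bleaches: list[BleachAnnotation],
    background: tuple = (0.0, 0.0),
    default_alpha: float = 0.05,
    default_gamma: float = 1.0,
    min_per_molecule: int = 5,
) -> list[CorrectionFactors]:
    """Per-molecule corrections with the population-median/config fallback.

    Molecules with a usable acceptor-first bleach get their own estimates;
    the remainder inherit the population medians, or the config defaults
    when no molecule in the run qualifies.  The provenance of each
    molecule's factors is recorded in ``source``.
    """
    per_alpha: dict[int, float] = {}
    per_gamma: dict[int, float] = {}
    for i, (trace, bleach) in enumerate(zip(traces, bleaches)):
        try:
            alpha_i = estimate_crosstalk(trace, bleach, background, min_per_molecule)
            gamma_i = estimate_gamma(trace, bleach, alpha_i, background,
                                     min_per_molecule)
        except CorrectionUnavailable:
            continue
        per_alpha[i] = alpha_i
        per_gamma[i] = gamma_i
    med_alpha = float(np.median(list(per_alpha.values()))) if per_alpha else None
    med_gamma = float(np.median(list(per_gamma.values()))) if per_gamma else None

    factors = []
    for i in range(len(traces)):
        if i in per_alpha:
            factors.append(CorrectionFactors(per_alpha[i], per_gamma[i],
                                             source="per_molecule"))
        elif med_alpha is not None:
            factors.append(CorrectionFactors(med_alpha, med_gamma,
                                             source="population_median"))
        else:
            factors.append(CorrectionFactors(default_alpha, default_gamma,
                                             source="config"))
    return factors
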