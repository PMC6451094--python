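"""FRET-efficiency histograms and constrained Gaussian-mixture fits.

Histograms are built molecule-wise (one mean efficiency per molecule) or
frame-wise (one entry per usable frame) and fitted by nonlinear least
squares with sums of Gaussians — the same histogram-domain fitting used for
the published population tables — including a global amplitude-only mode in
which peak positions and widths are shared across conditions and only the
amplitudes (and, optionally, a small bounded peak shift) vary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import find_peaks

from .traces import FretTrace

__all__ = [
    "FretHistogram",
    "GaussianComponent",
    "MixtureFit",
    "DegenerateMixtureWarning",
    "build_histogram",
    "histogram_from_values",
    "fit_mixture",
    "global_amplitude_fit",
    "goodness_of_fit",
    "merged_area",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)


class DegenerateMixtureWarning(UserWarning):
    """Two fitted components are closer than one width apart."""


@dataclass
class FretHistogram:
    """Binned FRET-efficiency distribution."""

    mode: str  # molecule_wise | frame_wise
    edges: np.ndarray
    counts: np.ndarray
    n_molecules: int = 0
    normalized: bool = False

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.counts) != len(self.edges) - 1:
            raise ValueError("counts must have one entry per bin")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    def normalize(self) -> "FretHistogram":
        total = self.counts.sum()
        if total <= 0:
            raise ValueError("cannot normalize an empty histogram")
        return FretHistogram(self.mode, self.edges, self.counts / total,
                             self.n_molecules, normalized=True)


@dataclass
class GaussianComponent:
    """One mixture component; area in % of total, mean/width in FRET units."""

    area: float
    mean: float
    sigma: float
    constraint: str = "free"  # free | fixed | bounded_shift

    def pdf(self, x: np.ndarray) -> np.ndarray:
        return np.exp(-0.5 * ((x - self.mean) / self.sigma) ** 2)


@dataclass
class MixtureFit:
    """Result of a Gaussian-mixture histogram fit."""

    components: list
    r_squared: float
    residuals: np.ndarray
    fit_mode: str = "free"  # free | global_amplitude_only
    converged: bool = True
    messages: list = field(default_factory=list)

    @property
    def means(self) -> np.ndarray:
        return np.array([c.mean for c in self.components])

    @property
    def areas(self) -> np.ndarray:
        return np.array([c.area for c in self.components])

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        return _model(x, self._amplitudes, self.means,
                      np.array([c.sigma for c in self.components]))

    def as_table(self) -> pd.DataFrame:
        """Fit report in the published layout: A in %, mu and sigma in FRET %."""
        return pd.DataFrame(
            {
                "A_pct": [round(c.area, 1) for c in self.components],
                "mu_pct": [round(100 * c.mean, 1) for c in self.components],
                "sigma_pct": [round(100 * c.sigma, 1) for c in self.components],
            },
            index=[f"S{i + 1}" for i in range(len(self.components))],
        )


def build_histogram(
    fret_traces: list[FretTrace],
    mode: str = "molecule_wise",
    bin_width: float = 0.02,
    hist_range: tuple = (-0.1, 1.1),
    dynamic_flags: list | None = None,
    include_dynamic: bool = False,
) -> FretHistogram:
    """Histogram corrected FRET traces molecule-wise or frame-wise.

    Molecule-wise, each molecule contributes its mean efficiency over the
    analysis window; dynamic molecules are excluded by default (their mean
    mixes states).  Frame-wise, every usable frame contributes.
    """
    if not fret_traces:
        raise ValueError("no traces to histogram")
    if dynamic_flags is None:
        dynamic_flags = [False] * len(fret_traces)
    values: list[float] = []
    n_molecules = 0
    for trace, dynamic in zip(fret_traces, dynamic_flags):
        if mode == "molecule_wise" and dynamic and not include_dynamic:
            continue
        windowed = trace.windowed
        if len(windowed) == 0:
            continue
        n_molecules += 1
        if mode == "molecule_wise":
            values.append(float(windowed.mean()))
        elif mode == "frame_wise":
            values.extend(windowed.tolist())
        else:
            raise ValueError(f"unknown histogram mode {mode!r}")
    hist = histogram_from_values(np.array(values), mode, bin_width, hist_range)
    hist.n_molecules = n_molecules
    return hist


def histogram_from_values(
    values: np.ndarray,
    mode: str = "molecule_wise",
    bin_width: float = 0.02,
    hist_range: tuple = (-0.1, 1.1),
) -> FretHistogram:
    values = np.asarray(values, dtype=float)
    lo, hi = hist_range
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    return FretHistogram(mode, edges, counts.astype(float),
                         n_molecules=len(values))


def _model(x: np.ndarray, amps: np.ndarray, means: np.ndarray,
           sigmas: np.ndarray) -> np.ndarray:
    return np.sum(
        amps[:, None] * np.exp(-0.5 * ((x[None, :] - means[:, None])
                                       / sigmas[:, None]) ** 2),
        axis=0,
    )


def _areas_pct(amps: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    raw = amps * sigmas * _SQRT2PI
    total = raw.sum()
    return 100.0 * raw / total if total > 0 else raw


def _initial_guesses(hist: FretHistogram, n_components: int) -> list[np.ndarray]:
    """Candidate mean vectors for the multistart fit.

    All ``n_components``-subsets of a small candidate pool (histogram
    peaks, distribution quantiles, an even spread over the occupied
    support) are tried; overlapping mixtures have rugged least-squares
    landscapes and a single data-driven start is not reliable.
    """
    x, y = hist.centers, hist.counts
    total = y.sum()
    if total <= 0:
        return [np.linspace(0.2, 0.8, n_components)]
    pool: list[float] = []
    cdf = np.cumsum(y) / total
    pool.extend(np.interp((np.arange(n_components) + 0.5) / n_components, cdf, x))
    pool.extend(np.interp([0.1, 0.5, 0.9], cdf, x))
    peaks, props = find_peaks(y, prominence=0.02 * y.max())
    if len(peaks) > 0:
        order = np.argsort(props["prominences"])[::-1]
        pool.extend(x[peaks[order[:4]]])
    occ = x[y > 0]
    pool.extend(np.linspace(occ[0], occ[-1], n_components + 2)[1:-1])
    # dedup within 0.02 FRET
    uniq: list[float] = []
    for v in sorted(pool):
        if not uniq or v - uniq[-1] > 0.02:
            uniq.append(float(v))
    if len(uniq) < n_components:
        return [np.linspace(occ[0], occ[-1], n_components)]
    from itertools import combinations

    guesses = [np.array(c) for c in combinations(uniq, n_components)]
    return guesses[:120]


def fit_mixture(
    hist: FretHistogram,
    n_components: int,
    init_means: np.ndarray | None = None,
    init_sigma: float = 0.06,
    sigma_bounds: tuple = (0.01, 0.3),
) -> MixtureFit:
    """Free least-squares Gaussian-mixture fit of a histogram.

    The fit minimizes Poisson-weighted residuals (weights
    ``1/sqrt(max(count, 1))``) over a multistart library of
    initializations (supplied means, histogram peaks, quantiles and their
    combinations), keeping the lowest-cost solution.  Components are
    returned sorted by mean with areas in percent of the total fitted
    area.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    occupied = int((hist.counts > 0).sum())
    if occupied <= 3 * n_components:
        raise ValueError(
            f"only {occupied} occupied bins for {3 * n_components} free parameters"
        )
    x, y = hist.centers, hist.counts
    scale = max(y.max(), 1e-12)
    weights = 1.0 / np.sqrt(np.maximum(y, 1.0))

    candidates = ([np.asarray(init_means, dtype=float)] if init_means is not None
                  else []) + _initial_guesses(hist, n_components)

    lower = np.concatenate([
        np.zeros(n_components),
        np.full(n_components, x[0]),
        np.full(n_components, sigma_bounds[0]),
    ])
    upper = np.concatenate([
        np.full(n_components, 5.0 * scale),
        np.full(n_components, x[-1]),
        np.full(n_components, sigma_bounds[1]),
    ])

    def resid(p):
        a, m, s = np.split(p, 3)
        return weights * (_model(x, a, m, s) - y)

    best = None
    for means0 in candidates:
        if len(means0) != n_components:
            continue
        amps0 = np.interp(means0, x, y).clip(0.05 * scale, None)
        p0 = np.concatenate([amps0, means0, np.full(n_components, init_sigma)])
        sol = least_squares(resid, p0, bounds=(lower, upper))
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise RuntimeError("mixture fit failed to converge: "
                           + (best.message if best is not None else "no start"))

    amps, means, sigmas = np.split(best.x, 3)
    order = np.argsort(means)
    amps, means, sigmas = amps[order], means[order], sigmas[order]
    areas = _areas_pct(amps, sigmas)
    components = [GaussianComponent(a, m, s) for a, m, s in zip(areas, means, sigmas)]
    fit = MixtureFit(components, 0.0, best.fun, fit_mode="free")
    fit._amplitudes = amps
    fit.r_squared = goodness_of_fit(fit, hist)
    _warn_if_degenerate(components)
    return fit


def _warn_if_degenerate(components: list) -> None:
    for i in range(len(components)):
        for j in range(i + 1, len(components)):
            ci, cj = components[i], components[j]
            if abs(ci.mean - cj.mean) < max(ci.sigma, cj.sigma):
                warnings.warn(
                    f"components at E={ci.mean:.3f} and E={cj.mean:.3f} are closer "
                    "than one width; the decomposition is poorly identified",
                    DegenerateMixtureWarning,
                    stacklevel=3,
                )


def global_amplitude_fit(
    hists: list[FretHistogram],
    fixed_components: list[tuple[float, float]],
    max_shift: float = 0.01,
) -> list[MixtureFit]:
    """Joint amplitude-only fit of several histograms to one state set.

    ``fixed_components`` are shared ``(mean, sigma)`` pairs.  Widths are
    fixed and the state set is common, but each histogram's peaks may
    shift by at most ``max_shift`` (FRET units) — the small allowance for
    condition-to-condition background-correction differences; amplitudes
    are free per histogram.
    """
    means0 = np.array([m for m, _ in fixed_components])
    sigmas = np.array([s for _, s in fixed_components])
    k = len(fixed_components)
    n_hist = len(hists)
    xs = [h.centers for h in hists]
    ys = [h.counts for h in hists]
    scales = [max(y.max(), 1e-12) for y in ys]
    shift_bound = max(max_shift, 1e-12)

    # parameters per histogram: k mean shifts then k amplitudes
    p0 = np.concatenate([np.concatenate([np.zeros(k), np.full(k, 0.25 * s)])
                         for s in scales])
    lower = np.concatenate([np.concatenate([np.full(k, -shift_bound),
                                            np.zeros(k)])
                            for _ in range(n_hist)])
    upper = np.concatenate([np.concatenate([np.full(k, shift_bound),
                                            np.full(k, 5.0 * s)])
                            for s in scales])

    def _unpack(p, h):
        block = p[2 * k * h: 2 * k * (h + 1)]
        return means0 + block[:k], block[k:]

    def resid(p):
        out = []
        for h in range(n_hist):
            means, amps = _unpack(p, h)
            out.append(_model(xs[h], amps, means, sigmas) - ys[h])
        return np.concatenate(out)

    sol = least_squares(resid, p0, bounds=(lower, upper))
    if not sol.success:
        raise RuntimeError(f"global amplitude fit failed: {sol.message}")
    fits = []
    for h in range(n_hist):
        means, amps = _unpack(sol.x, h)
        areas = _areas_pct(amps, sigmas)
        comps = [GaussianComponent(a, m, s, constraint="bounded_shift")
                 for a, m, s in zip(areas, means, sigmas)]
        fit = MixtureFit(comps, 0.0, _model(xs[h], amps, means, sigmas) - ys[h],
                         fit_mode="global_amplitude_only")
        fit._amplitudes = amps
        fit.r_squared = goodness_of_fit(fit, hists[h])
        fits.append(fit)
    return fits


def goodness_of_fit(fit: MixtureFit, hist: FretHistogram) -> float:
    """Coefficient of determination of the fit on the histogram's bins."""
    y = hist.counts
    if np.allclose(y, y.mean()):
        raise ValueError("zero-variance histogram has no defined R^2")
    model = fit.evaluate(hist.centers)
    ss_res = float(np.sum((y - model) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


def merged_area(fit: MixtureFit, indices: tuple) -> float:
    """Combined area (%) of several components reported as one population.

    Used for the convention of reporting a main peak and its unresolved
    shoulder as a single low-FRET population.
    """
    return float(sum(fit.components[i].area for i in indices))
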