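"""Transition density plots, subpopulation assignment and dwell-time kinetics.

Every decoded transition contributes a fixed-width 2D Gaussian at its
(initial E, final E) coordinate to the transition density plot (TDP).
Clusters in the TDP are gated — either from explicit rectangles or
k-means-seeded ones — and each molecule is assigned to the subpopulation
whose gate set captures the plurality of its transitions.  Dwell times per
(subpopulation, state) follow exponential statistics whose mono-exponential
histogram fit yields the state exit rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from sklearn.cluster import KMeans

__all__ = [
    "TransitionDensityPlot",
    "Gate",
    "build_tdp",
    "auto_gates",
    "gates_from_state_means",
    "SubpopulationAssignment",
    "assign_subpopulations",
    "Dwell",
    "DwellTimeSet",
    "extract_dwells",
    "fit_dwell_rate",
]


@dataclass
class TransitionDensityPlot:
    """2D density of (initial E, final E) transition coordinates."""

    grid: np.ndarray  # (n, n) density
    axis: np.ndarray  # shared initial/final E axis
    kernel_width: float
    n_transitions: int

    @property
    def cell_area(self) -> float:
        step = float(self.axis[1] - self.axis[0])
        return step * step

    @property
    def total_mass(self) -> float:
        return float(self.grid.sum() * self.cell_area)

    def density_in(self, gate: "Gate") -> float:
        """Maximum density value inside a rectangular gate."""
        ix = (self.axis >= gate.from_range[0]) & (self.axis <= gate.from_range[1])
        iy = (self.axis >= gate.to_range[0]) & (self.axis <= gate.to_range[1])
        sub = self.grid[np.ix_(iy, ix)]
        return float(sub.max()) if sub.size else 0.0


def build_tdp(
    transitions: np.ndarray,
    kernel_width: float = 0.03,
    grid_size: int = 101,
    e_range: tuple = (0.0, 1.0),
) -> TransitionDensityPlot:
    """Superimpose unit-mass 2D Gaussians for each transition.

    ``transitions`` is an ``(n, 2)`` array of (from-E, to-E) pairs.  Each
    kernel is normalized on the discrete grid, so the grid integral equals
    the transition count exactly even for kernels truncated at the border.
    """
    transitions = np.atleast_2d(np.asarray(transitions, dtype=float))
    if transitions.size == 0:
        raise ValueError("empty transition set")
    axis = np.linspace(e_range[0], e_range[1], grid_size)
    cell = (axis[1] - axis[0]) ** 2
    grid = np.zeros((grid_size, grid_size))
    for from_e, to_e in transitions:
        gx = np.exp(-0.5 * ((axis - from_e) / kernel_width) ** 2)
        gy = np.exp(-0.5 * ((axis - to_e) / kernel_width) ** 2)
        kernel = np.outer(gy, gx)
        mass = kernel.sum() * cell
        if mass > 0:
            grid += kernel / mass
    return TransitionDensityPlot(grid=grid, axis=axis,
                                 kernel_width=kernel_width,
                                 n_transitions=len(transitions))


@dataclass
class Gate:
    """Rectangular (from-E, to-E) selection region."""

    from_range: tuple
    to_range: tuple

    def contains(self, from_e: float, to_e: float) -> bool:
        return (self.from_range[0] <= from_e <= self.from_range[1]
                and self.to_range[0] <= to_e <= self.to_range[1])

    def overlaps(self, other: "Gate") -> bool:
        def _ov(a, b):
            return a[0] < b[1] and b[0] < a[1]
        return _ov(self.from_range, other.from_range) and _ov(self.to_range,
                                                              other.to_range)


def auto_gates(
    transitions: np.ndarray,
    n_clusters: int,
    half_width: float = 0.05,
    seed: int = 0,
) -> list[Gate]:
    """Seed rectangular gates from k-means clusters of transition coordinates."""
    transitions = np.atleast_2d(np.asarray(transitions, dtype=float))
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    km.fit(transitions)
    gates = []
    for cx, cy in km.cluster_centers_:
        gates.append(Gate((cx - half_width, cx + half_width),
                          (cy - half_width, cy + half_width)))
    return gates


def gates_from_state_means(
    state_means: tuple,
    half_width: float = 0.05,
    linear_chain: bool = True,
) -> list[Gate]:
    """Gates at every allowed ordered state pair of one subpopulation.

    With ``linear_chain`` only nearest-neighbour transitions get gates
    (the connectivity in which the outer states exchange only via the
    intermediate one).
    """
    means = sorted(state_means)
    gates = []
    n = len(means)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if linear_chain and abs(i - j) > 1:
                continue
            gates.append(Gate((means[i] - half_width, means[i] + half_width),
                              (means[j] - half_width, means[j] + half_width)))
    return gates


@dataclass
class SubpopulationAssignment:
    """Mapping of molecules to TDP-gated subpopulations."""

    labels: dict  # molecule_id -> subpopulation label or "unassigned"
    gates: dict  # label -> list[Gate]
    capture_counts: dict  # molecule_id -> {label: captured transitions}

    def counts(self) -> dict:
        out: dict = {}
        for label in self.labels.values():
            out[label] = out.get(label, 0) + 1
        return out

    def fraction(self, label: str, of: tuple | None = None) -> float:
        """Fraction of molecules with ``label`` among those labeled in ``of``."""
        counts = self.counts()
        if of is None:
            total = sum(counts.values())
        else:
            total = sum(counts.get(l, 0) for l in of)
        return counts.get(label, 0) / total if total else float("nan")


def assign_subpopulations(
    molecule_transitions: dict,
    gates: dict,
) -> SubpopulationAssignment:
    """Assign each molecule to the subpopulation capturing most transitions.

    ``molecule_transitions`` maps molecule id to an ``(n, 2)`` array of
    (from-E, to-E) pairs; ``gates`` maps subpopulation label to its gate
    list.  Gate sets of different subpopulations must not overlap.  A
    molecule with no captured transitions, or with a tie between labels,
    is ``"unassigned"``; assignments are per-run constants — a molecule
    never carries more than one label.
    """
    labels = list(gates)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            for ga in gates[a]:
                for gb in gates[b]:
                    if ga.overlaps(gb):
                        raise ValueError(
                            f"gates of subpopulations {a!r} and {b!r} overlap"
                        )
    assignment: dict = {}
    capture: dict = {}
    for mol_id, transitions in molecule_transitions.items():
        transitions = np.atleast_2d(np.asarray(transitions, dtype=float))
        counts = {label: 0 for label in labels}
        if transitions.size:
            for from_e, to_e in transitions:
                for label in labels:
                    if any(g.contains(from_e, to_e) for g in gates[label]):
                        counts[label] += 1
                        break
        capture[mol_id] = counts
        best = max(counts.values())
        if best == 0 or sum(c == best for c in counts.values()) > 1:
            assignment[mol_id] = "unassigned"
        else:
            assignment[mol_id] = max(counts, key=counts.get)
    return SubpopulationAssignment(labels=assignment, gates=gates,
                                   capture_counts=capture)


@dataclass
class Dwell:
    """One dwell: duration in seconds, with censoring for edge dwells."""

    duration: float
    censored: bool
    state: int
    molecule_id: int
    subpopulation: str = ""


@dataclass
class DwellTimeSet:
    """Dwell durations grouped by (subpopulation, state)."""

    dwells: list = field(default_factory=list)

    def select(self, subpopulation: str | None = None,
               state: int | None = None, uncensored_only: bool = False):
        out = []
        for d in self.dwells:
            if subpopulation is not None and d.subpopulation != subpopulation:
                continue
            if state is not None and d.state != state:
                continue
            if uncensored_only and d.censored:
                continue
            out.append(d)
        return out

    def durations(self, **kwargs) -> np.ndarray:
        return np.array([d.duration for d in self.select(**kwargs)])


def extract_dwells(
    paths: dict,
    frame_time: float,
    assignment: SubpopulationAssignment | None = None,
) -> DwellTimeSet:
    """Dwell durations from decoded state paths.

    ``paths`` maps molecule id to a per-frame state-index array.  The
    first and last dwell of every trace are flagged censored: their entry
    or exit was not observed.
    """
    dwell_set = DwellTimeSet()
    for mol_id, path in paths.items():
        path = np.asarray(path)
        label = (assignment.labels.get(mol_id, "unassigned")
                 if assignment is not None else "")
        changes = np.flatnonzero(np.diff(path) != 0)
        bounds = np.concatenate([[0], changes + 1, [len(path)]])
        n_dwells = len(bounds) - 1
        for k in range(n_dwells):
            start, stop = bounds[k], bounds[k + 1]
            censored = k == 0 or k == n_dwells - 1
            dwell_set.dwells.append(Dwell(
                duration=float((stop - start) * frame_time),
                censored=censored,
                state=int(path[start]),
                molecule_id=mol_id,
                subpopulation=label,
            ))
    return dwell_set


def fit_dwell_rate(
    durations: np.ndarray,
    frame_time: float,
    min_dwells: int = 20,
) -> tuple[float, float]:
    """State exit rate from a mono-exponential fit to the dwell histogram.

    Dwell durations are discrete multiples of the frame time (geometric in
    frames); fitting ``A * exp(-k t)`` to the frame-resolved histogram
    returns ``k = -ln(p_stay) / frame_time`` directly, i.e. the
    discretization-corrected exponential rate.  Returns ``(rate, stderr)``.
    """
    durations = np.asarray(durations, dtype=float)
    if len(durations) < min_dwells:
        raise ValueError(
            f"need at least {min_dwells} uncensored dwells, got {len(durations)}"
        )
    n_max = int(np.ceil(durations.max() / frame_time))
    edges = (np.arange(n_max + 1) + 0.5) * frame_time
    counts, _ = np.histogram(durations, bins=edges)
    centers = (np.arange(1, n_max + 1)) * frame_time
    keep = counts > 0
    k0 = 1.0 / max(durations.mean(), frame_time)

    def model(t, amp, k):
        return amp * np.exp(-k * t)

    popt, pcov = curve_fit(model, centers[keep], counts[keep],
                           p0=(counts.max(), k0), maxfev=10000)
    return float(popt[1]), float(np.sqrt(pcov[1, 1]))
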