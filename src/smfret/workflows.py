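"""Condition-level workflows gluing the pipeline stages together.

These helpers express the recurring experiment patterns — "simulate a
population for condition X and classify it", "run the paired survival
experiment for a dissociation condition" — on top of the lower-level
modules, so analysis scripts and tests stay short and share one code
path.
"""

from __future__ import annotations

import numpy as np

from . import conditions
from .config import SimulationConfig, SurvivalExperimentConfig
from .corrections import compute_fret, detect_bleach_steps, estimate_population_factors
from .histograms import fit_mixture, histogram_from_values
from .hmm import classify_static_dynamic, decode_path, train_hmm
from .kinetics import (
    assign_subpopulations,
    gates_from_state_means,
)
from .simulate import (
    MixtureClass,
    generate_population,
    generate_survival_experiment,
    sample_moleculewise_fret,
)
from .survival import build_survival, dissociation_rate

__all__ = [
    "population_config",
    "subpopulation_mixture",
    "correct_population",
    "classify_population",
    "fit_moleculewise_condition",
    "run_dissociation_condition",
    "subpopulation_analysis",
]

_DEFAULT_BACKGROUND = (50.0, 50.0)


def population_config(
    condition: str,
    n_molecules: int = 300,
    n_frames: int = 400,
    seed: int = 0,
    subpopulation: str = "P1",
    static_fraction: float | None = None,
    **overrides,
) -> SimulationConfig:
    """Simulation config with the published emission parameters of a condition."""
    if static_fraction is None:
        static_fraction = conditions.STATIC_FRACTION.get(condition, 0.0)
    return SimulationConfig(
        n_molecules=n_molecules,
        n_frames=n_frames,
        seed=seed,
        emission_states=conditions.emission_states(condition, subpopulation),
        static_fraction=static_fraction,
        **overrides,
    )


def subpopulation_mixture(
    condition: str,
    labels: tuple = ("P1", "P2"),
    weights: tuple | None = None,
) -> list[MixtureClass]:
    """Mixture classes with per-subpopulation emission states for a condition."""
    if weights is None:
        weights = conditions.SUBPOPULATION_WEIGHTS[condition]
    total = sum(weights)
    return [
        MixtureClass(
            weight=w / total,
            label=lab,
            overrides={"emission_states": conditions.emission_states(condition, lab)},
        )
        for w, lab in zip(weights, labels)
    ]


def correct_population(
    traces: list,
    background: tuple = _DEFAULT_BACKGROUND,
    default_alpha: float = 0.05,
    default_gamma: float = 0.9,
):
    """Bleach detection, correction-factor estimation and FRET calculation."""
    bleaches = [detect_bleach_steps(t, background=background) for t in traces]
    factors = estimate_population_factors(
        traces, bleaches, background=background,
        default_alpha=default_alpha, default_gamma=default_gamma,
    )
    fret = [compute_fret(t, f, background=background, bleach=b)
            for t, f, b in zip(traces, factors, bleaches)]
    return fret, factors, bleaches


def classify_population(
    fret_traces: list,
    seed: int = 0,
    **kwargs,
) -> tuple[list, float]:
    """Static/dynamic labels and the static percentage among assigned traces."""
    labels = [classify_static_dynamic(ft, seed=seed, **kwargs)[0]
              for ft in fret_traces]
    assigned = [lab for lab in labels if lab != "unassigned"]
    static_pct = (100.0 * sum(lab == "static" for lab in assigned) / len(assigned)
                  if assigned else float("nan"))
    return labels, static_pct


def fit_moleculewise_condition(
    condition: str,
    n_molecules: int = 2000,
    seed: int = 0,
    bin_width: float = 0.02,
):
    """Sample molecule-wise FRET values for a condition and fit the mixture."""
    comps = conditions.MOLECULEWISE_COMPONENTS[condition]
    rng = np.random.default_rng(seed)
    values = sample_moleculewise_fret(comps, n_molecules, rng)
    hist = histogram_from_values(values, bin_width=bin_width)
    return fit_mixture(hist, len(comps)), hist


def run_dissociation_condition(
    condition: str,
    n_molecules: int = 500,
    seed: int = 0,
    bleach_rate: float = conditions.PHOTOBLEACH_RATE,
    concentration: float = float("nan"),
):
    """Paired survival experiment for a named dissociation condition."""
    cfg = SurvivalExperimentConfig(
        n_molecules=n_molecules,
        bleach_rate=bleach_rate,
        dissociation_rate=conditions.DISSOCIATION_RATES[condition],
        seed=seed,
    )
    experiment = generate_survival_experiment(cfg)
    return dissociation_rate(
        build_survival(experiment.control),
        build_survival(experiment.treatment),
        condition=condition,
        concentration=concentration,
    )


def subpopulation_analysis(
    condition: str,
    n_molecules: int = 300,
    n_frames: int = 600,
    seed: int = 0,
    gate_half_width: float = 0.05,
    hmm_restarts: int = 3,
    hmm_max_iter: int = 200,
    background: tuple = _DEFAULT_BACKGROUND,
):
    """Full dynamic-population workflow: simulate → HMM → TDP gates → assign.

    Simulates a dynamic two-subpopulation mixture for the condition,
    trains a per-molecule 3-state HMM, decodes transitions, gates them
    with rectangles around the known subpopulation state pairs, and
    assigns each molecule by transition majority.  Returns the assignment,
    the pooled transition list, and the ground truth.
    """
    mixture = subpopulation_mixture(condition)
    base = population_config(condition, n_molecules=n_molecules,
                             n_frames=n_frames, seed=seed,
                             static_fraction=0.0,
                             bleach_rate_donor=0.0, bleach_rate_acceptor=0.0)
    traces, truth = generate_population(base, mixture)
    fret, _factors, _bleaches = correct_population(traces, background=background)

    molecule_transitions: dict = {}
    pooled = []
    for ft in fret:
        if ft.n_usable < 30:
            continue
        model = train_hmm(ft, n_states=3, seed=seed,
                          n_restarts=hmm_restarts, max_iter=hmm_max_iter)
        path = decode_path(model, ft)
        coords = np.array([(fe, te) for _t, fe, te in path.transitions])
        molecule_transitions[ft.molecule_id] = coords
        pooled.extend(coords.tolist())

    gates = {
        label: gates_from_state_means(
            [m for m, _sd in conditions.emission_states(condition, label)],
            half_width=gate_half_width,
        )
        for label in ("P1", "P2")
    }
    assignment = assign_subpopulations(molecule_transitions, gates)
    return assignment, np.array(pooled), truth
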