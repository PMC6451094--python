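"""Reference parameter sets for the experimental conditions.

These are the published Gaussian-fit parameters characterizing the
molecule-wise and frame-wise FRET-efficiency distributions of TBP–DNA
complexes on the H2B promoter under different cofactor conditions
(binary DNA/TBP complexes, ternary complexes with Mot1, and the effect
of ATP or TFIIA).  They parameterize the synthetic-data generator, so
simulated populations reproduce the statistical structure of the real
measurements and every recovery test has a known ground truth.

Conventions follow the published tables: component areas ``A`` in percent
of the population, means ``mu`` and widths ``sigma`` in FRET-efficiency
percent.
"""

from __future__ import annotations

__all__ = [
    "MOLECULEWISE_COMPONENTS",
    "FRAMEWISE_SUBPOPULATIONS",
    "SUBPOPULATION_WEIGHTS",
    "STATIC_FRACTION",
    "DISSOCIATION_RATES",
    "PHOTOBLEACH_RATE",
    "emission_states",
]

# Molecule-wise mixture components per condition: (A %, mu %, sigma %).
# The binary-complex low-FRET population is the published combined area of
# its main peak and shoulder.
MOLECULEWISE_COMPONENTS: dict[str, list[tuple[float, float, float]]] = {
    "DNA/TBP": [(72, 25, 4), (27, 34, 13)],
    "DNA/TBP/Mot1": [(6, 24, 4), (28, 34, 13), (65, 78, 7)],
    "DNA/TBP/Mot1+ATP": [(49, 24, 4), (43, 32, 13), (8, 77, 7)],
}

# Frame-wise three-state emission parameters per condition and
# subpopulation: (A %, mu %, sigma %) for states S1 < S2 < S3.
FRAMEWISE_SUBPOPULATIONS: dict[str, dict[str, list[tuple[float, float, float]]]] = {
    "DNA/TBP": {
        "P1": [(18, 25, 9), (51, 44, 8), (31, 69, 9)],
        "P2": [(21, 32, 10), (39, 59, 7), (40, 76, 7)],
    },
    "DNA/TBP/TFIIA": {
        "P1": [(9, 19, 6), (53, 41, 9), (39, 68, 7)],
        "P2": [(11, 29, 10), (48, 56, 7), (41, 75, 6)],
        "P3": [(6, 32, 12), (51, 68, 7), (43, 83, 5)],
    },
    "DNA/TBP/Mot1": {
        "P1": [(15, 25, 8), (39, 45, 9), (46, 69, 7)],
        "P2": [(10, 30, 10), (43, 57, 8), (47, 76, 6)],
        "P3": [(51, 35, 11), (44, 61, 6), (5, 81, 6)],
    },
    "DNA/TBP/Mot1+ATP": {
        "P1": [(23, 25, 7), (30, 45, 7), (47, 68, 7)],
        "P2": [(11, 30, 11), (39, 56, 6), (50, 74, 6)],
        "P3": [(15, 32, 14), (42, 67, 7), (43, 82, 4)],
    },
}

# Two-subpopulation weights (P1, P2) per condition, as the published ratio
# of the P1/P2 fractions.
SUBPOPULATION_WEIGHTS: dict[str, tuple[float, float]] = {
    "DNA/TBP": (0.435, 0.564),
    "DNA/TBP/TFIIA": (0.183, 0.817),
    "DNA/TBP/Mot1": (0.418, 0.582),
    "DNA/TBP/Mot1+ATP": (0.231, 0.770),
}

# Fraction of molecules with a static FRET signal.
STATIC_FRACTION: dict[str, float] = {
    "DNA/TBP/Mot1": 0.60,       # pre-ATP ternary complexes, ~60% static
    "DNA/TBP/Mot1+ATP": 0.95,   # over 90% static after ATP addition
}

# Photobleaching-corrected dissociation rates (1/s) by condition label.
DISSOCIATION_RATES: dict[str, float] = {
    "ATP only": 0.0,
    "ADP + Mot1": 0.0,
    "ATP + 1 nM Mot1": 0.02,
    "ATP + 3.4 nM Mot1": 0.05,
    "ATP + 12 nM Mot1": 0.2,
}

# Typical single-experiment photobleaching rate used by the simulated
# survival experiments (the real rate is alignment-dependent and fitted
# per experiment).
PHOTOBLEACH_RATE: float = 0.10


def emission_states(condition: str, subpopulation: str) -> tuple:
    """Emission ``(mean, sd)`` pairs on [0, 1] for one subpopulation."""
    comps = FRAMEWISE_SUBPOPULATIONS[condition][subpopulation]
    return tuple((mu / 100.0, sd / 100.0) for _a, mu, sd in comps)
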