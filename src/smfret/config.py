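"""Configuration objects for the simulation and analysis pipeline.

Two config types drive the synthetic-data generator: :class:`SimulationConfig`
describes an imaging experiment on surface-immobilized FRET pairs (frame time,
emission states, kinetics, detection corrections, camera noise), and
:class:`SurvivalExperimentConfig` describes a paired photobleaching /
dissociation measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ConfigurationError",
    "SimulationConfig",
    "SurvivalExperimentConfig",
    "linear_chain_matrix",
]


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


def linear_chain_matrix(p_up: Sequence[float], p_down: Sequence[float]) -> np.ndarray:
    """Row-stochastic matrix for a linear (nearest-neighbour) state chain.

    ``p_up[i]`` is the per-frame probability of moving from state ``i`` to
    ``i+1`` and ``p_down[i]`` from state ``i+1`` down to ``i``.  Direct jumps
    between non-adjacent states are forbidden, the topology in which a
    low-to-high FRET transition must pass through the intermediate state.
    """
    n = len(p_up) + 1
    if len(p_down) != len(p_up):
        raise ConfigurationError("p_up and p_down must have equal length")
    mat = np.zeros((n, n))
    for i in range(n - 1):
        mat[i, i + 1] = p_up[i]
        mat[i + 1, i] = p_down[i]
    for i in range(n):
        mat[i, i] = 1.0 - mat[i].sum()
    if (mat < 0).any():
        raise ConfigurationError("switch probabilities exceed 1 in a row")
    return mat


def _default_transition_matrix() -> np.ndarray:
    # mean dwell ~10 frames per state; no direct jumps between outer states
    return linear_chain_matrix([0.1, 0.05], [0.05, 0.1])


@dataclass
class SimulationConfig:
    """Parameters of a synthetic two-channel TIRF FRET measurement.

    Attributes
    ----------
    n_molecules:
        Number of immobilized molecules to simulate.
    frame_time:
        Camera integration time per frame in seconds (typical range
        0.015–0.3 s for this kind of measurement).
    n_frames:
        Movie length in frames.
    emission_states:
        List of ``(mean, sd)`` pairs of apparent FRET efficiency for each
        hidden conformational state, both in [0, 1].
    transition_matrix:
        Row-stochastic matrix of per-frame switching probabilities between
        emission states.
    static_fraction:
        Probability that a molecule shows a single static FRET state with no
        transitions.
    total_intensity:
        Photon budget per frame (counts) of a molecule before detection
        corrections.
    crosstalk_alpha:
        Fraction of donor signal leaking into the acceptor channel.
    gamma:
        Relative acceptor/donor detection-efficiency (and quantum-yield)
        factor; the acceptor channel records ``gamma * total * E``.
    background:
        Per-frame background counts added to (donor, acceptor) channels.
    static_frame_sd:
        When set, a static molecule draws one personal mean efficiency
        from its state's ``(mean, sd)`` Gaussian — modelling
        molecule-to-molecule heterogeneity — and its frames scatter
        around that mean with this (smaller) width.  When ``None`` (the
        default) every frame is drawn from the state Gaussian directly.
    noise_model:
        ``"gaussian_read"`` (additive read noise only), ``"poisson_shot"``
        (Poisson shot noise plus read noise, the default) or
        ``"emccd_excess"`` (shot noise variance doubled by the EM excess
        noise factor, Gaussian approximation).
    read_noise_sd:
        Gaussian read-noise standard deviation in counts.
    bleach_rate_donor, bleach_rate_acceptor:
        Single-step photobleaching rates (1/s); waiting times are
        exponential and the two fluorophores bleach independently.
    excitation_scheme:
        ``"single"`` (532 nm only), ``"alternating_488_532"`` (frame-wise
        alternation for three-color detection of a labeled cofactor) or
        ``"red_after_frame10"`` (direct red excitation after ten green
        frames, the dissociation-measurement scheme).
    mot1_fraction:
        Fraction of molecules carrying a 488-excited cofactor label (only
        meaningful with the alternating scheme).
    mot1_intensity:
        Mean counts per 488-frame from the cofactor label.
    direct_excitation_fraction:
        Fraction of the 532-excited donor signal that also appears in
        488-excitation frames through direct excitation of the donor dye.
    seed:
        Base seed; every molecule draws from an independent substream so
        results are bit-reproducible and independent of molecule order.
    """

    n_molecules: int = 100
    frame_time: float = 0.015
    n_frames: int = 400
    emission_states: tuple = ((0.25, 0.09), (0.44, 0.08), (0.69, 0.09))
    transition_matrix: np.ndarray = field(default_factory=_default_transition_matrix)
    static_fraction: float = 0.0
    static_state: int | None = None
    static_frame_sd: float | None = None
    total_intensity: float = 500.0
    crosstalk_alpha: float = 0.05
    gamma: float = 0.9
    background: tuple = (50.0, 50.0)
    noise_model: str = "poisson_shot"
    read_noise_sd: float = 10.0
    bleach_rate_donor: float = 0.02
    bleach_rate_acceptor: float = 0.04
    excitation_scheme: str = "single"
    mot1_fraction: float = 0.0
    mot1_intensity: float = 300.0
    direct_excitation_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.frame_time <= 0:
            raise ConfigurationError("frame_time must be positive")
        if self.n_frames < 1 or self.n_molecules < 0:
            raise ConfigurationError("n_frames and n_molecules must be positive")
        if not 0.0 <= self.static_fraction <= 1.0:
            raise ConfigurationError("static_fraction must lie in [0, 1]")
        if not 0.0 <= self.crosstalk_alpha < 1.0:
            raise ConfigurationError("crosstalk_alpha must lie in [0, 1)")
        if self.gamma <= 0:
            raise ConfigurationError("gamma must be positive")
        if self.bleach_rate_donor < 0 or self.bleach_rate_acceptor < 0:
            raise ConfigurationError("bleach rates must be non-negative")
        mat = self.transition_matrix
        n_states = len(self.emission_states)
        if mat.shape != (n_states, n_states):
            raise ConfigurationError(
                f"transition matrix shape {mat.shape} does not match "
                f"{n_states} emission states"
            )
        if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-12):
            raise ConfigurationError("transition matrix rows must sum to 1")
        if (mat < 0).any():
            raise ConfigurationError("transition probabilities must be non-negative")
        for mean, sd in self.emission_states:
            if not 0.0 <= mean <= 1.0:
                raise ConfigurationError("emission state means must lie in [0, 1]")
            if not 0.0 <= sd <= 1.0:
                raise ConfigurationError("emission state widths must lie in [0, 1]")
        if self.noise_model not in ("gaussian_read", "poisson_shot", "emccd_excess"):
            raise ConfigurationError(f"unknown noise model {self.noise_model!r}")
        if self.excitation_scheme not in (
            "single",
            "alternating_488_532",
            "red_after_frame10",
        ):
            raise ConfigurationError(
                f"unknown excitation scheme {self.excitation_scheme!r}"
            )

    def with_overrides(self, **overrides) -> "SimulationConfig":
        return replace(self, **overrides)


@dataclass
class SurvivalExperimentConfig:
    """Paired photobleaching-control / dissociation survival experiment.

    The control arm disappears at the photobleaching rate ``k1 =
    bleach_rate`` alone; the treatment arm at ``k2 = bleach_rate +
    dissociation_rate``.  Disappearance times are discretized to the frame
    time and right-censored at the end of the recording.
    """

    n_molecules: int = 500
    bleach_rate: float = 0.10
    dissociation_rate: float = 0.05
    frame_time: float = 0.030
    n_frames: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.bleach_rate < 0 or self.dissociation_rate < 0:
            raise ConfigurationError("rates must be non-negative")
        if self.frame_time <= 0 or self.n_frames < 1 or self.n_molecules < 1:
            raise ConfigurationError("frame_time, n_frames, n_molecules must be positive")

    @property
    def horizon(self) -> float:
        return self.n_frames * self.frame_time
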