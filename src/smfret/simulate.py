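"""Synthetic-data generator for two-channel TIRF FRET experiments.

Everything downstream of the camera is testable against this module: it
produces ground-truthed intensity traces with Markovian FRET-state
switching, single-step photobleaching, spectral crosstalk, unequal
detection efficiencies, background and camera noise; bead images for
channel registration; rendered two-channel movies; and paired
photobleaching/dissociation survival experiments.

The forward model per frame is::

    E_app ~ Normal(mu_state, sd_state)          (clipped to [0, 1])
    I_D   = T * (1 - E_app)                     (donor channel, ideal)
    I_A   = gamma * T * E_app                   (acceptor channel, ideal)
    acceptor_detected = I_A + alpha * I_D + bg_A (+ noise)
    donor_detected    = I_D + bg_D               (+ noise)

so that the corrected ratiometric efficiency
``(I_A) / (I_A + gamma * I_D)`` recovers ``E_app`` exactly in the
noise-free limit.  After acceptor photobleaching the donor receives the
full photon budget ``T`` in a single step (the signature used to estimate
per-molecule correction factors); after donor photobleaching both
channels drop to background.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .config import ConfigurationError, SimulationConfig, SurvivalExperimentConfig
from .traces import GroundTruth, IntensityTrace, MoleculeTruth

__all__ = [
    "molecule_rng",
    "stationary_distribution",
    "generate_state_path",
    "generate_trace",
    "generate_molecule",
    "MixtureClass",
    "generate_population",
    "sample_moleculewise_fret",
    "BeadImages",
    "generate_bead_stack",
    "Movie",
    "generate_movie",
    "SurvivalSample",
    "SurvivalExperiment",
    "generate_survival_experiment",
]


def molecule_rng(seed: int, molecule_index: int, stream: int = 0) -> np.random.Generator:
    """Independent, reproducible substream for one molecule.

    Streams are derived with ``SeedSequence`` spawn keys, so adding or
    reordering molecules never reshuffles another molecule's randomness.
    """
    ss = np.random.SeedSequence(seed, spawn_key=(molecule_index, stream))
    return np.random.default_rng(ss)


def stationary_distribution(transition_matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    mat = np.asarray(transition_matrix, dtype=float)
    vals, vecs = np.linalg.eig(mat.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def _draw_static(config: SimulationConfig, rng: np.random.Generator) -> bool:
    return bool(rng.random() < config.static_fraction)


def generate_state_path(
    config: SimulationConfig,
    molecule_index: int,
    rng: np.random.Generator | None = None,
    static: bool | None = None,
) -> np.ndarray:
    """Realize one molecule's hidden-state path.

    Dynamic molecules follow a discrete Markov chain with the configured
    per-frame transition matrix, started from its stationary distribution.
    Static molecules occupy a single state for the whole trace.
    """
    if molecule_index >= config.n_molecules:
        raise ConfigurationError("molecule_index exceeds n_molecules")
    if rng is None:
        rng = molecule_rng(config.seed, molecule_index, stream=0)
    mat = config.transition_matrix
    n_states = mat.shape[0]
    pi = stationary_distribution(mat)
    if static is None:
        static = _draw_static(config, rng)
    if static:
        state = config.static_state
        if state is None:
            state = int(rng.choice(n_states, p=pi))
        return np.full(config.n_frames, state, dtype=np.int64)
    path = np.empty(config.n_frames, dtype=np.int64)
    path[0] = rng.choice(n_states, p=pi)
    # cumulative-row lookup keeps the per-frame draw cheap
    cum = np.cumsum(mat, axis=1)
    u = rng.random(config.n_frames - 1)
    for t in range(1, config.n_frames):
        path[t] = np.searchsorted(cum[path[t - 1]], u[t - 1], side="right")
    return path


def _bleach_frame(rate: float, frame_time: float, n_frames: int,
                  rng: np.random.Generator) -> int | None:
    """Frame index from which a fluorophore is dark, or None if it survives."""
    if rate <= 0:
        # consume a draw regardless so rate=0 and rate>0 traces stay aligned
        rng.exponential()
        return None
    t = rng.exponential(1.0 / rate)
    frame = int(t / frame_time)
    return frame if frame < n_frames else None


def _add_noise(signal: np.ndarray, config: SimulationConfig,
               rng: np.random.Generator) -> np.ndarray:
    model = config.noise_model
    out = np.asarray(signal, dtype=float)
    if model == "poisson_shot":
        out = rng.poisson(np.clip(out, 0, None)).astype(float)
    elif model == "emccd_excess":
        # EM excess noise factor ~sqrt(2): shot-noise variance doubled
        clipped = np.clip(out, 0, None)
        out = clipped + np.sqrt(2.0 * clipped) * rng.standard_normal(out.shape)
    if config.read_noise_sd > 0:
        out = out + config.read_noise_sd * rng.standard_normal(out.shape)
    return out


def generate_trace(
    config: SimulationConfig,
    path: np.ndarray,
    molecule_index: int = 0,
    rng: np.random.Generator | None = None,
    subpopulation: str = "P1",
    static: bool = False,
    mot1_labeled: bool | None = None,
) -> tuple[IntensityTrace, MoleculeTruth]:
    """Generate a two-channel intensity trace from a hidden-state path."""
    path = np.asarray(path, dtype=np.int64)
    if len(path) != config.n_frames:
        raise ConfigurationError("state path length must equal n_frames")
    if rng is None:
        rng = molecule_rng(config.seed, molecule_index, stream=1)

    means = np.array([m for m, _ in config.emission_states])
    sds = np.array([s for _, s in config.emission_states])
    if static and config.static_frame_sd is not None:
        # molecule-to-molecule heterogeneity: one personal mean per molecule
        state = int(path[0])
        personal = rng.normal(means[state], sds[state])
        e_app = rng.normal(personal, config.static_frame_sd, len(path))
    else:
        e_app = rng.normal(means[path], sds[path])
    e_app = np.clip(e_app, 0.0, 1.0)

    total = config.total_intensity
    donor_ideal = total * (1.0 - e_app)
    acceptor_ideal = config.gamma * total * e_app

    fa = _bleach_frame(config.bleach_rate_acceptor, config.frame_time,
                       config.n_frames, rng)
    fd = _bleach_frame(config.bleach_rate_donor, config.frame_time,
                       config.n_frames, rng)
    if fa is not None and (fd is None or fa < fd):
        # acceptor dark, donor takes over the full photon budget
        donor_ideal[fa:] = total
        acceptor_ideal[fa:] = 0.0
    if fd is not None:
        donor_ideal[fd:] = 0.0
        acceptor_ideal[fd:] = 0.0

    bg_d, bg_a = config.background
    donor_detected = donor_ideal + bg_d
    acceptor_detected = acceptor_ideal + config.crosstalk_alpha * donor_ideal + bg_a

    donor_detected = _add_noise(donor_detected, config, rng)
    acceptor_detected = _add_noise(acceptor_detected, config, rng)

    ex488 = None
    if config.excitation_scheme == "alternating_488_532":
        if mot1_labeled is None:
            mot1_labeled = bool(rng.random() < config.mot1_fraction)
        label_signal = config.mot1_intensity if mot1_labeled else 0.0
        label = np.full(config.n_frames, label_signal)
        if fd is not None:
            # the cofactor label is assumed to survive; only direct-excitation
            # bleed from the donor disappears with the donor
            pass
        direct = config.direct_excitation_fraction * donor_ideal
        ex488 = _add_noise(label + direct + bg_d, config, rng)
    else:
        mot1_labeled = bool(mot1_labeled)

    trace = IntensityTrace(
        molecule_id=molecule_index,
        frame_time=config.frame_time,
        donor=donor_detected,
        acceptor=acceptor_detected,
        ex488=ex488,
        excitation_scheme=config.excitation_scheme,
    )
    truth = MoleculeTruth(
        molecule_id=molecule_index,
        state_path=path,
        apparent_e=e_app,
        subpopulation=subpopulation,
        static=static,
        static_state=int(path[0]) if static else None,
        acceptor_bleach_frame=fa,
        donor_bleach_frame=fd,
        mot1_labeled=bool(mot1_labeled),
    )
    return trace, truth


def generate_molecule(
    config: SimulationConfig,
    molecule_index: int,
    subpopulation: str = "P1",
) -> tuple[IntensityTrace, MoleculeTruth]:
    """Path + trace for one molecule, with the static draw from its own stream."""
    rng_path = molecule_rng(config.seed, molecule_index, stream=0)
    static = _draw_static(config, rng_path)
    path = generate_state_path(config, molecule_index, rng=rng_path, static=static)
    return generate_trace(config, path, molecule_index,
                          subpopulation=subpopulation, static=static)


@dataclass
class MixtureClass:
    """One molecule class in a population mixture."""

    weight: float
    label: str
    overrides: dict = field(default_factory=dict)


def generate_population(
    config: SimulationConfig,
    mixture: list[MixtureClass] | None = None,
) -> tuple[list[IntensityTrace], GroundTruth]:
    """Generate a population of molecules, optionally from a class mixture.

    Class membership is drawn per molecule with the mixture weights; each
    class applies its overrides on top of the base config.  A molecule never
    changes class within a run.
    """
    if mixture is None:
        mixture = [MixtureClass(1.0, "P1")]
    weights = np.array([c.weight for c in mixture], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-6:
        if abs(weights.sum() - 1.0) > 0.02:
            raise ConfigurationError("mixture weights must sum to 1")
        weights = weights / weights.sum()  # absorb rounding from printed weights
    labels = [c.label for c in mixture]
    sub_configs = [config.with_overrides(**c.overrides) for c in mixture]

    class_rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(0x706F70,))
    )
    assignments = class_rng.choice(len(mixture), size=config.n_molecules, p=weights)

    traces: list[IntensityTrace] = []
    molecules: list[MoleculeTruth] = []
    for i in range(config.n_molecules):
        k = int(assignments[i])
        sub = sub_configs[k]
        sub = replace(sub, n_molecules=config.n_molecules, seed=config.seed)
        trace, truth = generate_molecule(sub, i, subpopulation=labels[k])
        traces.append(trace)
        molecules.append(truth)
    truth_all = GroundTruth(
        molecules=molecules,
        mixture=[(c.weight, c.label, dict(c.overrides)) for c in mixture],
    )
    return traces, truth_all


def sample_moleculewise_fret(
    components: list[tuple[float, float, float]],
    n: int,
    rng: np.random.Generator,
    percent: bool = True,
) -> np.ndarray:
    """Sample molecule-wise FRET values from a Gaussian mixture.

    ``components`` are ``(area, mean, sd)`` triples; with ``percent=True``
    (the convention of published fit tables) all three are given in percent
    and the returned efficiencies are on [0, 1].
    """
    comps = np.asarray(components, dtype=float)
    scale = 100.0 if percent else 1.0
    weights = comps[:, 0] / comps[:, 0].sum()
    which = rng.choice(len(comps), size=n, p=weights)
    return rng.normal(comps[which, 1] / scale, comps[which, 2] / scale)


# ---------------------------------------------------------------------------
# image-domain generators


@dataclass
class BeadImages:
    """Matched bead images of the two spectral channels."""

    channel1: np.ndarray
    channel2: np.ndarray
    positions1: np.ndarray  # (n, 2) x, y in channel-1 pixel coords
    positions2: np.ndarray


def _render_psf(image: np.ndarray, x: float, y: float, counts: float,
                sigma: float) -> None:
    """Add a normalized 2D Gaussian spot in place (origin top-left, 0-based)."""
    h, w = image.shape
    r = int(np.ceil(4 * sigma))
    x0, x1 = int(np.floor(x)) - r, int(np.floor(x)) + r + 1
    y0, y1 = int(np.floor(y)) - r, int(np.floor(y)) + r + 1
    x0c, x1c = max(x0, 0), min(x1, w)
    y0c, y1c = max(y0, 0), min(y1, h)
    if x0c >= x1c or y0c >= y1c:
        return
    xs = np.arange(x0c, x1c)
    ys = np.arange(y0c, y1c)
    gx = np.exp(-0.5 * ((xs - x) / sigma) ** 2)
    gy = np.exp(-0.5 * ((ys - y) / sigma) ** 2)
    patch = counts * np.outer(gy, gx) / (2 * np.pi * sigma**2)
    image[y0c:y1c, x0c:x1c] += patch


def generate_bead_stack(
    true_map,
    n_beads: int,
    noise: float = 2.0,
    image_shape: tuple = (64, 64),
    psf_sigma: float = 1.0,
    amplitude: float = 5000.0,
    seed: int = 0,
    margin: float = 8.0,
) -> BeadImages:
    """Render fluorescent beads into both channels of the dual-view chip.

    Bead positions in channel 1 are uniform within the margins; channel-2
    positions are the mapped coordinates, so downstream map estimation can
    be validated against ``true_map`` exactly.
    """
    if n_beads < 3:
        raise ConfigurationError("at least 3 beads are required for map estimation")
    rng = np.random.default_rng(seed)
    h, w = image_shape
    pos1 = np.column_stack([
        rng.uniform(margin, w - margin, n_beads),
        rng.uniform(margin, h - margin, n_beads),
    ])
    pos2 = true_map.apply(pos1)
    ch1 = np.zeros(image_shape)
    ch2 = np.zeros(image_shape)
    for (x1, y1), (x2, y2) in zip(pos1, pos2):
        _render_psf(ch1, x1, y1, amplitude, psf_sigma)
        _render_psf(ch2, x2, y2, amplitude, psf_sigma)
    if noise > 0:
        ch1 = ch1 + noise * rng.standard_normal(image_shape)
        ch2 = ch2 + noise * rng.standard_normal(image_shape)
    return BeadImages(ch1, ch2, pos1, pos2)


@dataclass
class Movie:
    """Rendered dual-view movie with per-molecule ground truth.

    ``stack`` has shape ``(n_frames, height, 2 * width)``: the left half of
    the chip is the donor channel, the right half the acceptor channel
    (channel-local coordinates).
    """

    stack: np.ndarray
    frame_time: float
    channel_width: int
    traces: list
    truth: GroundTruth


def generate_movie(
    config: SimulationConfig,
    channel_map,
    image_shape: tuple = (48, 48),
    psf_sigma: float = 1.0,
    pixel_background: float = 20.0,
    pixel_noise_sd: float = 3.0,
    margin: float = 6.0,
) -> Movie:
    """Render a population of molecules into a two-channel image stack.

    Trace-level background and noise are disabled and re-introduced at the
    pixel level, so extraction accuracy can be judged against the clean
    per-frame counts stored in ``Movie.traces``.
    """
    clean = config.with_overrides(background=(0.0, 0.0),
                                  noise_model="gaussian_read",
                                  read_noise_sd=0.0)
    traces, truth = generate_population(clean)
    h, w = image_shape
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(0x6D6F76,))
    )
    pos1 = np.column_stack([
        rng.uniform(margin, w - margin, config.n_molecules),
        rng.uniform(margin, h - margin, config.n_molecules),
    ])
    pos2 = channel_map.apply(pos1)
    for mol, p in zip(truth.molecules, pos1):
        mol.position = (float(p[0]), float(p[1]))

    stack = np.full((config.n_frames, h, 2 * w), float(pixel_background))
    for trace, (x1, y1), (x2, y2) in zip(traces, pos1, pos2):
        for t in range(config.n_frames):
            _render_psf(stack[t, :, :w], x1, y1, trace.donor[t], psf_sigma)
            _render_psf(stack[t, :, w:], x2, y2, trace.acceptor[t], psf_sigma)
    if pixel_noise_sd > 0:
        stack = stack + pixel_noise_sd * rng.standard_normal(stack.shape)
    return Movie(stack=stack, frame_time=config.frame_time, channel_width=w,
                 traces=traces, truth=truth)


# ---------------------------------------------------------------------------
# survival experiments


@dataclass
class SurvivalSample:
    """Disappearance times of one experimental arm."""

    times: np.ndarray  # seconds, discretized to the frame time
    censored: np.ndarray  # True where the molecule outlived the recording
    frame_time: float
    horizon: float
    label: str = ""

    @property
    def n(self) -> int:
        return len(self.times)


@dataclass
class SurvivalExperiment:
    """Paired bleaching-only control and bleaching+dissociation treatment."""

    control: SurvivalSample
    treatment: SurvivalSample
    true_bleach_rate: float
    true_dissociation_rate: float


def _exponential_sample(rate: float, config: SurvivalExperimentConfig,
                        rng: np.random.Generator, label: str) -> SurvivalSample:
    horizon = config.horizon
    if rate <= 0:
        raw = np.full(config.n_molecules, np.inf)
    else:
        raw = rng.exponential(1.0 / rate, size=config.n_molecules)
    censored = raw >= horizon
    frames = np.ceil(raw / config.frame_time)
    times = np.where(censored, horizon, frames * config.frame_time)
    return SurvivalSample(times=times, censored=censored,
                          frame_time=config.frame_time, horizon=horizon,
                          label=label)


def generate_survival_experiment(
    config: SurvivalExperimentConfig,
) -> SurvivalExperiment:
    """Generate paired control/treatment disappearance-time samples.

    The control arm disappears by photobleaching alone (rate ``k1``); the
    treatment arm by photobleaching plus dissociation (rate ``k2 = k1 +
    k_diss``), so the downstream ``k2 - k1`` statistic estimates the
    dissociation rate.
    """
    rng_c = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
    rng_t = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(2,)))
    control = _exponential_sample(config.bleach_rate, config, rng_c, "control")
    treatment = _exponential_sample(config.bleach_rate + config.dissociation_rate,
                                    config, rng_t, "treatment")
    return SurvivalExperiment(
        control=control,
        treatment=treatment,
        true_bleach_rate=config.bleach_rate,
        true_dissociation_rate=config.dissociation_rate,
    )
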