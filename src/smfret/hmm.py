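"""Per-molecule Gaussian-emission hidden Markov models.

Each dynamic molecule gets its own model, trained by Baum–Welch on the
corrected FRET-efficiency series until the likelihood change falls below
1e-9, decoded by Viterbi, and used to tabulate the (initial E, final E)
transition pairs that feed the transition density plot.  Model order is
chosen as the smallest state count whose penalized likelihood (BIC)
matches the best candidate, and the same criterion drives the automated
static/dynamic trace classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _hmmkern
from .traces import FretTrace

__all__ = [
    "HmmModel",
    "StatePath",
    "train_hmm",
    "forward_loglik",
    "decode_path",
    "select_n_states",
    "classify_static_dynamic",
    "gaussian_loglik",
]


@dataclass
class HmmModel:
    """A trained Gaussian-emission HMM for one molecule."""

    n_states: int
    startprob: np.ndarray
    transmat: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float = np.nan
    n_iterations: int = 0
    converged: bool = False
    degenerate: bool = False
    loglik_history: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.startprob = np.asarray(self.startprob, dtype=float)
        self.transmat = np.asarray(self.transmat, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if not np.allclose(self.transmat.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if (self.sds <= 0).any():
            raise ValueError("emission SDs must be positive")

    @property
    def n_parameters(self) -> int:
        n = self.n_states
        return (n - 1) + n * (n - 1) + 2 * n

    def bic(self, n_obs: int) -> float:
        return -2.0 * self.log_likelihood + self.n_parameters * np.log(n_obs)


@dataclass
class StatePath:
    """Viterbi decoding of one trace under its trained model."""

    states: np.ndarray
    posteriors: np.ndarray
    log_probability: float
    frame_time: float
    state_means: np.ndarray
    transitions: list = field(default_factory=list)  # (time_s, from_E, to_E)

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)


def gaussian_loglik(obs: np.ndarray) -> float:
    """Log-likelihood of a single-Gaussian (one-state) model at its MLE."""
    obs = np.asarray(obs, dtype=float)
    sd = max(float(obs.std()), 1e-6)
    z = (obs - obs.mean()) / sd
    return float(-0.5 * np.sum(z**2) - len(obs) * np.log(sd * np.sqrt(2 * np.pi)))


def forward_loglik(model: HmmModel, obs: np.ndarray) -> float:
    """Scaled-forward total log-likelihood of a series under a model."""
    obs = np.ascontiguousarray(obs, dtype=float)
    return float(_hmmkern.forward_loglik(obs, model.startprob, model.transmat,
                                         model.means, model.sds))


def _initial_models(obs: np.ndarray, n_states: int, n_restarts: int,
                    seed: int) -> list[tuple]:
    """Quantile-spread emission means with seeded jitter per restart."""
    rng = np.random.default_rng(seed)
    q = np.quantile(obs, (np.arange(n_states) + 0.5) / n_states)
    sd0 = max(float(obs.std()) / max(n_states, 1), 0.02)
    inits = []
    for r in range(n_restarts):
        means = np.sort(q + (0.0 if r == 0 else rng.normal(0, sd0, n_states)))
        inits.append((means, np.full(n_states, max(float(obs.std()), 0.02))))
    return inits


def _extract_obs(trace) -> np.ndarray:
    if isinstance(trace, FretTrace):
        return np.ascontiguousarray(trace.windowed)
    return np.ascontiguousarray(np.asarray(trace, dtype=float))


def train_hmm(
    trace,
    n_states: int = 3,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-9,
    min_sd: float = 1e-3,
    keep_history: bool = False,
) -> HmmModel:
    """Baum–Welch training on a FRET-efficiency series.

    Training runs from several seeded initializations (quantile-spread
    means) and keeps the highest-likelihood model.  Convergence is an
    absolute likelihood change below ``tol`` (default 1e-9); models that
    hit ``max_iter`` first are returned with ``converged=False``.  A model
    whose states collapse (near-duplicate means or an unoccupied state) is
    flagged ``degenerate``.
    """
    obs = _extract_obs(trace)
    if len(obs) < 10 * n_states:
        raise ValueError(
            f"need at least {10 * n_states} frames to train {n_states} states"
        )
    best: HmmModel | None = None
    for means0, sds0 in _initial_models(obs, n_states, n_restarts, seed):
        model = _train_single(obs, means0, sds0, max_iter, tol, min_sd,
                              keep_history)
        if best is None or model.log_likelihood > best.log_likelihood:
            best = model
    assert best is not None
    occupancy = _state_occupancy(best, obs)
    sep = np.diff(np.sort(best.means))
    # near-duplicate: adjacent means closer than half the pooled width
    widths = 0.5 * (best.sds[:-1] + best.sds[1:])
    best.degenerate = bool(
        (occupancy < 1.0).any()
        or (len(sep) > 0 and (sep < 0.5 * widths).any())
    )
    return best


def _train_single(obs, means, sds, max_iter, tol, min_sd, keep_history) -> HmmModel:
    n_states = len(means)
    startprob = np.full(n_states, 1.0 / n_states)
    transmat = np.full((n_states, n_states), 0.1 / max(n_states - 1, 1))
    np.fill_diagonal(transmat, 0.9)
    means = means.astype(float).copy()
    sds = np.clip(sds.astype(float).copy(), min_sd, None)

    history = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        loglik, gamma, xi_sum = _hmmkern.baum_welch_estep(
            obs, startprob, transmat, means, sds
        )
        history.append(loglik)
        if abs(loglik - prev) < tol:
            converged = True
            break
        prev = loglik
        # M-step
        startprob = gamma[0] / gamma[0].sum()
        denom = xi_sum.sum(axis=1, keepdims=True)
        transmat = np.where(denom > 0, xi_sum / np.where(denom > 0, denom, 1.0),
                            np.eye(n_states)[: n_states])
        transmat = transmat / transmat.sum(axis=1, keepdims=True)
        occ = gamma.sum(axis=0)
        means = gamma.T @ obs / np.where(occ > 0, occ, 1.0)
        var = (gamma * (obs[:, None] - means[None, :]) ** 2).sum(axis=0)
        sds = np.sqrt(var / np.where(occ > 0, occ, 1.0))
        sds = np.clip(sds, min_sd, None)

    final_loglik = float(
        _hmmkern.forward_loglik(obs, startprob, transmat, means, sds)
    )
    order = np.argsort(means)
    return HmmModel(
        n_states=n_states,
        startprob=startprob[order],
        transmat=transmat[np.ix_(order, order)],
        means=means[order],
        sds=sds[order],
        log_likelihood=final_loglik,
        n_iterations=it,
        converged=converged,
        loglik_history=np.array(history) if keep_history else None,
    )


def _state_occupancy(model: HmmModel, obs: np.ndarray) -> np.ndarray:
    _, gamma, _ = _hmmkern.baum_welch_estep(
        obs, model.startprob, model.transmat, model.means, model.sds
    )
    return gamma.sum(axis=0)


def decode_path(model: HmmModel, trace) -> StatePath:
    """Viterbi most-likely state path with tabulated transitions.

    Transitions are recorded as ``(time_s, from-state mean E, to-state
    mean E)`` at every state change of the decoded path.
    """
    obs = _extract_obs(trace)
    frame_time = trace.frame_time if isinstance(trace, FretTrace) else 1.0
    path, logp = _hmmkern.viterbi(obs, model.startprob, model.transmat,
                                  model.means, model.sds)
    _, gamma, _ = _hmmkern.baum_welch_estep(
        obs, model.startprob, model.transmat, model.means, model.sds
    )
    transitions = []
    changes = np.flatnonzero(np.diff(path) != 0)
    for t in changes:
        transitions.append(
            (float((t + 1) * frame_time),
             float(model.means[path[t]]),
             float(model.means[path[t + 1]]))
        )
    return StatePath(
        states=path,
        posteriors=gamma,
        log_probability=float(logp),
        frame_time=frame_time,
        state_means=model.means,
        transitions=transitions,
    )


def select_n_states(
    trace,
    candidates=(1, 2, 3, 4),
    seed: int = 0,
    n_restarts: int = 3,
    max_iter: int = 200,
    tolerance: float = 0.0,
) -> int:
    """Smallest state count whose BIC is within ``tolerance`` of the best."""
    obs = _extract_obs(trace)
    bics = {}
    for n in sorted(candidates):
        if n == 1:
            loglik = gaussian_loglik(obs)
            bics[n] = -2.0 * loglik + 2 * np.log(len(obs))
        else:
            if len(obs) < 10 * n:
                continue
            model = train_hmm(obs, n_states=n, seed=seed, n_restarts=n_restarts,
                              max_iter=max_iter)
            bics[n] = model.bic(len(obs))
    best = min(bics.values())
    for n in sorted(bics):
        if bics[n] <= best + tolerance:
            return n
    raise RuntimeError("unreachable")


def classify_static_dynamic(
    fret_trace: FretTrace,
    margin: float = 0.0,
    min_frames: int = 20,
    min_dwell: int = 2,
    seed: int = 0,
    n_states: int = 3,
    n_restarts: int = 3,
    max_iter: int = 200,
) -> tuple[str, float]:
    """Automated static/dynamic trace classification.

    A trace is dynamic iff (a) a ``n_states``-state HMM improves the BIC
    over a one-state Gaussian by more than ``margin``, and (b) its decoded
    path contains at least one transition whose flanking dwells both last
    at least ``min_dwell`` frames.  Returns ``(label, score)`` where the
    score is the BIC improvement; traces with too short an analysis window
    are labeled ``"unassigned"``.
    """
    obs = fret_trace.windowed
    if len(obs) < max(min_frames, 10 * n_states):
        return "unassigned", float("nan")
    bic1 = -2.0 * gaussian_loglik(obs) + 2 * np.log(len(obs))
    model = train_hmm(obs, n_states=n_states, seed=seed,
                      n_restarts=n_restarts, max_iter=max_iter)
    bic_n = model.bic(len(obs))
    score = bic1 - bic_n
    if score <= margin:
        return "static", score
    path = decode_path(model, fret_trace).states
    if not _has_substantial_transition(path, min_dwell):
        return "static", score
    return "dynamic", score


def _has_substantial_transition(path: np.ndarray, min_dwell: int) -> bool:
    changes = np.flatnonzero(np.diff(path) != 0)
    if len(changes) == 0:
        return False
    bounds = np.concatenate([[-1], changes, [len(path) - 1]])
    dwells = np.diff(bounds)  # frames per dwell, in order
    for k in range(len(changes)):
        if dwells[k] >= min_dwell and dwells[k + 1] >= min_dwell:
            return True
    return False
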