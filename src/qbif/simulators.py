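"""Simulated listeners, experiment runners and error metrics.

Simulated listeners respond through the classical asymmetric transfer
function p = (1 - 10**(-SII*P/Q))**N — deliberately *not* the logistic
link the estimator assumes — so every simulation also probes robustness of
the procedure to link-function misspecification.  Listener parameters are
drawn per listener: weights are uniform draws normalized to sum to 1,
P = 1, Q ~ U(0.2, 0.5), N ~ U(2, 12).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import inference
from .adaptive import run_qbif
from .config import SessionConfig
from .errors import InvalidArgumentError
from .rng import child_rng, child_seed
from .sii_core import (
    BandGrid,
    SpectralWeights,
    StimulusSpec,
    compute_sii,
    traditional_link,
)
from .strategies import ScheduleConfig, compound_schedule, random_schedule

__all__ = [
    "SimulatedListener",
    "ErrorCurve",
    "StrategyOutcome",
    "sample_listener",
    "respond",
    "normalized_rmse",
    "run_strategy_experiment",
    "nband_sweep",
    "trials_to_criterion",
]

Q_RANGE = (0.2, 0.5)
N_RANGE = (2.0, 12.0)


@dataclass
class SimulatedListener:
    """Ground-truth weights plus the (P, Q, N) transfer function used to
    emit Bernoulli responses."""

    weights: SpectralWeights
    P: float
    Q: float
    N: float
    rng: np.random.Generator

    def prob_correct(self, stimulus: StimulusSpec) -> float:
        sii = compute_sii(self.weights, stimulus)
        return traditional_link(sii, self.P, self.Q, self.N)


@dataclass(frozen=True)
class ErrorCurve:
    """Across-listener mean and SD of the normalized RMS weight error at a
    series of trial-count checkpoints."""

    trial_counts: tuple[int, ...]
    mean_nrmse: tuple[float, ...]
    sd_nrmse: tuple[float, ...]
    n_listeners: int

    def __post_init__(self):
        if not (len(self.trial_counts) == len(self.mean_nrmse) == len(self.sd_nrmse)):
            raise InvalidArgumentError("curve fields must have equal lengths")


@dataclass(frozen=True)
class StrategyOutcome:
    """One strategy's simulation outcome: the error curve plus the
    across-listener mean and SD of per-listener percent-correct."""

    curve: ErrorCurve
    score_mean: float  # percent
    score_sd: float  # percent
    per_listener_scores: tuple[float, ...]  # percent


def sample_listener(grid: BandGrid, rng: np.random.Generator) -> SimulatedListener:
    """Draw one simulated listener: weights = u / sum(u) with u_i ~ U(0,1),
    Q ~ U(0.2, 0.5), N ~ U(2, 12), P = 1."""
    u = rng.uniform(0.0, 1.0, size=grid.n_band)
    weights = SpectralWeights(tuple(u / u.sum()))
    q = rng.uniform(*Q_RANGE)
    n = rng.uniform(*N_RANGE)
    return SimulatedListener(weights=weights, P=1.0, Q=q, N=n, rng=rng)


def respond(listener: SimulatedListener, stimulus: StimulusSpec) -> bool:
    """Bernoulli response through the listener's transfer function."""
    return bool(listener.rng.random() < listener.prob_correct(stimulus))


def normalized_rmse(estimated: SpectralWeights, truth: SpectralWeights, n_band: int) -> float:
    """RMS weight error rescaled by n_band/6 so grids with different band
    counts are compared on a per-octave (6-octave-span) basis."""
    if len(estimated) != len(truth):
        raise InvalidArgumentError("weight vectors differ in length")
    diff = estimated.asarray() - truth.asarray()
    return float(np.sqrt(np.mean(diff**2)) * (n_band / 6.0))


def _checkpoints(n_trials: int, step: int) -> list[int]:
    return list(range(step, n_trials + 1, step))


def _nrmse_from_coefs(coef_rows, truth: SpectralWeights, n_band: int) -> list[float]:
    out = []
    for row in coef_rows:
        if not np.all(np.isfinite(row)):
            out.append(np.nan)
            continue
        try:
            w = SpectralWeights.from_raw(np.clip(row[:-1], 0.0, None))
            out.append(normalized_rmse(w, truth, n_band))
        except InvalidArgumentError:
            out.append(np.nan)
    return out


def run_strategy_experiment(
    strategy: str,
    n_listeners: int,
    n_trials: int = 500,
    checkpoint_step: int = 10,
    seed: int = 0,
    mode: str = "fisher",
    n_band: int = 6,
    ridge: float = inference.DEFAULT_RIDGE,
) -> StrategyOutcome:
    """Simulate one sampling strategy across a panel of listeners.

    Per listener: generate the trial stream under ``strategy`` (qbif runs
    the full adaptive session; compound/random present their fixed in-quiet
    schedules), fit the logistic model at every checkpoint, convert the
    coefficients to weights, and score the normalized RMS error against the
    listener's true weights.  Checkpoint fit failures are recorded as
    missing, not fatal.
    """
    if n_listeners < 1:
        raise InvalidArgumentError("need at least one listener")
    if strategy not in ("qbif", "compound", "random"):
        raise InvalidArgumentError(f"unknown strategy {strategy!r}")
    grid = BandGrid.octave(n_band)
    checkpoints = _checkpoints(n_trials, checkpoint_step)
    nrmse = np.full((n_listeners, len(checkpoints)), np.nan)
    scores = np.empty(n_listeners)

    for j in range(n_listeners):
        listener = sample_listener(grid, child_rng(seed, f"{strategy}-listener-{j}"))
        listener.rng = child_rng(seed, f"{strategy}-responses-{j}")
        if strategy == "qbif":
            cfg = SessionConfig(
                center_frequencies_hz=grid.center_frequencies_hz,
                presented_range=(2, n_band - 1),
                trial_budget=n_trials,
                optimizer_mode=mode,
                ridge=ridge,
                seed=child_seed(seed, f"{strategy}-session-{j}"),
            )
            result = run_qbif(lambda s: respond(listener, s), cfg)
            scores[j] = result.proportion_correct * 100.0
            rows = [result.interim_coef[t - 1] for t in checkpoints]
            nrmse[j] = _nrmse_from_coefs(rows, listener.weights, n_band)
        else:
            sched_cfg = ScheduleConfig(
                n_band=n_band,
                total_trials=n_trials,
                rng_seed=child_seed(seed, f"{strategy}-schedule-{j}"),
            )
            schedule = (
                compound_schedule(sched_cfg)
                if strategy == "compound"
                else random_schedule(sched_cfg)
            )
            responses = np.array([respond(listener, s) for s in schedule])
            scores[j] = responses.mean() * 100.0
            X = inference.design_matrix(schedule)
            warm = None
            coef_rows = []
            for t in checkpoints:
                try:
                    st = inference.fit_posterior_xy(
                        X[:t], responses[:t].astype(float), ridge=ridge, x0=warm
                    )
                    warm = st.coef_mean
                    coef_rows.append(st.coef_mean)
                except inference.ConvergenceError:
                    coef_rows.append(np.full(n_band + 1, np.nan))
            nrmse[j] = _nrmse_from_coefs(coef_rows, listener.weights, n_band)

    sd = (
        np.nanstd(nrmse, axis=0, ddof=1)
        if n_listeners > 1
        else np.zeros(len(checkpoints))
    )
    curve = ErrorCurve(
        trial_counts=tuple(checkpoints),
        mean_nrmse=tuple(np.nanmean(nrmse, axis=0)),
        sd_nrmse=tuple(sd),
        n_listeners=n_listeners,
    )
    return StrategyOutcome(
        curve=curve,
        score_mean=float(scores.mean()),
        score_sd=float(scores.std(ddof=1)) if n_listeners > 1 else 0.0,
        per_listener_scores=tuple(scores),
    )


def nband_sweep(
    n_band_values,
    n_listeners: int,
    n_trials: int = 500,
    seed: int = 0,
    checkpoint_step: int = 10,
    mode: str = "fisher",
) -> dict[int, ErrorCurve]:
    """Run the adaptive procedure at several band-grid sizes and collect
    the normalized-error curves (pools generalize to 2..n_band-1 presented
    bands on octave grids starting at 250 Hz)."""
    out: dict[int, ErrorCurve] = {}
    for nb in n_band_values:
        if nb < 2:
            raise InvalidArgumentError("n_band must be >= 2")
        outcome = run_strategy_experiment(
            "qbif",
            n_listeners,
            n_trials,
            checkpoint_step=checkpoint_step,
            seed=seed,
            mode=mode,
            n_band=int(nb),
        )
        out[int(nb)] = outcome.curve
    return out


def trials_to_criterion(curve: ErrorCurve, threshold: float = 0.05) -> float:
    """Trial count at which the across-listener mean error curve first
    crosses ``threshold``, linearly interpolated between checkpoints.
    NaN if the curve never crosses."""
    t = np.asarray(curve.trial_counts, dtype=float)
    m = np.asarray(curve.mean_nrmse, dtype=float)
    below = np.flatnonzero(m <= threshold)
    if len(below) == 0:
        return float("nan")
    i = below[0]
    if i == 0:
        return float(t[0])
    # linear interpolation between the bracketing checkpoints
    t0, t1, m0, m1 = t[i - 1], t[i], m[i - 1], m[i]
    if m0 == m1:
        return float(t1)
    return float(t0 + (m0 - threshold) / (m0 - m1) * (t1 - t0))
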