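"""The qBIF engine.

A session has two phases.  A short *training* phase presents easy stimuli
(maximum TMR, few bands omitted) in a staged schedule so that the first
logistic fit is well posed — "training" trains the algorithm, not the
listener.  The *adaptive* phase then alternates: refit the posterior on
all responses so far, pick from the stimulus pool the candidate whose
expected post-trial posterior entropy (log-determinant of the coefficient
covariance) is smallest, present it, record the response.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .config import SessionConfig
from .errors import InvalidArgumentError, SessionAbortedError
from . import inference
from .inference import PosteriorState, TrialRecord, design_matrix, design_row
from .rng import child_rng
from .sii_core import BandGrid, LinkParams, SpectralWeights, StimulusSpec

__all__ = [
    "StimulusPool",
    "TrainingState",
    "SessionResult",
    "build_pool",
    "training_next",
    "select_next",
    "run_qbif",
    "DEFAULT_TMR_GRID_DB",
    "DEFAULT_PRESENTED_RANGE",
]

DEFAULT_TMR_GRID_DB = (-5.0, 0.0, 5.0, 10.0, 15.0)
DEFAULT_PRESENTED_RANGE = (2, 5)

#: Tolerance within which pool criteria count as tied (broken at random).
TIE_TOL = 1e-12


@dataclass(frozen=True)
class StimulusPool:
    """All candidate stimuli: the Cartesian product of a TMR grid and every
    band mask whose presented-band count lies in ``presented_range``."""

    stimuli: tuple[StimulusSpec, ...]
    tmr_grid_db: tuple[float, ...]
    presented_range: tuple[int, int]

    def __len__(self) -> int:
        return len(self.stimuli)

    @property
    def masks(self) -> tuple[tuple[bool, ...], ...]:
        seen = dict.fromkeys(s.band_mask for s in self.stimuli)
        return tuple(seen)

    def design_matrix(self) -> np.ndarray:
        return design_matrix(self.stimuli)


def _masks_with_counts(n_band: int, counts) -> list[tuple[bool, ...]]:
    masks = []
    for k in counts:
        for idx in itertools.combinations(range(n_band), k):
            mask = [False] * n_band
            for i in idx:
                mask[i] = True
            masks.append(tuple(mask))
    # lexicographic over the 0/1 tuples, deterministic
    return sorted(masks)


def build_pool(
    grid: BandGrid,
    tmr_grid_db=DEFAULT_TMR_GRID_DB,
    presented_range=DEFAULT_PRESENTED_RANGE,
) -> StimulusPool:
    """Enumerate the candidate pool (TMR-major, mask lexicographic).

    Defaults give the 6-band pool: TMRs -5..15 dB in 5-dB steps and 2-5
    presented bands, i.e. 56 masks and 280 stimuli.
    """
    tmrs = tuple(float(t) for t in tmr_grid_db)
    lo, hi = int(presented_range[0]), int(presented_range[1])
    if len(tmrs) == 0:
        raise InvalidArgumentError("TMR grid is empty")
    if not (1 <= lo <= hi <= grid.n_band):
        raise InvalidArgumentError(
            f"presented range ({lo}, {hi}) outside [1, {grid.n_band}]"
        )
    masks = _masks_with_counts(grid.n_band, range(lo, hi + 1))
    stimuli = tuple(
        StimulusSpec(tmr_db=t, band_mask=m) for t in tmrs for m in masks
    )
    return StimulusPool(stimuli=stimuli, tmr_grid_db=tmrs, presented_range=(lo, hi))


@dataclass
class TrainingState:
    """Progress through the staged training schedule.

    ``phase`` is the current omitted-band count; within each phase every
    mask with exactly that many omitted bands appears once, in random
    order.  After each response the stopping rules are evaluated:
    (a) more than 10 trials and cumulative score below 65%, or
    (b) more than 50 trials.  Phases past ``max_omitted`` (set by the pool's
    minimum presented count) end training by exhaustion.
    """

    grid: BandGrid
    tmr_db: float = 15.0
    max_omitted: int = 4
    phase: int = 1
    pending: list[tuple[bool, ...]] = field(default_factory=list)
    n_training_trials: int = 0
    n_correct: int = 0
    _phase_filled: bool = False

    def record(self, correct: bool) -> None:
        self.n_training_trials += 1
        self.n_correct += bool(correct)

    @property
    def score(self) -> float:
        if self.n_training_trials == 0:
            return 1.0
        return self.n_correct / self.n_training_trials

    @property
    def finished(self) -> bool:
        n = self.n_training_trials
        if n > 10 and self.score < 0.65:
            return True
        if n > 50:
            return True
        return self._phase_filled and not self.pending and self.phase >= self.max_omitted

    def _refill(self, rng: np.random.Generator) -> None:
        if self._phase_filled:
            self.phase += 1
        if self.phase > self.max_omitted:
            return
        masks = _masks_with_counts(self.grid.n_band, [self.grid.n_band - self.phase])
        order = rng.permutation(len(masks))
        self.pending = [masks[i] for i in order]
        self._phase_filled = True


def training_next(state: TrainingState, rng: np.random.Generator):
    """Next training stimulus, or ``None`` once a stopping rule has fired
    or the schedule is exhausted.  Stimuli are at the training TMR with
    exactly ``state.phase`` bands omitted."""
    if state.finished:
        return None
    if not state.pending:
        state._refill(rng)
        if not state.pending:
            return None
    mask = state.pending.pop(0)
    return StimulusSpec(tmr_db=state.tmr_db, band_mask=mask)


def _fisher_criteria(state: PosteriorState, X: np.ndarray) -> np.ndarray:
    """Vectorized fisher-mode expected log-determinants for every pool row."""
    p = expit(X @ state.coef_mean)
    quad = np.einsum("ij,jk,ik->i", X, state.coef_cov, X)
    return inference.log_det_cov(state) - np.log1p(p * (1.0 - p) * quad)


def select_next(
    state: PosteriorState,
    pool: StimulusPool,
    records,
    mode: str = "refit",
    rng: np.random.Generator | None = None,
    ridge: float = inference.DEFAULT_RIDGE,
    _pool_design: np.ndarray | None = None,
) -> StimulusSpec:
    """Pool stimulus minimizing the expected post-trial posterior entropy.

    Ties within 1e-12 are broken uniformly at random with the session rng.
    """
    if len(pool) == 0:
        raise InvalidArgumentError("empty stimulus pool")
    if mode == "fisher":
        X = pool.design_matrix() if _pool_design is None else _pool_design
        crit = _fisher_criteria(state, X)
    else:
        crit = np.array(
            [
                inference.expected_post_logdet(state, records, s, mode=mode, ridge=ridge)
                for s in pool.stimuli
            ]
        )
    best = crit.min()
    tied = np.flatnonzero(crit <= best + TIE_TOL)
    if len(tied) == 1:
        return pool.stimuli[tied[0]]
    rng = np.random.default_rng() if rng is None else rng
    return pool.stimuli[int(rng.choice(tied))]


@dataclass
class SessionResult:
    """Everything a qBIF run produced."""

    records: list[TrialRecord]
    phases: list[str]  # "training" | "adaptive", per trial
    interim_coef: np.ndarray  # (n_trials, n_band+1)
    interim_logdet: np.ndarray  # (n_trials,)
    weights: SpectralWeights | None
    link: LinkParams | None
    posterior: PosteriorState | None
    config: SessionConfig
    seed: int

    @property
    def n_trials(self) -> int:
        return len(self.records)

    @property
    def n_training(self) -> int:
        return sum(p == "training" for p in self.phases)

    @property
    def n_adaptive(self) -> int:
        return len(self.records) - self.n_training

    @property
    def proportion_correct(self) -> float:
        return float(np.mean([r.correct for r in self.records]))


def run_qbif(listener, config: SessionConfig) -> SessionResult:
    """Run a full qBIF session against a response callback.

    ``listener`` maps a :class:`StimulusSpec` to a boolean response.  The
    trial budget counts training and adaptive trials together.  The
    posterior is refit after every trial (interim estimates are logged for
    every trial); stimulus selection starts once training finishes.
    """
    grid = config.band_grid()
    pool = build_pool(grid, config.tmr_grid_db, config.presented_range)
    pool_design = pool.design_matrix()
    train_rng = child_rng(config.seed, "training-shuffle")
    tie_rng = child_rng(config.seed, "tie-break")
    max_omitted = grid.n_band - pool.presented_range[0]
    tstate = TrainingState(
        grid=grid, tmr_db=max(pool.tmr_grid_db), max_omitted=max_omitted
    )

    d = grid.n_band + 1
    budget = config.trial_budget
    X = np.empty((budget, d))
    y = np.empty(budget)
    records: list[TrialRecord] = []
    phases: list[str] = []
    coefs = np.full((budget, d), np.nan)
    logdets = np.full(budget, np.nan)
    post: PosteriorState | None = None

    def _present(stim: StimulusSpec) -> bool:
        try:
            return bool(listener(stim))
        except Exception as exc:
            partial = _result(None)
            raise SessionAbortedError(
                f"response callback raised at trial {len(records) + 1}: {exc}",
                partial_result=partial,
            ) from exc

    def _refit(warm):
        k = len(records)
        return inference.fit_posterior_xy(
            X[:k], y[:k], ridge=config.ridge, x0=warm
        )

    def _log(k, state):
        coefs[k] = state.coef_mean
        logdets[k] = inference.log_det_cov(state)

    def _result(state):
        weights = link = None
        if state is not None:
            try:
                weights, link = inference.to_sii_params(state)
            except Exception:
                pass
        k = len(records)
        return SessionResult(
            records=records,
            phases=phases,
            interim_coef=coefs[:k].copy(),
            interim_logdet=logdets[:k].copy(),
            weights=weights,
            link=link,
            posterior=state,
            config=config,
            seed=config.seed,
        )

    # --- training phase ---
    while len(records) < budget:
        stim = training_next(tstate, train_rng)
        if stim is None:
            break
        resp = _present(stim)
        k = len(records)
        X[k] = design_row(stim)
        y[k] = resp
        records.append(TrialRecord(stimulus=stim, correct=resp))
        phases.append("training")
        tstate.record(resp)
        post = _refit(None if post is None else post.coef_mean)
        _log(k, post)

    # --- adaptive phase ---
    while len(records) < budget:
        stim = select_next(
            post,
            pool,
            records,
            mode=config.optimizer_mode,
            rng=tie_rng,
            ridge=config.ridge,
            _pool_design=pool_design,
        )
        resp = _present(stim)
        k = len(records)
        X[k] = design_row(stim)
        y[k] = resp
        records.append(TrialRecord(stimulus=stim, correct=resp))
        phases.append("adaptive")
        post = _refit(post.coef_mean)
        _log(k, post)

    return _result(post)
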