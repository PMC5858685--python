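"""Posterior inference over the SII parameters.

The logistic link composed with the weighted SII is nonlinear in
(weights, SRT, beta) because beta multiplies every weight.  Writing

    c_i = 30 * beta * w_i        (per-band slopes on audibility)
    c_0 = -beta * (15 + SRT)     (intercept)

turns the model into an ordinary logistic regression on the per-band
audibilities: with design row x = (mask_1*A_1, ..., mask_n*A_n, 1),

    P(correct) = sigmoid(c . x).

This is the only formulation under which trial-by-trial refitting is a
plain (here ridge-penalized) logistic regression, and the Gaussian
approximation to the posterior — mean = penalized MLE, covariance =
inverse penalized observed information — supports the entropy-based
stimulus search.  The inversion back to (weights, SRT, beta) follows from
sum_i w_i = 1.

Interim coefficients may go negative while data are scarce; only the
*reported* weights are clipped at zero and renormalized, since
constraining the fit would break the Gaussian entropy proxy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve
from scipy.special import expit

from .errors import (
    ConvergenceError,
    DegenerateFitError,
    InvalidArgumentError,
    NumericalStateError,
)
from .sii_core import LinkParams, SpectralWeights, StimulusSpec, band_audibility

__all__ = [
    "TrialRecord",
    "PosteriorState",
    "design_row",
    "design_matrix",
    "fit_posterior",
    "fit_posterior_xy",
    "predict_prob",
    "to_sii_params",
    "log_det_cov",
    "expected_post_logdet",
    "DEFAULT_RIDGE",
]

#: Default ridge penalty on all coefficients (including the intercept);
#: keeps early-session fits finite under complete separation.
DEFAULT_RIDGE = 0.01

MAX_ITER = 100
TOL = 1e-8


@dataclass(frozen=True)
class TrialRecord:
    """One presented stimulus and the binary response it drew."""

    stimulus: StimulusSpec
    correct: bool


@dataclass(frozen=True)
class PosteriorState:
    """Gaussian posterior over the regression coefficients.

    ``coef_mean`` holds the per-band slopes c_1..c_n followed by the
    intercept c_0; ``coef_cov`` is the inverse penalized observed
    information at the optimum.
    """

    coef_mean: np.ndarray
    coef_cov: np.ndarray
    n_trials_fit: int

    @property
    def n_band(self) -> int:
        return len(self.coef_mean) - 1


def design_row(stimulus: StimulusSpec) -> np.ndarray:
    """Predictor row for one stimulus: per-band audibility where the band
    is presented, zero where omitted, then a constant 1 for the intercept."""
    a = 1.0 if stimulus.in_quiet else band_audibility(stimulus.tmr_db)
    row = np.empty(stimulus.n_band + 1)
    row[:-1] = np.asarray(stimulus.band_mask, dtype=float) * a
    row[-1] = 1.0
    return row


def design_matrix(stimuli: Iterable[StimulusSpec]) -> np.ndarray:
    return np.array([design_row(s) for s in stimuli], dtype=float)


def _neg_penalized_loglik(X, y, c, ridge):
    eta = X @ c
    # log(1 + e^eta) - y*eta, computed stably
    return float(np.sum(np.logaddexp(0.0, eta) - y * eta) + 0.5 * ridge * c @ c)


def fit_posterior_xy(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = DEFAULT_RIDGE,
    x0: np.ndarray | None = None,
    max_iter: int = MAX_ITER,
    tol: float = TOL,
) -> PosteriorState:
    """Damped-Newton fit of the ridge-penalized logistic regression.

    Maximizes the Bernoulli log-likelihood minus (ridge/2)*||c||^2; the
    covariance is the inverse of the penalized observed information at the
    optimum.  ``x0`` warm-starts the iteration (used by the trial-by-trial
    refits and the one-step-ahead search).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y) or len(X) == 0:
        raise InvalidArgumentError("need a non-empty design matrix matching y")
    if ridge < 0:
        raise InvalidArgumentError("ridge must be >= 0")
    d = X.shape[1]
    c = np.zeros(d) if x0 is None else np.array(x0, dtype=float)
    obj = _neg_penalized_loglik(X, y, c, ridge)
    H = None
    converged = False
    for _ in range(max_iter):
        p = expit(X @ c)
        w = p * (1.0 - p)
        g = X.T @ (y - p) - ridge * c
        H = (X * w[:, None]).T @ X
        H[np.diag_indices(d)] += ridge
        try:
            step = solve(H, g, assume_a="pos")
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        # backtracking keeps Newton monotone under near-separation
        t = 1.0
        for _ in range(40):
            c_new = c + t * step
            obj_new = _neg_penalized_loglik(X, y, c_new, ridge)
            if obj_new <= obj + 1e-14:
                break
            t *= 0.5
        delta = np.max(np.abs(c_new - c))
        c, obj = c_new, obj_new
        if delta < tol:
            converged = True
            break
    # observed information at the final iterate
    p = expit(X @ c)
    w = p * (1.0 - p)
    H = (X * w[:, None]).T @ X
    H[np.diag_indices(d)] += ridge
    try:
        cho = cho_factor(H)
        cov = cho_solve(cho, np.eye(d))
    except np.linalg.LinAlgError as exc:
        raise NumericalStateError(f"information matrix not positive definite: {exc}")
    cov = 0.5 * (cov + cov.T)
    state = PosteriorState(coef_mean=c, coef_cov=cov, n_trials_fit=len(y))
    if not converged:
        raise ConvergenceError(
            f"logistic fit did not converge in {max_iter} iterations", last_state=state
        )
    return state


def fit_posterior(
    records: Sequence[TrialRecord],
    ridge: float = DEFAULT_RIDGE,
    x0: np.ndarray | None = None,
    max_iter: int = MAX_ITER,
    tol: float = TOL,
) -> PosteriorState:
    """Fit the penalized logistic regression to a list of trial records."""
    if len(records) == 0:
        raise InvalidArgumentError("need at least one trial record")
    X = design_matrix(r.stimulus for r in records)
    y = np.array([r.correct for r in records], dtype=float)
    return fit_posterior_xy(X, y, ridge=ridge, x0=x0, max_iter=max_iter, tol=tol)


def predict_prob(state: PosteriorState, stimulus: StimulusSpec) -> float:
    """Predicted probability of a correct response at the posterior mean."""
    return float(expit(design_row(stimulus) @ state.coef_mean))


def to_sii_params(state: PosteriorState) -> tuple[SpectralWeights, LinkParams]:
    """Invert the coefficient parameterization back to SII parameters.

    beta uses the raw slope sum (Sigma c_i = 30*beta since the weights sum
    to 1); reported weights clip negatives at zero and renormalize; the SRT
    follows from the intercept.
    """
    c = state.coef_mean[:-1]
    c0 = state.coef_mean[-1]
    pos = np.clip(c, 0.0, None)
    if pos.sum() <= 0:
        raise DegenerateFitError("all per-band slopes non-positive")
    beta = float(c.sum()) / 30.0
    if beta <= 0:
        raise DegenerateFitError("raw slope sum non-positive; beta undefined")
    weights = SpectralWeights(tuple(pos / pos.sum()))
    srt = -float(c0) / beta - 15.0
    return weights, LinkParams(srt_db=srt, beta=beta)


def log_det_cov(state: PosteriorState) -> float:
    """ln|cov| via Cholesky; the posterior-entropy proxy (entropy of a
    Gaussian is affine in the log-determinant of its covariance)."""
    try:
        chol = np.linalg.cholesky(state.coef_cov)
    except np.linalg.LinAlgError as exc:
        raise NumericalStateError(f"covariance not positive definite: {exc}")
    return float(2.0 * np.sum(np.log(np.diag(chol))))


def expected_post_logdet(
    state: PosteriorState,
    records: Sequence[TrialRecord],
    candidate: StimulusSpec,
    mode: str = "refit",
    ridge: float = DEFAULT_RIDGE,
) -> float:
    """Expected post-trial ln|cov| if ``candidate`` were presented next.

    The expectation runs over the two possible responses, weighted by the
    current-state predicted probability p_hat.

    mode="refit"  — refit the regression under each hypothetical outcome
                    and average the two log-determinants (the literal
                    one-step-ahead criterion).
    mode="fisher" — outcome-independent rank-one information update via the
                    matrix determinant lemma:
                    ln|cov| - ln(1 + p_hat*(1-p_hat) * x' cov x).
                    Fast approximation used in bulk simulation.
    """
    x = design_row(candidate)
    p_hat = float(expit(x @ state.coef_mean))
    if mode == "fisher":
        quad = float(x @ state.coef_cov @ x)
        return log_det_cov(state) - float(np.log1p(p_hat * (1.0 - p_hat) * quad))
    if mode != "refit":
        raise InvalidArgumentError(f"unknown mode {mode!r}")
    X = design_matrix([r.stimulus for r in records] + [candidate])
    y = np.array([r.correct for r in records] + [True], dtype=float)
    st1 = fit_posterior_xy(X, y, ridge=ridge, x0=state.coef_mean)
    ld1 = log_det_cov(st1)
    y[-1] = 0.0
    st0 = fit_posterior_xy(X, y, ridge=ridge, x0=state.coef_mean)
    ld0 = log_det_cov(st0)
    return p_hat * ld1 + (1.0 - p_hat) * ld0
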