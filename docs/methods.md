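# Methods

## Model

The package fits an individualized Speech Intelligibility Index (SII)
model to binary keyword-recognition responses.  A stimulus is a broadband
target-to-masker ratio (TMR, dB) plus a presence mask over `n_band`
octave bands (default centers 250, 500, 1000, 2000, 4000, 8000 Hz).  Band
audibility is `A = (clamp(TMR′, −15, 15) + 15)/30`; every presented band
carries the broadband mixing TMR (target and masker are mixed at a single
TMR before filtering), omitted bands contribute zero, and in-quiet
presentations force `A = 1` in presented bands.  The SII is
`Σᵢ wᵢ·maskᵢ·A` with spectral weights `wᵢ ≥ 0`, `Σwᵢ = 1`, and response
probability follows the logistic link
`p = σ(β·(30·SII − 15 − SRT))`.

### Reparameterization

`β` multiplies every weight, so the natural parameters are not a GLM.
With `cᵢ = 30·β·wᵢ` and intercept `c₀ = −β·(15 + SRT)` the model becomes
a logistic regression on the per-band audibility row
`x = (mask₁·A, …, mask_n·A, 1)`.  Inversion uses `Σwᵢ = 1`:
`β = Σcᵢ/30`, `SRT = −c₀/β − 15`, reported weights `max(cᵢ,0)/Σmax(cⱼ,0)`.
Interim coefficients may go negative while data are scarce; the fit is
deliberately unconstrained (a constrained fit would invalidate the
Gaussian posterior approximation that the entropy search relies on), and
only reported weights are clipped and renormalized.

### Fitting

`fit_posterior` maximizes the Bernoulli log-likelihood minus
`(ridge/2)·‖c‖²` by damped Newton iteration (backtracking line search on
the penalized objective; cap 100 iterations, convergence tolerance 1e-8
on the coefficient change).  The posterior is the Gaussian/Laplace
approximation: mean at the penalized optimum, covariance the inverse
penalized observed information there.  The ridge default is 0.01 on all
coefficients including the intercept — small enough to leave a 300-trial
fit essentially unpenalized, large enough to keep early-session fits
finite under complete separation (the first trials are easy and often all
correct).  Covariance log-determinants go through a Cholesky
factorization.

### Stimulus selection

The candidate pool is the Cartesian product of the TMR grid (−5…15 dB,
5-dB steps) and all masks with 2–5 presented bands: 56 masks, 280
stimuli.  After each trial the engine picks the candidate minimizing the
expected post-trial posterior entropy, `E[ln|P_{k+1}|]`, the expectation
running over the two possible responses weighted by the current predicted
probability `p̂`.  Two evaluation modes:

* `refit` (default for live sessions): refit the regression under each
  hypothetical outcome and average the two log-determinants — the literal
  one-step-ahead criterion.
* `fisher` (default in bulk simulation): the outcome-independent rank-one
  update `ln|P| − ln(1 + p̂(1−p̂)·xᵀPx)` from the matrix determinant
  lemma.  It matches refit mode within 10% relative reduction for ≥90% of
  the pool on a 200-trial session (asserted in the tests) at a tiny
  fraction of the cost, which is what makes 100-listener panels cheap.

Ties within 1e-12 break uniformly at random from a dedicated stream.

### Training schedule

Selection needs a usable interim fit, so each session opens with staged
"training" trials at the maximum pool TMR (15 dB): every single-band
omission once in random order (6 trials), then every two-band omission
(15), three (20), four (15), reshuffled within each stage.  After every
response the stopping rules are checked exactly as stated: stop when more
than 10 trials have run and the cumulative score is below 65%, or when
more than 50 trials have run.  "Score" is the cumulative proportion
correct over all training trials (the simplest reading; no window).  For
band counts other than six the omission stages extend to
`n_band − min_presented`; small grids (e.g. 4 bands) can exhaust the
schedule before either rule fires, which also ends training.

## Baseline strategies

Both baselines present speech in quiet and never look at responses.

* **Compound**: each band serves as target in turn (band 1…n, cycling).
  Per target, all C(n−1, 2) context pairs appear once in shuffled order,
  each as two consecutive trials — context+target, then context alone.
  500 trials may truncate mid-pair.
* **Random**: shuffled exhaustive passes over all masks with
  2…(n_band−1) presented bands (56 masks for six bands), repeated and
  truncated.

## Simulated listeners

A listener is a weight vector (uniform draws normalized to sum 1) and the
classical asymmetric transfer function `p = (1 − 10^(−SII·P/Q))^N` with
`P = 1`, `Q ~ U(0.2, 0.5)`, `N ~ U(2, 12)`.  Responses are Bernoulli
draws.  Because the generating link is not the logistic link the
estimator assumes, every simulation doubles as a link-misspecification
robustness check — weight recovery reaches mean normalized RMS error
below 0.05 within 250 adaptive trials regardless.

What the generator does **not** emulate: lexical and contextual structure
of real speech materials, attention lapses and learning effects, audibility
limits from hearing thresholds, and any trial-to-trial dependence —
passing simulations therefore demonstrate correctness of the estimation
machinery under the stated stochastic model, not clinical performance.

## Error metrics and experiment runners

Accuracy is the normalized RMS weight error
`sqrt(meanᵢ(ŵᵢ − wᵢ)²) · (n_band/6)`; the factor expresses the error per
octave on the fixed six-octave span so different band counts are
comparable.  `run_strategy_experiment` fits the logistic model at 10-trial
checkpoints (refitting cold for the baselines, reusing the session's
per-trial interim fits for qBIF), converts coefficients to reported
weights, and aggregates mean and SD across listeners; checkpoint fits
whose slopes are all non-positive are recorded as missing.  The
trials-to-criterion summary is where the across-listener mean curve first
crosses 0.05, linearly interpolated between checkpoints.  Panel sizes:
100 listeners per strategy in `scripts/acceptance.py` (≈1 min total,
fisher mode); the test suite uses 50/100/100 and 20 per band count in the
sweep.

## Audio chain

Trial audio is target plus masker scaled to the requested broadband RMS
TMR (a short masker loops with a random circular offset), split by
6th-order-per-edge Butterworth band-passes at `center/√2 … center·√2`
(12th-order band-pass sections, 36 dB/oct per cutoff), and reconstructed
by summing the masked-in bands.  Filters run forward-backward by default
so reconstruction is free of band-dependent group delay (a flag restores
causal single-pass filtering).  One consequence of contiguous octave
filters worth knowing: an omitted band is not silent — the adjacent
bands' skirts are only ~6 dB down at the shared cutoffs after the
zero-phase pass, so broadband energy inside an omitted octave drops by
roughly 17–19 dB integrated over the octave (33–44 dB in its center
third, ~44 dB for a center tone).  Steeper suppression would require
non-contiguous or higher-order designs that no longer reconstruct the
passband flat.

## Reproducibility

Every entry point is deterministic given (config, seed).  A root seed
spawns named child streams (training shuffle, tie-breaks, listener
parameters, listener responses, masker offset) via `SeedSequence` with a
CRC32 key per stream name, so changing how often one component draws
never perturbs another.

## Known limitations

* The asymmetric-link regression variant is a reserved config hook
  (`link:`) and intentionally unimplemented; only the logistic link fits.
* The entropy proxy assumes a Gaussian posterior; rarely (about one
  session in ten, shortly after training) a surprising response shrinks
  the observed information and `ln|P_k|` ticks up before resuming its
  decline.
* Octave resolution cannot represent fine spectral structure in a band
  importance function, and the audio chain's omitted-band suppression is
  bounded by the contiguous filter design as noted above.
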