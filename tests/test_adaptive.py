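"""Pool construction, training schedule, stimulus selection, session loop."""

import numpy as np
import pytest
from scipy.special import expit

from qbif.adaptive import (
    TrainingState,
    build_pool,
    run_qbif,
    select_next,
    training_next,
)
from qbif.config import SessionConfig
from qbif.errors import InvalidArgumentError, SessionAbortedError
from qbif.inference import (
    PosteriorState,
    TrialRecord,
    design_row,
    expected_post_logdet,
    fit_posterior,
)
from qbif.rng import child_rng
from qbif.sii_core import (
    BandGrid,
    LinkParams,
    SpectralWeights,
    StimulusSpec,
    compute_sii,
    logistic_link,
)

GRID = BandGrid()


class TestBuildPool:
    def test_default_pool_counts(self):
        pool = build_pool(GRID)
        assert len(pool) == 280
        assert len(pool.masks) == 56

    def test_four_band_pool(self):
        pool = build_pool(BandGrid.octave(4), presented_range=(2, 3))
        assert len(pool) == 50  # (C(4,2)+C(4,3)) * 5 TMRs

    def test_single_stimulus_pool(self):
        pool = build_pool(GRID, tmr_grid_db=(0.0,), presented_range=(6, 6))
        assert len(pool) == 1
        assert pool.stimuli[0].band_mask == (True,) * 6

    def test_no_duplicates_and_counts_in_range(self):
        pool = build_pool(GRID)
        seen = {(s.tmr_db, s.band_mask) for s in pool.stimuli}
        assert len(seen) == len(pool)
        assert all(2 <= s.n_presented <= 5 for s in pool.stimuli)

    def test_invalid_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            build_pool(GRID, presented_range=(0, 7))
        with pytest.raises(InvalidArgumentError):
            build_pool(GRID, tmr_grid_db=())


class TestTrainingSchedule:
    def test_first_six_omit_each_band_once(self):
        state = TrainingState(grid=GRID, max_omitted=4)
        rng = child_rng(3, "training-shuffle")
        omitted = []
        for _ in range(6):
            stim = training_next(state, rng)
            state.record(True)
            assert stim.tmr_db == 15.0
            assert stim.n_presented == 5
            omitted.append(stim.band_mask.index(False))
        assert sorted(omitted) == [0, 1, 2, 3, 4, 5]

    def test_phase_lengths_six_then_fifteen(self):
        state = TrainingState(grid=GRID, max_omitted=4)
        rng = child_rng(4, "training-shuffle")
        counts = []
        for _ in range(21):
            stim = training_next(state, rng)
            state.record(True)
            counts.append(stim.n_presented)
        assert counts[:6] == [5] * 6  # one band omitted
        assert counts[6:21] == [4] * 15  # two bands omitted

    def test_all_correct_ends_after_trial_51(self):
        state = TrainingState(grid=GRID, max_omitted=4)
        rng = child_rng(5, "training-shuffle")
        n = 0
        while True:
            stim = training_next(state, rng)
            if stim is None:
                break
            n += 1
            state.record(True)
        assert n == 51  # rule (b): n_trials > 50

    def test_low_score_rule_fires_at_trial_11(self):
        # correct on trials 1-7, wrong on 8-11: score 7/11 < 0.65 and 11 > 10
        responses = [True] * 7 + [False] * 4
        state = TrainingState(grid=GRID, max_omitted=4)
        rng = child_rng(6, "training-shuffle")
        n = 0
        for resp in responses:
            stim = training_next(state, rng)
            assert stim is not None
            n += 1
            state.record(resp)
        assert n == 11
        assert training_next(state, rng) is None

    def test_score_rule_needs_more_than_ten_trials(self):
        # equally poor score at trial 10 must NOT stop the schedule
        state = TrainingState(grid=GRID, max_omitted=4)
        rng = child_rng(7, "training-shuffle")
        for resp in [True] * 6 + [False] * 4:
            training_next(state, rng)
            state.record(resp)
        assert training_next(state, rng) is not None


class TestSelectNext:
    @staticmethod
    def fitted_state(seed=21, n=150):
        rng = np.random.default_rng(seed)
        pool = build_pool(GRID)
        coef = np.array([1.0, 0.8, 1.2, 1.0, 0.9, 1.1, -2.4])
        records = []
        for i in rng.integers(len(pool.stimuli), size=n):
            stim = pool.stimuli[i]
            p = expit(design_row(stim) @ coef)
            records.append(TrialRecord(stim, bool(rng.random() < p)))
        return fit_posterior(records), pool, records

    @pytest.mark.parametrize("mode", ["fisher", "refit"])
    def test_matches_brute_force_enumeration(self, mode):
        state, pool, records = self.fitted_state()
        small = pool if mode == "fisher" else build_pool(
            GRID, tmr_grid_db=(0.0, 15.0), presented_range=(5, 5)
        )
        chosen = select_next(state, small, records, mode=mode, rng=np.random.default_rng(0))
        crit = [
            expected_post_logdet(state, records, s, mode=mode) for s in small.stimuli
        ]
        best = min(crit)
        tied = {i for i, c in enumerate(crit) if c <= best + 1e-12}
        assert small.stimuli.index(chosen) in tied

    def test_single_stimulus_pool_returned(self):
        state, _, records = self.fitted_state()
        pool1 = build_pool(GRID, tmr_grid_db=(5.0,), presented_range=(6, 6))
        assert select_next(state, pool1, records, mode="fisher") == pool1.stimuli[0]

    def test_targets_uncertain_band(self):
        """With one band's slope variance inflated 100x the optimizer should
        present that band nearly always."""
        cov = np.eye(7) * 0.01
        cov[2, 2] = 1.0
        state = PosteriorState(np.array([1.0, 1, 1, 1, 1, 1, -2.4]), cov, 100)
        pool = build_pool(GRID)
        hits = 0
        for k in range(100):
            stim = select_next(state, pool, [], mode="fisher", rng=np.random.default_rng(k))
            hits += stim.band_mask[2]
        assert hits >= 95


def logistic_listener(weights, srt, beta, seed):
    truth = SpectralWeights(tuple(weights))
    params = LinkParams(srt, beta)
    rng = np.random.default_rng(seed)

    def respond(stim):
        return bool(rng.random() < logistic_link(compute_sii(truth, stim), params))

    return truth, respond


class TestRunQbif:
    def test_self_consistent_recovery(self):
        w = np.array([0.10, 0.25, 0.25, 0.20, 0.15, 0.05])
        truth, respond = logistic_listener(w, srt=-2.0, beta=0.2, seed=99)
        cfg = SessionConfig(trial_budget=500, optimizer_mode="fisher", seed=12)
        result = run_qbif(respond, cfg)
        rmse = np.sqrt(np.mean((result.weights.asarray() - w) ** 2))
        assert rmse < 0.05

    def test_budget_equal_to_training_gives_no_adaptive_trials(self):
        # a near-perfect listener keeps the training schedule running, so a
        # small budget is consumed entirely by training trials
        _, respond = logistic_listener(np.full(6, 1 / 6), -40.0, 0.5, seed=1)
        cfg = SessionConfig(trial_budget=15, seed=3)
        result = run_qbif(respond, cfg)
        assert result.n_trials == 15
        assert result.n_adaptive == 0

    def test_seeded_runs_identical(self):
        w = np.array([0.3, 0.1, 0.2, 0.1, 0.2, 0.1])
        cfg = SessionConfig(trial_budget=120, optimizer_mode="fisher", seed=8)
        _, respond1 = logistic_listener(w, -1.0, 0.25, seed=55)
        r1 = run_qbif(respond1, cfg)
        _, respond2 = logistic_listener(w, -1.0, 0.25, seed=55)
        r2 = run_qbif(respond2, cfg)
        assert [x.stimulus for x in r1.records] == [x.stimulus for x in r2.records]
        assert np.array_equal(r1.interim_coef, r2.interim_coef)

    def test_stimulus_provenance(self):
        """Adaptive stimuli come from the pool; training stimuli are at the
        top TMR with 1-4 omitted bands."""
        w = np.array([0.2, 0.2, 0.15, 0.15, 0.15, 0.15])
        _, respond = logistic_listener(w, 0.0, 0.2, seed=10)
        cfg = SessionConfig(trial_budget=150, optimizer_mode="fisher", seed=5)
        result = run_qbif(respond, cfg)
        pool = build_pool(GRID)
        pool_set = {(s.tmr_db, s.band_mask) for s in pool.stimuli}
        for rec, phase in zip(result.records, result.phases):
            if phase == "training":
                assert rec.stimulus.tmr_db == 15.0
                assert 1 <= 6 - rec.stimulus.n_presented <= 4
            else:
                assert (rec.stimulus.tmr_db, rec.stimulus.band_mask) in pool_set

    def test_selected_stimuli_hover_near_threshold(self):
        """Mean predicted probability at the selected stimuli converges
        toward 50% over the last 200 trials of a 500-trial session."""
        from qbif.simulators import respond as sim_respond, sample_listener

        listener = sample_listener(GRID, child_rng(2, "listener"))
        listener.rng = child_rng(2, "responses")
        cfg = SessionConfig(trial_budget=500, optimizer_mode="fisher", seed=2)
        result = run_qbif(lambda s: sim_respond(listener, s), cfg)
        rows = np.array([design_row(r.stimulus) for r in result.records])
        adaptive = [k for k, ph in enumerate(result.phases) if ph == "adaptive"]
        p_hat = [
            float(expit(rows[k] @ result.interim_coef[k - 1])) for k in adaptive[1:]
        ]
        assert 0.4 <= np.mean(p_hat[-200:]) <= 0.6

    def test_monotone_information_gain(self):
        """ln|P_k| is non-increasing across consecutive fits apart from
        refit noise: a surprising early response can shift the fitted
        probabilities enough to shrink the observed information, but such
        increases are rare and vanish once the posterior settles."""
        from qbif.simulators import respond as sim_respond, sample_listener

        for seed in (2, 14):
            listener = sample_listener(GRID, child_rng(seed, "listener"))
            listener.rng = child_rng(seed, "responses")
            cfg = SessionConfig(trial_budget=300, optimizer_mode="fisher", seed=seed)
            result = run_qbif(lambda s: sim_respond(listener, s), cfg)
            increases = np.diff(result.interim_logdet)
            assert np.sum(increases > 1e-6) <= 2
            assert np.all(increases[100:] <= 1e-6)

    def test_callback_failure_aborts_with_partial_result(self):
        calls = {"n": 0}

        def flaky(stim):
            calls["n"] += 1
            if calls["n"] > 10:
                raise RuntimeError("listener left the booth")
            return True

        cfg = SessionConfig(trial_budget=100, seed=1)
        with pytest.raises(SessionAbortedError) as err:
            run_qbif(flaky, cfg)
        assert err.value.partial_result.n_trials == 10
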