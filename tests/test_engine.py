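"""Tests of the trial-processing engine: posteriors, learning, schedules."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from latentcause.core import CauseStats, ModelParams, ModelState
from latentcause.engine import (
    conditioned_response,
    learning_posterior,
    m_step,
    num_em_iterations,
    process_trial,
    response_posterior,
    run_schedule,
    us_prediction,
)
from latentcause.oracles import (
    RandomScheduleConfig,
    generate_schedule,
    rw_reference,
    stats_from_scratch,
)

from conftest import acquisition, make_trial


class TestConditionedResponse:
    def test_half_at_threshold(self):
        assert conditioned_response(0.02, 0.02, 0.01) == pytest.approx(0.5)

    def test_saturates_for_strong_prediction(self):
        assert conditioned_response(1.0, 0.02, 0.01) == pytest.approx(1.0, abs=1e-10)

    def test_equals_tail_probability_when_lambda_is_us_variance(self):
        # With lambda = sigma_r^2 the CR is exactly P(r > theta) under
        # the predictive Gaussian.
        r_tilde, sigma_r_sq, theta = 0.3, 0.4, 0.02
        tail = 1 - norm.cdf(theta, loc=r_tilde, scale=math.sqrt(sigma_r_sq))
        assert conditioned_response(r_tilde, theta, sigma_r_sq) == pytest.approx(tail)

    def test_monotone_in_prediction_and_bounded(self):
        wide = np.linspace(-5, 5, 41)
        crs = [conditioned_response(r, 0.02, 0.01) for r in wide]
        assert all(0 <= c <= 1 for c in crs)
        assert all(b >= a for a, b in zip(crs, crs[1:]))
        # strictly increasing away from floating-point saturation
        grid = np.linspace(-0.3, 0.35, 27)
        crs = [conditioned_response(r, 0.02, 0.01) for r in grid]
        assert all(b > a for a, b in zip(crs, crs[1:]))

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ValueError):
            conditioned_response(0.1, 0.02, 0.0)


class TestUsPredictionAndMStep:
    def _state(self, w=0.657):
        state = ModelState(dim=1)
        cause = CauseStats(dim=1, weights=np.array([w]))
        cause.observe(make_trial(0.0))
        state.causes.append(cause)
        return state

    def test_zero_weights_predict_zero(self):
        state = ModelState(dim=1)
        state.causes.append(CauseStats(dim=1))
        assert us_prediction(state, np.array([1.0, 0.0]), np.ones(1)) == 0.0

    def test_single_confident_cause(self):
        state = self._state(0.657)
        assert us_prediction(state, np.array([1.0, 0.0]), np.ones(1)) == pytest.approx(
            0.657
        )

    def test_mass_on_new_slot_shrinks_prediction(self):
        state = self._state(0.657)
        full = us_prediction(state, np.array([1.0, 0.0]), np.ones(1))
        split = us_prediction(state, np.array([0.6, 0.4]), np.ones(1))
        assert abs(split) < abs(full)

    def test_zero_posterior_leaves_weights_untouched(self):
        state = self._state(0.5)
        m_step(state, np.array([0.0, 1.0]), np.ones(1), 1.0, eta=0.3)
        assert state.causes[0].weights == pytest.approx([0.5])

    def test_single_rescorla_wagner_step_and_compounding(self):
        state = self._state(0.0)
        m_step(state, np.array([1.0, 0.0]), np.ones(1), 1.0, eta=0.3)
        assert state.causes[0].weights == pytest.approx([0.3])
        m_step(state, np.array([1.0, 0.0]), np.ones(1), 1.0, eta=0.3)
        assert state.causes[0].weights == pytest.approx([0.51])


class TestRumination:
    @pytest.mark.parametrize(
        "gap,expected", [(1.0, 1), (0.25, 1), (2.5, 2), (3.0, 3), (100.0, 3)]
    )
    def test_iteration_budget(self, gap, expected, params):
        assert num_em_iterations(gap, params) == expected

    def test_nonpositive_gap_rejected(self, params):
        with pytest.raises(ValueError):
            num_em_iterations(0.0, params)


class TestPosteriors:
    def test_empty_history_all_mass_on_new_cause(self, params):
        state = ModelState(dim=1)
        q = response_posterior(state, np.ones(1), 0.0, params)
        assert q == pytest.approx([1.0])

    def test_familiar_cs_prefers_old_cause(self, params):
        state = ModelState(dim=1)
        run_state = run_schedule(acquisition(3), params, return_state=True)[1]
        q = response_posterior(run_state, np.ones(1), 3.0, params)
        assert q[0] > q[-1]

    def test_alpha_zero_is_single_cause(self):
        params = ModelParams(alpha=0.0)
        state = run_schedule(acquisition(2), params, return_state=True)[1]
        for x in ([1.0], [0.0], [7.0]):
            q = response_posterior(state, np.asarray(x), 3.0, params)
            assert q == pytest.approx([1.0, 0.0], abs=1e-15)

    def test_first_trial_learning_posterior(self, params):
        state = ModelState(dim=1)
        q = learning_posterior(state, np.ones(1), 1.0, 0.0, params)
        assert q == pytest.approx([1.0])

    def test_reinforced_trial_after_acquisition_prefers_acq_cause(self, params):
        state = run_schedule(acquisition(3), params, return_state=True)[1]
        q = learning_posterior(state, np.ones(1), 1.0, 3.0, params)
        assert int(np.argmax(q)) == 0

    def test_prediction_error_shifts_mass_to_new_cause(self, params):
        # Same unreinforced trial, with strong vs zero weights on the
        # old cause: the big US prediction error moves posterior mass
        # toward the new-cause slot.
        strong = run_schedule(acquisition(3), params, return_state=True)[1]
        weak = strong.copy()
        weak.causes[0].weights = np.zeros(1)
        q_strong = learning_posterior(strong, np.ones(1), 0.0, 3.0, params)
        q_weak = learning_posterior(weak, np.ones(1), 0.0, 3.0, params)
        assert q_strong[-1] > q_weak[-1]


class TestProcessTrial:
    def test_new_cause_instantiation_increments_k(self, params):
        state = ModelState(dim=1)
        result = process_trial(state, make_trial(0.0), 1, params)
        assert state.n_causes == 1
        assert result.map_cause == 0
        assert state.assignments == [0]

    def test_time_regression_rejected(self, params):
        state = ModelState(dim=1)
        process_trial(state, make_trial(5.0), 1, params)
        with pytest.raises(ValueError):
            process_trial(state, make_trial(4.0), 1, params)

    def test_retrieval_rumination_raises_posterior_and_lowers_weight(self, params):
        """On an unreinforced reexposure of a trained CS, more E/M
        alternations pull the acquisition cause's posterior up while
        its associative weight falls — the engine of the
        retrieval-extinction effect."""
        base = run_schedule(acquisition(3), params, return_state=True)[1]
        q_acq, w_acq = [], []
        for n_iters in (1, 2, 3):
            state = base.copy()
            result = process_trial(
                state, make_trial(22.0, us=0.0, phase="retrieval"), n_iters, params
            )
            q_acq.append(result.learning_posterior[0])
            w_acq.append(state.causes[0].weights[0])
        assert q_acq[0] < q_acq[1] < q_acq[2]
        assert w_acq[0] > w_acq[1] > w_acq[2]

    def test_probe_trial_learns_nothing(self, params):
        base = run_schedule(acquisition(3), params, return_state=True)[1]
        w_before = base.causes[0].weights.copy()
        result = process_trial(
            base, make_trial(22.0, us=None, phase="test"), 1, params
        )
        np.testing.assert_allclose(base.causes[0].weights, w_before)
        assert result.n_em_iters == 0
        np.testing.assert_allclose(
            result.learning_posterior, result.response_posterior
        )


class TestRunSchedule:
    def test_conditioning_raises_probe_cr(self, params):
        sched = acquisition(3) + [make_trial(22.0, us=0.0, phase="test")]
        table = run_schedule(sched, params)
        naive_cr = table[0].cr
        assert table[-1].cr > naive_cr

    def test_empty_schedule(self, params):
        assert len(run_schedule([], params)) == 0

    def test_bit_reproducible(self, params):
        sched = generate_schedule(RandomScheduleConfig(n_trials=25, dim=2, seed=7))
        a = run_schedule(sched, params).to_frame().to_csv(index=False)
        b = run_schedule(sched, params).to_frame().to_csv(index=False)
        assert a == b

    def test_invalid_schedule_rejected_before_compute(self, params):
        bad = [make_trial(1.0), make_trial(1.0)]
        with pytest.raises(ValueError):
            run_schedule(bad, params)
        mixed = [make_trial(0.0, x=[1.0]), make_trial(1.0, x=[1.0, 0.0])]
        with pytest.raises(ValueError):
            run_schedule(mixed, params)

    def test_results_rows_align_with_schedule(self, params):
        sched = acquisition(3) + [make_trial(30.0, us=0.0, phase="test")]
        table = run_schedule(sched, params)
        assert [r.time for r in table] == [t.time for t in sched]
        assert [r.phase for r in table] == [t.phase for t in sched]


class TestEngineProperties:
    def test_rescorla_wagner_equivalence(self):
        """alpha=0 with unit gaps reduces exactly to the RW recursion."""
        params = ModelParams(alpha=0.0)
        for seed in range(25):
            sched = generate_schedule(
                RandomScheduleConfig(
                    n_trials=30,
                    dim=3,
                    seed=seed,
                    time_gap_range=(1.0, 1.0),
                    feature_sparsity=0.4,
                )
            )
            table = run_schedule(sched, params)
            expected = rw_reference(sched, params.eta)
            got = np.array([r.weights_snapshot[0] for r in table])
            np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_incremental_stats_match_from_scratch(self, params):
        for seed in range(30):
            sched = generate_schedule(
                RandomScheduleConfig(n_trials=40, dim=2, seed=seed)
            )
            table, state = run_schedule(sched, params, return_state=True)
            ref = stats_from_scratch(sched, state.assignments)
            assert len(ref) == state.n_causes
            for got, exp in zip(state.causes, ref):
                assert got.count == exp.count
                assert got.times == exp.times
                np.testing.assert_allclose(
                    got.feature_sum, exp.feature_sum, atol=1e-12
                )

    def test_every_posterior_is_normalized(self, params):
        for seed in range(10):
            sched = generate_schedule(
                RandomScheduleConfig(n_trials=30, dim=2, seed=100 + seed)
            )
            for row in run_schedule(sched, params):
                for q in (row.response_posterior, row.learning_posterior):
                    assert np.all(q >= 0)
                    assert q.sum() == pytest.approx(1.0, abs=1e-12)
                assert row.map_cause == int(np.argmax(row.learning_posterior))

    def test_spontaneous_recovery_is_never_complete(self, params):
        """With an extinction cause holding at least as many, more
        recent trials, the acquisition cause's prior mass never exceeds
        the extinction cause's, and the ratio rises monotonically with
        the probe delay."""
        from latentcause.core import crp_prior
        from test_core import state_with

        state = state_with([[0.0, 1.0, 2.0], [22.0, 23.0, 24.0, 25.0]])
        ratios = []
        for delay in [1.0, 5.0, 20.0, 100.0, 1000.0, 1e5]:
            prior = crp_prior(state, 25.0 + delay, alpha=0.1)
            assert prior[0] <= prior[1]
            ratios.append(prior[0] / prior[1])
        assert all(b > a for a, b in zip(ratios, ratios[1:]))
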