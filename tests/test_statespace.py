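"""Unit and property tests for the innovations-form state-space core."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vnsdyn.containers import UniformSeries
from vnsdyn.statespace import (EstimationError, InnovationsStateSpace,
                               StateSpaceParams, count_parameters,
                               fit_percent, pem_refine, predict_one_step,
                               ridge_regularize, simulate, subspace_estimate,
                               _pack_theta)

from conftest import make_dataset


def first_order_params(a=0.5, b=1.0, c=1.0, k=0.0, tau=0):
    return StateSpaceParams([[a]], [b], [c], [k], dead_time=tau,
                            structure=(1,))


# ---------------------------------------------------------------------------
# fit percentage


class TestFitPercent:
    def test_perfect_prediction_scores_100(self):
        y = np.array([0.1, -0.4, 2.0, 1.0])
        assert fit_percent(y, y) == pytest.approx(100.0)

    def test_mean_predictor_scores_exactly_zero(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=200)
        assert fit_percent(y, np.full_like(y, y.mean())) == pytest.approx(0.0)

    def test_hand_computed_case(self):
        # y=[0,2], yhat=[1,1]: RMSE = 1, sigma = 1 -> 0%
        assert fit_percent([0.0, 2.0], [1.0, 1.0]) == pytest.approx(0.0)

    def test_constant_series_raises(self):
        with pytest.raises(ValueError, match="standard deviation"):
            fit_percent([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])

    @given(st.integers(0, 2 ** 32 - 1), st.floats(0.5, 10.0),
           st.floats(-5.0, 5.0))
    def test_affine_invariance(self, seed, scale, shift):
        """Scaling/shifting y and yhat together leaves fit% unchanged."""
        rng = np.random.default_rng(seed)
        y = rng.normal(size=50)
        yhat = y + rng.normal(scale=0.3, size=50)
        f0 = fit_percent(y, yhat)
        f1 = fit_percent(scale * y + shift, scale * yhat + shift)
        assert f1 == pytest.approx(f0, abs=1e-8)


def test_count_parameters_modal_budget():
    assert count_parameters(1) == 5
    assert count_parameters(2) == 10
    assert count_parameters(10) == 50
    with pytest.raises(ValueError):
        count_parameters(0)


# ---------------------------------------------------------------------------
# simulation


class TestSimulate:
    def test_equilibrium_is_conserved(self):
        p = first_order_params(a=0.9, b=0.3)
        y = simulate(p, np.zeros(50)).values
        assert np.all(y == 0)

    def test_linearity(self):
        p = first_order_params(a=0.8, b=0.5, tau=3)
        u = np.sin(np.arange(100) * 0.1)
        y1 = simulate(p, u).values
        y2 = simulate(p, 2 * u).values
        np.testing.assert_allclose(y2, 2 * y1, atol=1e-12)

    def test_first_order_step_closed_form(self):
        # step response of x[k+1] = a x[k] + b u[k]: y[k] = g (1 - a^k)
        a, b = 0.9, 0.2
        p = first_order_params(a=a, b=b)
        y = simulate(p, np.ones(100)).values
        k = np.arange(100)
        g = b / (1 - a)
        np.testing.assert_allclose(y, g * (1 - a ** k), atol=1e-12)

    def test_dead_time_delays_response(self):
        p = first_order_params(a=0.5, b=1.0, tau=7)
        y = simulate(p, np.ones(30)).values
        assert np.all(y[:8] == 0) and y[8] != 0

    def test_unstable_model_warns(self):
        p = first_order_params(a=1.2)
        with pytest.warns(RuntimeWarning, match="unstable"):
            simulate(p, np.ones(10))

    def test_nonzero_initial_state(self):
        a = 0.5
        p = first_order_params(a=a, b=0.0)
        y = simulate(p, np.zeros(10), x0=[2.0]).values
        np.testing.assert_allclose(y, 2.0 * a ** np.arange(10), atol=1e-12)


# ---------------------------------------------------------------------------
# one-step prediction


class TestPredictOneStep:
    def test_zero_innovation_gain_equals_simulation(self):
        p = first_order_params(a=0.7, b=0.4, k=0.0, tau=2)
        u = np.concatenate([np.zeros(10), np.ones(40)])
        rng = np.random.default_rng(0)
        y = simulate(p, u).values + rng.normal(0, 0.1, 50)
        ds = make_dataset(u, y)
        res = predict_one_step(p, ds)
        np.testing.assert_allclose(res.predicted, simulate(p, u).values,
                                   atol=1e-12)

    def test_true_model_on_noise_free_data_is_exact(self):
        p = first_order_params(a=0.8, b=0.5, k=0.3)
        u = np.concatenate([np.zeros(5), np.ones(45)])
        y = simulate(p, u).values
        res = predict_one_step(p, make_dataset(u, y))
        assert np.max(np.abs(res.residuals)) < 1e-10
        assert res.fit_percent == pytest.approx(100.0, abs=1e-6)

    def test_constant_output_raises(self):
        p = first_order_params()
        ds = make_dataset(np.ones(20), np.ones(20))
        with pytest.raises(ValueError, match="standard deviation"):
            predict_one_step(p, ds)

    def test_fit_identity_holds(self):
        p = first_order_params(a=0.6, b=0.2, k=0.1)
        rng = np.random.default_rng(1)
        u = rng.normal(size=60)
        y = rng.normal(size=60)
        res = predict_one_step(p, make_dataset(u, y, onset_index=0))
        assert res.fit_percent == pytest.approx(
            (1 - res.rmse / res.sigma) * 100)


# ---------------------------------------------------------------------------
# subspace identification


class TestSubspace:
    def test_known_recursion_recovered(self):
        # y[k] = 0.5 y[k-1] + u[k-1]
        rng = np.random.default_rng(0)
        datasets = []
        for r in range(3):
            u = (rng.random(300) > 0.5).astype(float)
            y = np.zeros(300)
            for k in range(1, 300):
                y[k] = 0.5 * y[k - 1] + u[k - 1]
            datasets.append(make_dataset(u, y))
        p = subspace_estimate(datasets, 1, 0)
        assert np.linalg.eigvals(p.A)[0] == pytest.approx(0.5, abs=1e-6)
        assert p.dc_gain() == pytest.approx(2.0, abs=1e-6)

    def test_unexcited_data_raises(self):
        ds = make_dataset(np.zeros(300), np.zeros(300))
        with pytest.raises(EstimationError, match="unexcited"):
            subspace_estimate([ds] * 3, 1, 0)

    def test_too_few_samples_raises(self):
        ds = make_dataset(np.ones(30), np.ones(30))
        with pytest.raises(EstimationError, match="too few samples"):
            subspace_estimate([ds], 1, 0)

    def test_order2_self_consistency(self, second_order_truth,
                                     second_order_records):
        """Noise-free order-2 truth at correct tau: simulation fit > 99
        on the training records."""
        p = subspace_estimate(second_order_records, 2, 15)
        for d in second_order_records:
            ysim = simulate(p, d.input).values
            assert fit_percent(d.y, ysim) > 99.0


# ---------------------------------------------------------------------------
# prediction-error refinement and ridge


class TestPEM:
    def test_truth_initialization_is_stationary(self, first_order_truth,
                                                first_order_records):
        init = first_order_truth.as_params()
        refined = pem_refine(init, first_order_records)
        sse0 = sum(np.sum(predict_one_step(init, d).residuals ** 2)
                   for d in first_order_records)
        sse1 = sum(np.sum(predict_one_step(refined, d).residuals ** 2)
                   for d in first_order_records)
        assert sse1 <= sse0 + 1e-12

    def test_objective_never_worse_than_init(self, first_order_records):
        init = subspace_estimate(first_order_records, 1, 12)
        # perturb the initialization away from the optimum
        bad = init.copy()
        bad.B = bad.B * 1.5
        bad.A = bad.A * 0.9
        refined = pem_refine(bad, first_order_records)
        sse_bad = sum(np.sum(predict_one_step(bad, d).residuals ** 2)
                      for d in first_order_records)
        sse_ref = sum(np.sum(predict_one_step(refined, d).residuals ** 2)
                      for d in first_order_records)
        assert sse_ref <= sse_bad

    def test_noise_free_refinement_is_nearly_exact(self, first_order_records):
        model = InnovationsStateSpace(first_order_records, order=1,
                                      dead_time=12).fit()
        assert np.all(model.fit_percents >= 99.9)


class TestRidge:
    def test_lambda_zero_is_identity(self, first_order_records):
        p = subspace_estimate(first_order_records, 1, 12)
        q = ridge_regularize(p, first_order_records, 0.0)
        np.testing.assert_array_equal(p.A, q.A)
        np.testing.assert_array_equal(p.B, q.B)

    def test_negative_lambda_raises(self, first_order_records):
        p = subspace_estimate(first_order_records, 1, 12)
        with pytest.raises(ValueError):
            ridge_regularize(p, first_order_records, -1.0)

    def test_huge_lambda_shrinks_to_baseline(self, first_order_records):
        p = pem_refine(subspace_estimate(first_order_records, 1, 12),
                       first_order_records)
        q = ridge_regularize(p, first_order_records, 1e12)
        assert np.linalg.norm(_pack_theta(q)) < 1e-3
        res = predict_one_step(q, first_order_records[0])
        assert np.max(np.abs(res.predicted)) < 1e-3

    def test_shrinkage_is_monotone_along_the_path(self, first_order_records):
        p = pem_refine(subspace_estimate(first_order_records, 1, 12),
                       first_order_records)
        norms = []
        for lam in (1e-6, 1e-2, 1e2, 1e6):
            q = ridge_regularize(p, first_order_records, lam)
            norms.append(np.linalg.norm(_pack_theta(q)))
        assert all(b <= a + 1e-9 for a, b in zip(norms, norms[1:]))


# ---------------------------------------------------------------------------
# model object and serialization


def test_results_summary_mentions_key_quantities(first_order_records):
    res = InnovationsStateSpace(first_order_records, 1, 12).fit()
    text = res.summary()
    assert "order (M)" in text and "dead time" in text
    assert "DC gain" in text


def test_serialization_round_trip():
    p = StateSpaceParams([[0.9, 0.2], [-0.2, 0.9]], [1.0, 0.5],
                         [0.3, -0.1], [0.05, 0.02], dead_time=9,
                         structure=(2,))
    q = StateSpaceParams.from_json(p.to_json())
    np.testing.assert_array_equal(p.A, q.A)
    np.testing.assert_array_equal(p.K, q.K)
    assert q.dead_time == 9 and q.structure == (2,)
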