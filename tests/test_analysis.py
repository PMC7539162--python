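"""Tests for baselines, statistical comparisons and response curves."""

import numpy as np
import pytest

from vnsdyn.analysis import (compare_delays, compare_paired,
                             experimental_response_curves,
                             naive_predictor_fit, run_baseline_tests,
                             simulated_response_curves,
                             standard_simulation_input)
from vnsdyn.selection import CVResult
from vnsdyn.statespace import StateSpaceParams
from vnsdyn.synthetic import generate_cohort, CohortConfig

from conftest import make_dataset


class TestNaivePredictor:
    def test_hand_computed_fixture(self):
        # y=[1,2,3,4]: yhat=[1,2,3] vs y[2:4]; RMSE=1, sigma=sqrt(2/3)
        ds = make_dataset(np.zeros(4), [1.0, 2.0, 3.0, 4.0])
        expected = (1 - 1 / np.sqrt(2 / 3)) * 100
        assert naive_predictor_fit(ds) == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(-22.47, abs=0.01)

    def test_slowly_varying_series_scores_high_but_below_100(self):
        y = np.sin(np.arange(300) * 0.02)
        ds = make_dataset(np.zeros(300), y)
        f = naive_predictor_fit(ds)
        assert 90 < f < 100

    def test_white_noise_expectation_near_minus_41(self):
        """For i.i.d. noise the naive RMSE inflates by sqrt(2), so the
        expected fit is (1 - sqrt(2)) * 100."""
        rng = np.random.default_rng(0)
        fits = [naive_predictor_fit(make_dataset(np.zeros(400),
                                                 rng.normal(size=400)))
                for _ in range(200)]
        assert np.mean(fits) == pytest.approx((1 - np.sqrt(2)) * 100,
                                              abs=2.0)

    def test_constant_series_raises(self):
        with pytest.raises(ValueError):
            naive_predictor_fit(make_dataset(np.zeros(10), np.ones(10)))


class TestBaselineTests:
    def test_identical_fits_do_not_pass(self):
        fits = np.array([50.0, 60.0, 55.0, 58.0, 52.0, 61.0])
        rep = run_baseline_tests(fits, fits)
        assert not rep.naive_test.passed
        assert rep.naive_test.p_value > 0.5

    def test_mean_baseline_is_exactly_zero(self):
        fits = np.array([50.0, 60.0, 55.0, 58.0, 52.0, 61.0])
        naive = np.array([44.0, 57.0, 48.0, 55.0, 49.0, 52.0])
        rep = run_baseline_tests(fits, naive)
        np.testing.assert_array_equal(rep.mean_fits, 0.0)

    def test_clear_superiority_passes_one_sided(self):
        rng = np.random.default_rng(1)
        model = 70 + rng.normal(0, 3, 12)
        naive = 50 + rng.normal(0, 3, 12)
        rep = run_baseline_tests(model, naive)
        assert rep.passed
        assert rep.naive_test.p_value < 0.001
        assert rep.mean_test.p_value < 0.001

    def test_few_subjects_warn(self):
        with pytest.warns(RuntimeWarning, match="fewer than 6"):
            run_baseline_tests([60.0, 62, 64], [50.0, 51, 52])


class TestComparePaired:
    def test_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        rep = compare_paired(a, a)
        assert rep.statistic == 0.0 and rep.p_value == 1.0

    def test_hand_computed_t(self):
        # differences [1,2,3]: mean 2, sd 1, t = 2 / (1/sqrt(3))
        a = np.array([2.0, 4.0, 6.0])
        b = np.array([1.0, 2.0, 3.0])
        rep = compare_paired(a, b)
        assert rep.test_used == "paired_t"
        assert rep.statistic == pytest.approx(2 * np.sqrt(3), abs=1e-6)
        assert rep.dof == (2,)

    def test_nonnormal_differences_take_wilcoxon_branch(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=25)
        diffs = rng.standard_cauchy(25) ** 3  # heavy-tailed
        from scipy import stats
        assert stats.shapiro(diffs).pvalue < 0.05  # fixture premise
        rep = compare_paired(base + diffs, base)
        assert rep.test_used == "wilcoxon"

    def test_zero_variance_differences_raise(self):
        with pytest.raises(ValueError):
            compare_paired([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])


class TestCompareDelays:
    def test_identical_sets_are_null(self):
        d = np.array([15.0, 18.0, 20.0, 17.0])
        rep = compare_delays({"a": d, "b": d, "c": d})
        assert rep.statistic == 0.0 and rep.effect_size == 0.0

    def test_matches_hand_computed_rm_anova(self):
        """3 subjects x 3 conditions, F from the textbook two-way
        decomposition computed by hand."""
        data = np.array([[10.0, 12.0, 11.0],
                         [14.0, 15.0, 16.0],
                         [20.0, 19.0, 24.0]])  # subjects x conditions
        grand = data.mean()
        ss_cond = 3 * np.sum((data.mean(axis=0) - grand) ** 2)
        ss_subj = 3 * np.sum((data.mean(axis=1) - grand) ** 2)
        ss_tot = np.sum((data - grand) ** 2)
        ss_err = ss_tot - ss_cond - ss_subj
        f_hand = (ss_cond / 2) / (ss_err / 4)
        eta_hand = ss_cond / (ss_cond + ss_err)
        rep = compare_delays({"x": data[:, 0], "y": data[:, 1],
                              "z": data[:, 2]})
        assert rep.statistic == pytest.approx(f_hand, abs=1e-6)
        assert rep.effect_size == pytest.approx(eta_hand, abs=1e-6)
        assert rep.dof == (2, 4)

    def test_null_calibration(self):
        """Sets drawn from one distribution: p > .05 in >= 90% of
        seeded replicates."""
        rng = np.random.default_rng(7)
        nonsig = 0
        reps = 20
        for _ in range(reps):
            sets = {k: 17 + rng.normal(0, 5, 12) for k in ("a", "b", "c")}
            if compare_delays(sets).p_value > 0.05:
                nonsig += 1
        assert nonsig >= int(0.9 * reps)

    def test_wrong_set_count_raises(self):
        with pytest.raises(ValueError):
            compare_delays({"a": [1, 2, 3], "b": [1, 2, 3]})


def _curve_datasets(curves_by_subject, group="active", biomarker="hr"):
    """Build administration datasets whose 250-s display cut equals the
    given per-subject curves."""
    datasets = []
    for subj, curve in curves_by_subject.items():
        y = np.zeros(300)
        y[50:300] = curve
        datasets.append(make_dataset(
            np.concatenate([np.zeros(60),
                            np.ones(120), np.zeros(120)]), y,
            onset_index=60, subject=subj, group=group, biomarker=biomarker))
    return datasets


class TestExperimentalCurves:
    def test_identical_subjects_have_zero_sem(self):
        curve = np.sin(np.arange(250) * 0.05)
        ds = _curve_datasets({"A": curve, "B": curve, "C": curve})
        out = experimental_response_curves(ds, "active", "hr")
        np.testing.assert_allclose(out.sem, 0.0, atol=1e-12)
        np.testing.assert_allclose(out.mean, curve * 100, atol=1e-9)

    def test_single_subject_flagged_with_zero_sem(self):
        ds = _curve_datasets({"A": np.sin(np.arange(250) * 0.1)})
        out = experimental_response_curves(ds, "active", "hr")
        assert "single_subject_sem_zero" in out.flags
        np.testing.assert_array_equal(out.sem, 0.0)

    def test_sham_cohort_stays_near_zero(self):
        """Zero-gain truth with low noise: the population mean curve is
        bounded by the noise SEM."""
        cfg = CohortConfig(hr_noise_sd=0.005, ppg_noise_sd=0.005)
        cohort = generate_cohort(4, 0, seed=3, config=cfg)
        out = experimental_response_curves(cohort.datasets, "sham", "hr")
        # 0.5% noise, 4 admins x 4 subjects: mean curve within ~3x SEM
        assert np.max(np.abs(out.mean)) < 3.5 * np.median(out.sem) + 0.2

    def test_grid_is_250_seconds(self):
        ds = _curve_datasets({"A": np.sin(np.arange(250) * 0.1)})
        out = experimental_response_curves(ds, "active", "hr")
        assert len(out.time_s) == 250
        assert out.stim_window_s == (10, 130)


class TestSimulatedCurves:
    def _cv(self, params, subject="A", group="active", biomarker="hr"):
        return CVResult(subject, biomarker, group, [params] * 4,
                        [80.0] * 4, [(params.order, params.dead_time,
                                      1e-15)] * 4)

    def test_zero_gain_models_give_flat_curves(self):
        p = StateSpaceParams([[0.9]], [0.0], [1.0], [0.1], dead_time=12,
                             structure=(1,))
        out = simulated_response_curves([self._cv(p)], "active", "hr")
        np.testing.assert_allclose(out.mean, 0.0, atol=1e-12)

    def test_curves_are_zero_before_stimulus(self):
        p = StateSpaceParams([[0.95]], [-0.002], [1.0], [0.0], dead_time=8,
                             structure=(1,))
        out = simulated_response_curves([self._cv(p)], "active", "hr")
        assert np.all(out.mean[:10 + 8] == 0)
        assert np.any(out.mean[10 + 9:] != 0)

    def test_standard_input_support(self):
        u = standard_simulation_input()
        assert len(u) == 250
        assert np.all(u.values[:10] == 0)
        assert np.all(u.values[10:130] > 0)
        assert np.all(u.values[135:] == 0)

    def test_response_sign_follows_gain_sign(self):
        neg = StateSpaceParams([[0.95]], [-0.002], [1.0], [0.0],
                               dead_time=10, structure=(1,))
        pos = StateSpaceParams([[0.95]], [0.02], [1.0], [0.0],
                               dead_time=10, structure=(1,))
        down = simulated_response_curves([self._cv(neg)], "active", "hr")
        up = simulated_response_curves(
            [self._cv(pos, biomarker="ppg_amp")], "active", "ppg_amp")
        assert down.mean.min() < 0 and abs(down.mean.min()) > down.mean.max()
        assert up.mean.max() > 0 and up.mean.max() > abs(up.mean.min())
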