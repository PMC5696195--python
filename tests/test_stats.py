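import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from adcradiomics.stats import (
    UndefinedRocError,
    accuracy_from_rates,
    binormal_auc_simulation,
    compare_groups,
    contingency_rates,
    empirical_auc,
    icc_two_observers,
    roc_analysis,
    sidak_adjust,
    stepwise_logistic,
)


class TestCompareGroups:
    def test_identical_samples_never_significant(self, rng):
        x = rng.normal(0, 1, 30)
        res = compare_groups(x, x.copy())
        assert res.p_value > 0.9

    def test_large_gaussian_effect_routed_to_t(self, rng):
        res = compare_groups(rng.normal(0, 1, 200), rng.normal(2, 1, 200))
        assert res.test == "welch_t"
        assert res.p_value < 1e-10

    def test_heavy_tails_routed_to_mann_whitney(self, rng):
        res = compare_groups(rng.lognormal(0, 1.5, 100), rng.lognormal(0.5, 1.5, 100))
        assert res.test == "mann_whitney"

    def test_zero_variance_group_flagged(self, rng):
        res = compare_groups(np.full(10, 5.0), rng.normal(0, 1, 10))
        assert res.zero_variance
        assert res.test == "mann_whitney"

    def test_requires_three_per_group(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])


class TestRoc:
    def test_auc_equals_mann_whitney_u(self, rng):
        scores = rng.normal(0, 1, 60)
        tie_mask = rng.random(60) < 0.3
        scores[tie_mask] = np.round(scores[tie_mask], 1)  # introduce ties
        labels = rng.random(60) < 0.4
        if not labels.any() or labels.all():
            labels[:2] = [True, False]
        u = sps.mannwhitneyu(scores[labels], scores[~labels]).statistic
        assert empirical_auc(scores, labels) == pytest.approx(
            u / (labels.sum() * (~labels).sum())
        )

    def test_perfect_separation(self):
        scores = np.array([1.0, 2, 3, 10, 11, 12])
        labels = np.array([0, 0, 0, 1, 1, 1], bool)
        res = roc_analysis(scores, labels)
        assert res.auc == 1.0
        assert res.accuracy == 100.0
        assert 3.0 < res.cutoff < 10.0
        assert not res.positive_on_low

    def test_null_auc_near_half(self, rng):
        res = roc_analysis(rng.normal(0, 1, 4000), rng.random(4000) < 0.5)
        assert res.auc == pytest.approx(0.5, abs=0.05)

    def test_orientation_flag_when_low_predicts_event(self):
        scores = np.array([10.0, 11, 12, 1, 2, 3])
        labels = np.array([0, 0, 0, 1, 1, 1], bool)
        res = roc_analysis(scores, labels)
        assert res.positive_on_low
        assert res.auc == 1.0
        assert 3.0 < res.cutoff < 10.0

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(0, 1, 80)
        labels = rng.random(80) < 0.3
        labels[:2] = [True, False]
        a = empirical_auc(scores, labels)
        b = empirical_auc(np.exp(scores), labels)
        c = empirical_auc(3 * scores - 7, labels)
        assert a == b == c

    def test_ci_contains_auc_and_is_ordered(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 26), rng.normal(1, 1, 10)])
        labels = np.arange(36) >= 26
        for ci in ("delong", "hanley_mcneil"):
            res = roc_analysis(scores, labels, ci=ci)
            assert res.auc_ci_low <= res.auc <= res.auc_ci_high

    def test_accuracy_consistent_with_rates(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 26), rng.normal(1.5, 1, 10)])
        labels = np.arange(36) >= 26
        res = roc_analysis(scores, labels)
        expected = (res.sensitivity / 100 * 10 + res.specificity / 100 * 26) / 36 * 100
        assert res.accuracy == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedRocError):
            roc_analysis([1.0, 2.0, 3.0], [True, True, True])

    def test_binormal_simulation_converges_to_closed_form(self, rng):
        # mean empirical AUC ~ Phi(dmu / sqrt(s1^2+s2^2))
        expected = sps.norm.cdf(1.0 / np.sqrt(2.0))
        got = binormal_auc_simulation(1.0, 1.0, 26, 0.0, 1.0, 10, n_replicates=3000, rng=rng)
        assert got == pytest.approx(expected, abs=0.02)


class TestAccuracyFromRates:
    @pytest.mark.parametrize(
        "r1,r2,n1,n2,expected",
        [
            (69.2, 90.0, 26, 10, 75.0),
            (76.9, 80.0, 26, 10, 77.8),
            (73.1, 80.0, 26, 10, 75.0),
            (100.0, 100.0, 7, 13, 100.0),
        ],
    )
    def test_reconstruction(self, r1, r2, n1, n2, expected):
        assert accuracy_from_rates(r1, r2, n1, n2) == pytest.approx(expected, abs=0.05)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            accuracy_from_rates(101.0, 50.0, 10, 10)
        with pytest.raises(ValueError):
            accuracy_from_rates(50.0, 50.0, 0, 10)


class TestSidak:
    def test_identity_at_m_one(self):
        assert sidak_adjust(0.05, 1) == pytest.approx(0.05)

    def test_closed_form_m_two(self):
        assert sidak_adjust(0.05, 2) == pytest.approx(0.02532, abs=5e-5)

    @pytest.mark.parametrize("m", [1, 2, 4, 10, 14])
    def test_between_bonferroni_and_alpha(self, m):
        adj = sidak_adjust(0.05, m)
        assert 0.05 / m - 1e-12 <= adj <= 0.05 + 1e-12

    def test_familywise_error_control(self, rng):
        # m independent nulls tested at the adjusted level: FWER ~ alpha
        m, alpha, reps = 10, 0.05, 4000
        adj = sidak_adjust(alpha, m)
        p = rng.random((reps, m))
        fwer = (p < adj).any(axis=1).mean()
        assert fwer == pytest.approx(alpha, abs=0.015)


class TestStepwiseLogistic:
    def test_single_informative_feature_selected(self, rng):
        n = 200
        X = pd.DataFrame({f"noise{i}": rng.normal(0, 1, n) for i in range(5)})
        signal = rng.normal(0, 1, n)
        X["signal"] = signal
        y = rng.random(n) < 1 / (1 + np.exp(-3 * signal))
        res = stepwise_logistic(X, y)
        assert res.selected == ["signal"]
        assert res.wald_p["signal"] < 0.001

    def test_all_noise_mostly_empty(self, rng):
        hits = 0
        for _ in range(10):
            X = pd.DataFrame({f"n{i}": rng.normal(0, 1, 120) for i in range(4)})
            y = rng.random(120) < 0.4
            hits += bool(stepwise_logistic(X, y).selected)
        assert hits <= 3  # type-I entries are rare at p_enter=0.05

    def test_duplicated_feature_enters_once(self, rng):
        n = 200
        signal = rng.normal(0, 1, n)
        y = rng.random(n) < 1 / (1 + np.exp(-3 * signal))
        X = pd.DataFrame({"a": signal, "b": signal.copy(), "noise": rng.normal(0, 1, n)})
        res = stepwise_logistic(X, y)
        assert len(set(res.selected) & {"a", "b"}) == 1

    def test_separation_falls_back_to_ridge(self, rng):
        n = 40
        x = np.concatenate([rng.uniform(0, 1, n // 2), rng.uniform(2, 3, n // 2)])
        y = np.arange(n) >= n // 2  # perfectly separated
        X = pd.DataFrame({"x": x, "noise": rng.normal(0, 1, n)})
        res = stepwise_logistic(X, y)
        assert "x" in res.selected
        assert res.separation

    def test_missing_values_rejected(self):
        X = pd.DataFrame({"a": [1.0, np.nan, 2.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            stepwise_logistic(X, [True, False, True])


class TestContingency:
    def test_rates_from_counts(self):
        res = contingency_rates(6, 11, 4, 25)
        assert res.rate1 == pytest.approx(54.5, abs=0.05)
        assert res.rate2 == pytest.approx(16.0, abs=0.05)
        assert 0 <= res.p_value <= 1

    def test_zero_events_degenerate(self):
        res = contingency_rates(0, 12, 0, 20)
        assert res.rate1 == res.rate2 == 0.0
        assert res.p_value == 1.0

    def test_symmetric_under_group_swap(self):
        a = contingency_rates(6, 17, 4, 19)
        b = contingency_rates(4, 19, 6, 17)
        assert a.p_value == pytest.approx(b.p_value)
        assert (a.rate1, a.rate2) == (b.rate2, b.rate1)

    def test_fisher_used_for_sparse_tables(self):
        assert contingency_rates(1, 6, 5, 7).test == "fisher"

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            contingency_rates(5, 4, 1, 10)


class TestIcc:
    def test_identical_observers_give_one(self, rng):
        x = rng.normal(1000, 100, 20)
        res = icc_two_observers(x, x.copy())
        assert res.icc == pytest.approx(1.0, abs=1e-9)

    def test_independent_observers_near_zero(self, rng):
        res = icc_two_observers(rng.normal(0, 1, 2000), rng.normal(0, 1, 2000))
        assert abs(res.icc) < 0.08

    def test_variance_ratio_recovery(self, rng):
        # subjects sd=100, rater noise sd=33 -> ICC = 100^2/(100^2+33^2) ~ 0.902
        target = 100**2 / (100**2 + 33**2)
        iccs = []
        for _ in range(60):
            subj = rng.normal(0, 100, 40)
            iccs.append(
                icc_two_observers(subj + rng.normal(0, 33, 40), subj + rng.normal(0, 33, 40)).icc
            )
        assert np.mean(iccs) == pytest.approx(target, abs=0.03)

    def test_ci_brackets_estimate(self, rng):
        subj = rng.normal(0, 100, 30)
        res = icc_two_observers(subj + rng.normal(0, 30, 30), subj + rng.normal(0, 30, 30))
        assert res.ci_low <= res.icc <= res.ci_high

    def test_constant_ratings_flagged(self):
        res = icc_two_observers(np.full(10, 3.0), np.full(10, 3.0))
        assert res.degenerate

    def test_minimum_subjects(self):
        with pytest.raises(ValueError):
            icc_two_observers([1.0, 2.0], [1.0, 2.0])
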