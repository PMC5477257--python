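import math

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import minimize_scalar

from panctex import (
    cox_univariate,
    dichotomize_survival,
    km_curve,
    mann_whitney,
    median_split_km,
    roc_analysis,
    wald_statistic,
)
from panctex.exceptions import DivergenceError, NonIdentifiableError


class TestMannWhitney:
    def test_exact_enumeration_small_sample(self):
        # all C(4,2) labelings: U=0 is one of 6 extreme-or-more... p = 2/6
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(2 / 6, abs=1e-12)

    def test_identical_samples_symmetry(self):
        x = [1.0, 2.0, 3.0, 4.0]
        u, p = mann_whitney(x, x)
        assert u == pytest.approx(len(x) ** 2 / 2)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_swap_invariance(self, rng):
        x, y = rng.normal(0, 1, 9), rng.normal(0.5, 1, 13)
        _, p1 = mann_whitney(x, y)
        _, p2 = mann_whitney(y, x)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_matches_permutation_oracle(self, rng):
        """Asymptotic tie-corrected p agrees with a resampling null at n=15/15."""
        x = rng.normal(0.0, 1.0, 15).round(1)  # rounding induces ties
        y = rng.normal(0.6, 1.0, 15).round(1)
        u_obs, p = mann_whitney(x, y)
        pooled = np.concatenate([x, y])
        n_draw = 100_000
        perms = np.array([rng.permutation(pooled) for _ in range(n_draw)])
        ranks = stats.rankdata(perms, axis=1)
        u_perm = ranks[:, :15].sum(axis=1) - 15 * 16 / 2
        mu = 15 * 15 / 2
        p_mc = np.mean(np.abs(u_perm - mu) >= abs(u_obs - mu) - 1e-9)
        mc_err = 3 * math.sqrt(p_mc * (1 - p_mc) / n_draw + 1e-12)
        assert p == pytest.approx(p_mc, abs=max(mc_err, 0.01))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


def breslow_loglik(beta, x, time, event):
    """Explicit Breslow partial log-likelihood (reference implementation)."""
    ll = 0.0
    for t in np.unique(time[event == 1]):
        deaths = (time == t) & (event == 1)
        risk = time >= t
        ll += beta * x[deaths].sum() - deaths.sum() * math.log(
            np.exp(beta * x[risk]).sum()
        )
    return ll


class TestCoxUnivariate:
    def test_wald_invariant_by_construction(self, rng):
        x = rng.normal(0, 1, 40)
        t = rng.exponential(10, 40)
        e = rng.integers(0, 2, 40)
        e[:2] = 1
        fit = cox_univariate(x, t, e)
        assert fit.wald == pytest.approx(wald_statistic(fit.beta, fit.se), rel=1e-12)
        assert 0 < fit.p <= 1
        assert fit.se > 0

    def test_toy_data_matches_grid_search_oracle(self):
        x = np.array([0.1, 1.3, -0.4, 2.0, 0.7, -1.1])
        time = np.array([5.0, 2.0, 9.0, 6.0, 4.0, 3.0])
        event = np.array([1, 1, 0, 1, 1, 1])
        fit = cox_univariate(x, time, event, ties="breslow")
        res = minimize_scalar(
            lambda b: -breslow_loglik(b, x, time, event), bounds=(-10, 10),
            method="bounded", options={"xatol": 1e-10},
        )
        assert fit.beta == pytest.approx(res.x, abs=1e-4)

    def test_tied_data_matches_grid_search_oracle(self):
        x = np.array([0.5, -0.2, 1.1, 0.9, -1.4, 0.0, 2.2, -0.7])
        time = np.array([3.0, 3.0, 5.0, 5.0, 5.0, 8.0, 2.0, 9.0])
        event = np.array([1, 1, 1, 1, 0, 1, 1, 0])
        fit = cox_univariate(x, time, event, ties="breslow")
        res = minimize_scalar(
            lambda b: -breslow_loglik(b, x, time, event), bounds=(-10, 10),
            method="bounded", options={"xatol": 1e-10},
        )
        assert fit.beta == pytest.approx(res.x, abs=1e-4)

    def test_matches_lifelines(self, rng):
        """Independent cross-check against lifelines' Cox implementation."""
        import pandas as pd
        from lifelines import CoxPHFitter

        x = rng.normal(0, 1, 60)
        time = rng.exponential(20, 60).round(0) + 1  # ties on purpose
        event = (rng.random(60) < 0.7).astype(int)
        fit = cox_univariate(x, time, event, ties="efron")
        df = pd.DataFrame({"x": x, "T": time, "E": event})
        cph = CoxPHFitter().fit(df, duration_col="T", event_col="E")
        assert fit.beta == pytest.approx(cph.params_["x"], rel=1e-4, abs=1e-6)
        assert fit.se == pytest.approx(cph.standard_errors_["x"], rel=1e-3)

    def test_negating_covariate_negates_beta(self, rng):
        x = rng.normal(0, 1, 30)
        t = rng.exponential(10, 30)
        e = np.ones(30, dtype=int)
        f1 = cox_univariate(x, t, e)
        f2 = cox_univariate(-x, t, e)
        assert f1.beta == pytest.approx(-f2.beta, rel=1e-8)
        assert f1.se == pytest.approx(f2.se, rel=1e-8)

    def test_null_covariate_coverage(self, small_phantom_spec):
        """Independent covariate: |beta| < 2·se in at least 90 of 100 seeds."""
        hits = 0
        rng = np.random.default_rng(2)
        for _ in range(100):
            x = rng.normal(0, 1, 300)
            t = rng.exponential(31, 300)
            c = rng.uniform(0, 120, 300)
            e = (t <= c).astype(int)
            fit = cox_univariate(x, np.minimum(t, c), e)
            hits += abs(fit.beta) < 2 * fit.se
        assert hits >= 90

    def test_constant_covariate_not_identifiable(self):
        with pytest.raises(NonIdentifiableError):
            cox_univariate(np.ones(10), np.arange(1.0, 11.0), np.ones(10, dtype=int))

    def test_monotone_likelihood_diverges(self):
        # covariate perfectly orders survival → no finite maximum
        x = np.arange(10.0)
        time = np.arange(10.0, 0.0, -1.0)
        with pytest.raises(DivergenceError):
            cox_univariate(x, time, np.ones(10, dtype=int))

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError):
            cox_univariate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [1, 0, 0])


class TestDichotomize:
    def test_even_cohort_median_midpoint(self):
        np.testing.assert_array_equal(dichotomize_survival([1, 2, 3, 4]), [0, 0, 1, 1])

    def test_all_equal_all_labelled_one(self):
        np.testing.assert_array_equal(dichotomize_survival([5, 5, 5]), [1, 1, 1])

    def test_at_least_half_labelled(self, rng):
        times = rng.exponential(30, 30)
        labels = dichotomize_survival(times)
        assert labels.sum() >= math.ceil(30 / 2)
        np.testing.assert_array_equal(labels, (times >= np.median(times)).astype(int))


class TestROC:
    def test_perfect_separation(self):
        r = roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_tied_pair_enumeration(self):
        # positives [1,2] vs negatives [0,1]: wins 3, tie 1 → AUC 3.5/4
        r = roc_analysis([1, 2, 0, 1], [1, 1, 0, 0])
        assert r.auc == pytest.approx(0.875)

    def test_auc_equals_u_identity(self, rng):
        for _ in range(50):
            n1, n0 = rng.integers(2, 12, 2)
            feat = rng.integers(0, 5, n1 + n0).astype(float)
            out = np.r_[np.ones(n1, int), np.zeros(n0, int)]
            r = roc_analysis(feat, out)
            u, _ = mann_whitney(feat[out == 1], feat[out == 0])
            auc_u = u / (n1 * n0)
            assert r.auc == pytest.approx(max(auc_u, 1 - auc_u), abs=1e-12)

    def test_youden_threshold_attains_reported_operating_point(self, rng):
        feat = rng.normal(0, 1, 40)
        out = (rng.random(40) < 0.5).astype(int)
        out[0], out[1] = 1, 0
        r = roc_analysis(feat, out)
        pos, neg = feat[out == 1], feat[out == 0]
        if r.flipped:
            sens = (pos <= r.threshold).mean()
            spec = (neg > r.threshold).mean()
        else:
            sens = (pos >= r.threshold).mean()
            spec = (neg < r.threshold).mean()
        assert sens == pytest.approx(r.sensitivity)
        assert spec == pytest.approx(r.specificity)
        assert r.ci95[0] <= r.auc <= r.ci95[1]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([1.0, 2.0], [1, 1])


class TestKaplanMeier:
    def test_hand_product_limit(self):
        curve = km_curve([1.0, 2.0, 3.0], [1, 0, 1])
        assert curve.survival_at(1.0) == pytest.approx(2 / 3)
        assert curve.survival_at(2.5) == pytest.approx(2 / 3)
        assert curve.survival_at(3.0) == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(10, 25)
        curve = km_curve(t, np.ones(25, dtype=int))
        for q in [np.min(t), np.median(t), np.max(t)]:
            assert curve.survival_at(q) == pytest.approx((t > q).mean(), abs=1e-12)

    def test_all_censored_flat_at_one(self):
        curve = km_curve([1.0, 5.0, 9.0], [0, 0, 0])
        np.testing.assert_allclose(curve.survival, 1.0)

    def test_monotone_from_one(self, rng):
        t = rng.exponential(10, 40)
        e = (rng.random(40) < 0.6).astype(int)
        curve = km_curve(t, e)
        assert curve.survival[0] == 1.0
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert np.all((curve.survival >= 0) & (curve.survival <= 1))


class TestMedianSplitKM:
    def test_identical_groups_null(self):
        feat = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        time = np.array([2.0, 5.0, 9.0, 2.0, 5.0, 9.0])
        event = np.array([1, 1, 0, 1, 1, 0])
        _, _, stat, p = median_split_km(feat, time, event)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_split_rejected(self):
        with pytest.raises(ValueError):
            median_split_km([1.0] * 6, np.arange(1.0, 7.0), np.ones(6, dtype=int))

    def test_power_under_hazard_ratio_three(self):
        """HR = 3 between groups, n = 2×50: median p over seeds is well below 0.05."""
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(100):
            feat = np.r_[np.zeros(50), np.ones(50)]
            t = np.r_[rng.exponential(30, 50), rng.exponential(10, 50)]
            e = np.ones(100, dtype=int)
            *_, p = median_split_km(feat, t, e)
            pvals.append(p)
        assert np.median(pvals) < 0.05
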