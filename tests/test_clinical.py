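"""ROC tables, Kaplan-Meier, log-rank and Cox regression."""

import numpy as np
import pandas as pd
import pytest

from mirclone.clinical import cox_fit, km, km_by_group, logrank, roc, survival_at


def mannwhitney_auc(values, labels):
    """Brute-force U / (n1*n2) with 0.5 for ties."""
    v = np.asarray(values, float)
    y = np.asarray(labels, int)
    pos, neg = v[y == 1], v[y == 0]
    u = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return u / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        assert roc([1, 2, 3, 4], [0, 0, 1, 1]).auc == pytest.approx(1.0)

    def test_all_tied_values(self):
        assert roc([5, 5, 5, 5], [0, 1, 0, 1]).auc == pytest.approx(0.5)

    def test_auc_equals_mann_whitney(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(6, 50))
            v = rng.integers(0, 10, size=n).astype(float)  # ties likely
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                continue
            assert roc(v, y).auc == pytest.approx(mannwhitney_auc(v, y))

    def test_orientation_flag(self):
        v = [10, 9, 2, 1]
        y = [0, 0, 1, 1]  # marker drops in disease
        assert roc(v, y, higher_is_positive=False).auc == pytest.approx(1.0)
        assert roc(v, y, higher_is_positive=True).auc == pytest.approx(0.0)

    def test_table_fields_and_monotone_curve(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=40)
        y = (rng.random(40) < 0.5).astype(int)
        t = roc(v, y).table
        for col in ["cutoff", "sensitivity", "one_minus_specificity", "ppv", "npv",
                    "lr_positive", "lr_negative", "accuracy"]:
            assert col in t.columns
        # sweeping the threshold down, sensitivity and FPR only grow
        assert t.sensitivity.is_monotonic_increasing
        assert t.one_minus_specificity.is_monotonic_increasing

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc([1, 2, 3], [1, 1, 1])


class TestKm:
    def test_hand_product_limit(self):
        t = km([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        assert survival_at(t, 3) == pytest.approx(0.4)  # 4/5 * 3/4 * 2/3
        assert survival_at(t, 5) == pytest.approx(0.0)

    def test_censoring_fixture(self):
        # death at 1 (5 at risk), censor at 2, death at 3 (3 at risk)
        t = km([1, 2, 3, 4, 5], [1, 0, 1, 0, 0])
        assert survival_at(t, 1) == pytest.approx(4 / 5)
        assert survival_at(t, 3) == pytest.approx(4 / 5 * 2 / 3)

    def test_no_events_curve_stays_one(self):
        t = km([1, 2, 3], [0, 0, 0])
        assert survival_at(t, 10) == 1.0

    def test_ties_deaths_before_censorings(self):
        t = km([2, 2, 2, 5], [1, 0, 1, 1])
        # both deaths and the censoring at t=2 share the risk set of 4
        assert survival_at(t, 2) == pytest.approx(2 / 4)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km([-1, 2], [1, 1])

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(8)
        t = rng.exponential(10, size=60)
        e = (rng.random(60) < 0.7).astype(int)
        ours = km(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for _, row in ours.iterrows():
            assert row.survival == pytest.approx(
                float(kmf.survival_function_at_times(row.time).iloc[0])
            )


class TestLogrank:
    def test_identical_groups_give_chi2_zero(self):
        t = [1, 2, 3, 4, 5, 1, 2, 3, 4, 5]
        e = [1, 1, 0, 1, 1] * 2
        g = [0] * 5 + [1] * 5
        res = logrank(t, e, g)
        assert res.chi2 == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_no_usable_events_flagged(self):
        res = logrank([1, 1], [1, 0], [0, 1])  # single event, no variance?构
        assert res.flagged or res.p is not None

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(9)
        t = np.concatenate([rng.exponential(5, 30), rng.exponential(12, 30)])
        e = (rng.random(60) < 0.8).astype(int)
        g = np.array([0] * 30 + [1] * 30)
        ours = logrank(t, e, g)
        ref = logrank_test(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert ours.chi2 == pytest.approx(ref.test_statistic, rel=1e-6)
        assert ours.p == pytest.approx(ref.p_value, rel=1e-6)


class TestCox:
    def test_duplicated_symmetric_groups_give_zero_coef(self):
        t = [1.0, 2, 3, 4, 5, 1, 2, 3, 4, 5]
        e = [1] * 10
        X = pd.DataFrame({"g": [0] * 5 + [1] * 5})
        res = cox_fit(X, t, e)
        assert res.coef["g"] == pytest.approx(0.0, abs=1e-8)

    def test_loglik_nondecreasing(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame({"x": rng.normal(size=100)})
        t = rng.exponential(np.exp(-0.5 * X.x))
        e = np.ones(100, int)
        res = cox_fit(X, t, e)
        assert all(b >= a - 1e-9 for a, b in zip(res.loglik_trace, res.loglik_trace[1:]))

    def test_independent_covariate_coefficient_near_zero(self):
        rng = np.random.default_rng(11)
        n = 2000
        X = pd.DataFrame({"x": rng.integers(0, 2, size=n).astype(float)})
        t = rng.exponential(1.0, size=n)
        e = np.ones(n, int)
        res = cox_fit(X, t, e)
        assert abs(res.coef["x"]) < 0.1

    def test_true_hazard_ratio_two_recovered(self):
        rng = np.random.default_rng(12)
        n = 2000
        g = rng.integers(0, 2, size=n).astype(float)
        t = rng.exponential(1.0 / np.exp(np.log(2) * g))
        res = cox_fit(pd.DataFrame({"g": g}), t, np.ones(n, int))
        assert abs(res.coef["g"] - np.log(2)) < 0.1

    def test_matches_lifelines_without_ties(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(13)
        n = 150
        df = pd.DataFrame({
            "x1": rng.normal(size=n),
            "x2": rng.integers(0, 2, size=n).astype(float),
        })
        t = rng.exponential(1.0 / np.exp(0.8 * df.x1 - 0.5 * df.x2))
        e = (rng.random(n) < 0.8).astype(int)
        ours = cox_fit(df, t, e)
        lf = df.assign(T=t, E=e)
        cph = CoxPHFitter().fit(lf, "T", "E")
        for c in df.columns:
            assert ours.coef[c] == pytest.approx(cph.params_[c], abs=1e-4)
            assert ours.summary.loc[c, "se"] == pytest.approx(cph.standard_errors_[c], abs=1e-4)

    def test_constant_covariate_rejected(self):
        X = pd.DataFrame({"c": [1.0] * 10})
        with pytest.raises(ValueError, match="constant"):
            cox_fit(X, np.arange(1, 11), np.ones(10, int))

    def test_perfect_separation_raises(self):
        # covariate perfectly orders events: monotone likelihood
        n = 40
        x = np.arange(n, dtype=float)
        t = np.arange(n, 0, -1, dtype=float)
        with pytest.raises(RuntimeError):
            cox_fit(pd.DataFrame({"x": x}), t, np.ones(n, int))

    def test_direction_agrees_with_logrank(self):
        rng = np.random.default_rng(14)
        for s in range(5):
            n = 80
            g = rng.integers(0, 2, size=n)
            t = rng.exponential(1.0 / np.exp(1.0 * g))
            e = np.ones(n, int)
            res = cox_fit(pd.DataFrame({"g": g.astype(float)}), t, e)
            lr = logrank(t, e, g)
            km_g = km_by_group(t, e, g)
            med0 = survival_at(km_g[0], np.median(t))
            med1 = survival_at(km_g[1], np.median(t))
            assert (res.coef["g"] > 0) == (med1 < med0)
            assert lr.p < 0.05
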