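"""Prevalence filter, clustering, SAM, paired t and Fisher enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mirclone.stats import (
    cluster,
    fisher_enrichment,
    paired_t,
    prevalence_filter,
    sam_test,
)


def make_matrix(data, samples=None):
    df = pd.DataFrame(data)
    if samples:
        df.columns = samples
    return df


class TestPrevalence:
    @pytest.mark.parametrize(
        "row, n_samples, kept",
        [
            ([5, 0, 0, 0], 4, True),   # exactly 25% is retained
            ([0, 0, 0, 0], 4, False),
            ([5, 0, 0, 0, 0, 0, 0, 0], 8, False),  # 12.5% dropped
            ([5, 5, 0, 0], 4, True),
        ],
    )
    def test_threshold(self, row, n_samples, kept):
        m = pd.DataFrame([row], index=["x"])
        out = prevalence_filter(m)
        assert ("x" in out.index) is kept


GROUPS4 = {"T1": "HCC", "T2": "HCC", "N1": "ANL", "N2": "ANL"}


class TestCluster:
    def test_identical_samples_merge_at_zero(self):
        rng = np.random.default_rng(0)
        base = rng.lognormal(3, 1, size=20)
        m = pd.DataFrame({"A": base, "B": base, "C": base * 0 + rng.lognormal(3, 1, 20)})
        res = cluster(m, {s: "HCC" for s in m.columns}, k=2)
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_two_gaussian_groups_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(1)
        g1 = rng.normal(0, 1, size=(40, 8))
        g2 = rng.normal(4, 1, size=(40, 8))
        X = np.vstack([np.hstack([g1, g2]), np.hstack([g2, g1])])
        m = pd.DataFrame(2.0 ** X, columns=[f"s{i}" for i in range(16)])
        res = cluster(m, {c: "HCC" for c in m.columns}, k=2)
        truth = [0] * 8 + [1] * 8
        assert adjusted_rand_score(truth, res.labels.to_numpy()) == 1.0

    def test_highrisk_flag_on_marker_high_all_tumor_cluster(self):
        rng = np.random.default_rng(2)
        cols = ["T1", "T2", "T3", "N1", "N2", "N3"]
        groups = {c: ("HCC" if c.startswith("T") else "ANL") for c in cols}
        base = rng.lognormal(4, 0.5, size=20)
        m = pd.DataFrame({c: base * rng.lognormal(0, 0.05, 20) for c in cols})
        m.index = [f"g{i}" for i in range(19)] + ["marker"]
        # tumors share a distinct signature and high marker
        for c in ["T1", "T2", "T3"]:
            m.loc["g0":"g5", c] *= 8
            m.loc["marker", c] = 400
        for c in ["N1", "N2", "N3"]:
            m.loc["marker", c] = 50
        res = cluster(m, groups, marker="marker", marker_threshold=250, k=2)
        assert sorted(res.high_risk_samples) == ["T1", "T2", "T3"]

    def test_constant_profile_distance_defined(self):
        m = pd.DataFrame({"A": [1.0, 1, 1], "B": [1.0, 2, 3], "C": [3.0, 2, 1]})
        res = cluster(m, {c: "HCC" for c in m.columns}, k=2)  # must not raise
        assert len(res.labels) == 3

    def test_global_scaling_invariance(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.lognormal(3, 1, size=(30, 10)),
                         columns=[f"s{i}" for i in range(10)])
        r1 = cluster(m, {c: "HCC" for c in m.columns}, k=3, log_transform=False)
        r2 = cluster(m * 7.5, {c: "HCC" for c in m.columns}, k=3, log_transform=False)
        assert (r1.labels == r2.labels).all()


def null_matrix(rng, G, npairs):
    base = rng.lognormal(3, 1, size=G)
    X = base[:, None] * 2.0 ** rng.normal(0, 1, size=(G, 2 * npairs))
    cols = [f"P{i:02d}{s}" for i in range(npairs) for s in "TN"]
    return pd.DataFrame(X, index=[f"g{j}" for j in range(G)], columns=cols)


def sam_design(npairs):
    groups = {}
    pairs = {}
    for i in range(npairs):
        groups[f"P{i:02d}T"] = "HCC"
        groups[f"P{i:02d}N"] = "ANL"
        pairs[f"P{i:02d}T"] = pairs[f"P{i:02d}N"] = f"P{i:02d}"
    return groups, pairs


class TestSam:
    def test_equal_group_means_give_zero_d(self):
        groups, pairs = sam_design(4)
        m = null_matrix(np.random.default_rng(0), 10, 4)
        m.iloc[0] = 12.0  # identical everywhere
        res = sam_test(m, groups, pairs, n_perm=50, seed=0)
        assert res.d.iloc[0] == pytest.approx(0.0)

    def test_sample_relabeling_within_groups_invariant(self):
        groups, pairs = sam_design(6)
        m = null_matrix(np.random.default_rng(1), 40, 6)
        res1 = sam_test(m, groups, pairs, n_perm=64, seed=3)
        # permute pair order (relabeling pairs wholesale)
        perm = list(m.columns)
        perm = perm[4:] + perm[:4]
        res2 = sam_test(m[perm], groups, pairs, n_perm=64, seed=3)
        assert np.allclose(np.sort(res1.d), np.sort(res2.d))

    def test_global_null_mostly_zero_calls(self):
        groups, pairs = sam_design(10)
        zero = 0
        n_seeds = 25
        for s in range(n_seeds):
            m = null_matrix(np.random.default_rng(100 + s), 100, 10)
            res = sam_test(m, groups, pairs, n_perm=100, seed=s)
            zero += len(res.significant) == 0
        assert zero >= 0.9 * n_seeds

    def test_planted_fourfold_genes_recovered(self):
        groups, pairs = sam_design(18)
        rng = np.random.default_rng(7)
        m = null_matrix(rng, 200, 18)
        tumors = [c for c in m.columns if c.endswith("T")]
        planted = m.index[:20]
        m.loc[planted, tumors] *= 4.0
        res = sam_test(m, groups, pairs, n_perm=200, seed=7)
        sens = len(set(planted) & set(res.significant)) / len(planted)
        assert sens >= 0.8
        assert res.fp_median == 0

    def test_unpaired_mode_runs(self):
        groups, _ = sam_design(6)
        m = null_matrix(np.random.default_rng(2), 50, 6)
        res = sam_test(m, groups, paired=False, n_perm=100, seed=0)
        assert len(res.d) == 50

    def test_small_group_rejected(self):
        m = null_matrix(np.random.default_rng(0), 10, 1)
        groups, pairs = sam_design(1)
        with pytest.raises(ValueError):
            sam_test(m, groups, pairs)


class TestPairedT:
    def test_zero_differences_flagged_p_one(self):
        groups, pairs = sam_design(4)
        m = null_matrix(np.random.default_rng(0), 3, 4)
        m.iloc[0] = 5.0
        out = paired_t(m, groups, pairs)
        assert out.iloc[0].t == 0 and out.iloc[0].p == 1 and out.iloc[0].flagged

    def test_constant_nonzero_difference_undefined(self):
        groups, pairs = sam_design(4)
        vals = {}
        for i in range(4):
            vals[f"P{i:02d}T"] = [3.0]
            vals[f"P{i:02d}N"] = [1.0]
        m = pd.DataFrame(vals, index=["g0"])
        out = paired_t(m, groups, pairs)
        assert np.isnan(out.iloc[0].p) and out.iloc[0].flagged

    def test_incomplete_pairs_listed(self):
        groups, pairs = sam_design(3)
        m = null_matrix(np.random.default_rng(0), 5, 3).drop(columns=["P01N"])
        with pytest.raises(ValueError, match="P01"):
            paired_t(m, groups, {k: v for k, v in pairs.items() if k != "P01N"})

    def test_null_pvalues_uniform(self):
        groups, pairs = sam_design(10)
        m = null_matrix(np.random.default_rng(11), 5000, 10)
        out = paired_t(m, groups, pairs)
        ks = sps.kstest(out.p.dropna(), "uniform")
        assert ks.pvalue > 0.01


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by enumerating all tables with fixed margins."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    p_obs = sps.hypergeom.pmf(a, n, row1, col1)
    total = 0.0
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        pk = sps.hypergeom.pmf(k, n, row1, col1)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return total


class TestFisher:
    def test_example_8_2_2_8(self):
        universe = set(range(20))
        target = set(range(10))
        term = set(range(8)) | {10, 11}
        out = fisher_enrichment(target, universe, {"t": term})
        assert out.p.iloc[0] == pytest.approx(fisher_oracle(8, 2, 2, 8))

    def test_matches_enumeration_for_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            a, b, c, d = rng.integers(0, 12, size=4)
            if (a + b) == 0 or (a + c) == 0:
                continue
            n = a + b + c + d
            universe = set(range(n))
            target = set(range(a + b))
            term = set(range(a)) | set(range(a + b, a + b + c))
            out = fisher_enrichment(target, universe, {"t": term})
            assert out.p.iloc[0] == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-9)

    def test_exact_term_is_most_significant(self):
        universe = set(range(100))
        target = set(range(10))
        terms = {"exact": set(target), "half": set(range(5)) | set(range(50, 55)),
                 "off": set(range(60, 70))}
        out = fisher_enrichment(target, universe, terms)
        assert out.term.iloc[0] == "exact"
        assert out.p.is_monotonic_increasing

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment(set(), {1, 2}, {"t": {1}})
        with pytest.raises(ValueError):
            fisher_enrichment({99}, {1, 2}, {"t": {1}})
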