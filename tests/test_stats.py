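"""Nonparametric statistics against independent brute-force oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import gliohab as gh
from gliohab.classify import LabelComposition, log_ratio
from gliohab.stats import CategoryMap


# ---------------------------------------------------------------------------
# Independent oracles


def mwu_oracle(x, y):
    """Exact two-sided MWU p by enumerating every split of the pooled values.

    U is computed by direct pairwise comparison (ties count 1/2), not ranks.
    """
    x, y = list(x), list(y)
    pooled = x + y
    nx, n = len(x), len(pooled)

    def u_of(sample_x, sample_y):
        return sum(1.0 if a > b else (0.5 if a == b else 0.0)
                   for a in sample_x for b in sample_y)

    u_obs = u_of(x, y)
    us = []
    for idx in combinations(range(n), nx):
        sx = [pooled[i] for i in idx]
        sy = [pooled[i] for i in range(n) if i not in idx]
        us.append(u_of(sx, sy))
    us = np.array(us)
    lo = np.mean(us <= u_obs + 1e-9)
    hi = np.mean(us >= u_obs - 1e-9)
    return u_obs, min(1.0, 2.0 * min(lo, hi))


def bh_oracle(pvals):
    """Step-up BH by the textbook recursion."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        prev = min(prev, p[i] * m / rank_from_top)
        adj[i] = prev
    return adj


class TestMannWhitney:
    def test_spec_example_exact_third(self):
        u, p = gh.mann_whitney_u([1.2, 3.4], [5.6, 7.8])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_identical_samples_p_one(self):
        _, p = gh.mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_exact_matches_enumeration_all_small_splits(self):
        """Every two-sample split of 1..8 (distinct values) agrees with the
        full-permutation oracle."""
        values = list(range(1, 9))
        for nx in range(1, 8):
            for idx in combinations(range(8), nx):
                x = [values[i] for i in idx]
                y = [values[i] for i in range(8) if i not in idx]
                u_ref, p_ref = mwu_oracle(x, y)
                u, p = gh.mann_whitney_u(x, y)
                assert u == pytest.approx(u_ref)
                assert p == pytest.approx(p_ref)

    def test_exact_with_ties_matches_enumeration(self, rng):
        for _ in range(10):
            x = rng.integers(0, 4, size=4).astype(float)
            y = rng.integers(0, 4, size=5).astype(float)
            u_ref, p_ref = mwu_oracle(x, y)
            u, p = gh.mann_whitney_u(x, y)
            assert u == pytest.approx(u_ref)
            assert p == pytest.approx(p_ref)

    def test_normal_approximation_close_to_exact(self, rng):
        """At n=6+6 the tie/continuity-corrected normal p is within 0.02 of
        enumeration on seeded draws (spec-level agreement check)."""
        import gliohab.stats as gstats
        for seed in range(20):
            r = np.random.default_rng(seed)
            x = r.normal(size=6)
            y = r.normal(0.5, size=6)
            _, p_exact = gh.mann_whitney_u(x, y)
            old = gstats.EXACT_N_MAX
            try:
                gstats.EXACT_N_MAX = 0  # force the approximation path
                _, p_approx = gh.mann_whitney_u(x, y)
            finally:
                gstats.EXACT_N_MAX = old
            assert abs(p_approx - p_exact) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            gh.mann_whitney_u([], [1.0])


class TestBenjaminiHochberg:
    @pytest.mark.parametrize("pvals,expected", [
        ([0.3], [0.3]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.005, 0.5], [0.01, 0.5]),
    ])
    def test_step_up_arithmetic(self, pvals, expected):
        np.testing.assert_allclose(gh.benjamini_hochberg(pvals), expected)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 12))
            np.testing.assert_allclose(gh.benjamini_hochberg(p), bh_oracle(p),
                                       atol=1e-12)

    def test_monotone_capped_and_dominating(self, rng):
        p = np.sort(rng.uniform(size=10))
        adj = gh.benjamini_hochberg(p)
        assert np.all(np.diff(adj) >= -1e-12)  # monotone in order statistics
        assert np.all(adj <= 1.0)
        assert np.all(adj >= p - 1e-12)  # adjustment never shrinks a p value

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            gh.benjamini_hochberg([0.5, 1.5])


# ---------------------------------------------------------------------------
# Categorization


def _comps(mut_logratios, wt_logratios):
    comps = []
    for i, lr in enumerate(mut_logratios):
        p = np.full(len(lr), 100.0 / len(lr))
        comps.append(LabelComposition(f"m{i}", p, np.asarray(lr, float),
                                      idh_status="mutant"))
    for i, lr in enumerate(wt_logratios):
        p = np.full(len(lr), 100.0 / len(lr))
        comps.append(LabelComposition(f"w{i}", p, np.asarray(lr, float),
                                      idh_status="wildtype"))
    return comps


class TestCategorizeLabels:
    def test_planted_shift_gives_M(self, rng):
        K = 6
        mut = [rng.normal(0, 0.2, K) + np.eye(K)[0] * 3 for _ in range(15)]
        wt = [rng.normal(0, 0.2, K) for _ in range(15)]
        cat = gh.categorize_labels(_comps(mut, wt))
        assert cat.categories[1] == "M"

    def test_identical_distributions_give_N(self, rng):
        K = 4
        vals = [rng.normal(0, 1, K) for _ in range(20)]
        cat = gh.categorize_labels(_comps(vals[:10], vals[10:]))
        assert set(cat.categories.values()) == {"N"}

    def test_null_mostly_all_N_across_seeds(self):
        """Under the null, BH at alpha=0.05 leaves all labels N in >=90% of
        20 seeded replicates."""
        all_n = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            mut = [r.normal(0, 1, 8) for _ in range(12)]
            wt = [r.normal(0, 1, 8) for _ in range(12)]
            cat = gh.categorize_labels(_comps(mut, wt))
            all_n += set(cat.categories.values()) == {"N"}
        assert all_n >= 18

    def test_equivariant_under_relabeling(self, rng):
        K = 5
        mut = [rng.normal(0, 0.3, K) + np.array([2, 0, 0, 0, -2]) for _ in range(10)]
        wt = [rng.normal(0, 0.3, K) for _ in range(10)]
        cat = gh.categorize_labels(_comps(mut, wt))
        perm = np.array([3, 0, 4, 1, 2])
        cat_p = gh.categorize_labels(_comps([m[perm] for m in mut],
                                            [w[perm] for w in wt]))
        for k in range(K):
            assert cat_p.categories[k + 1] == cat.categories[perm[k] + 1]

    def test_single_class_rejected(self, rng):
        comps = _comps([rng.normal(size=3)] * 4, [])
        with pytest.raises(ValueError, match="each IDH class"):
            gh.categorize_labels(comps)


class TestMajorityCategory:
    def _catmap(self, cats):
        K = len(cats)
        return CategoryMap(categories={k + 1: c for k, c in enumerate(cats)},
                           raw_p={k + 1: 0.5 for k in range(K)},
                           adjusted_p={k + 1: 0.5 for k in range(K)},
                           direction={k + 1: "mutant" for k in range(K)})

    def _labeled(self, labels):
        return gh.LabeledTumorVolume("b", np.asarray(labels), int(np.max(labels)))

    def test_majority_wins(self):
        labels = np.zeros((5, 5, 1), int)
        labels[:3] = 1   # 60% of sphere -> W
        labels[3:] = 2   # 40% -> N
        cat = gh.majority_category(self._labeled(labels), self._catmap(["W", "N"]),
                                   center=(2, 2, 0), radius=10)
        assert cat == "W"

    def test_pure_sphere(self):
        labels = np.full((4, 4, 1), 2, int)
        cat = gh.majority_category(self._labeled(labels), self._catmap(["M", "N"]),
                                   center=(1, 1, 0), radius=2)
        assert cat == "N"

    def test_exact_tie_precedence_W_over_M(self):
        labels = np.zeros((4, 2, 1), int)
        labels[:2] = 1  # M
        labels[2:] = 2  # W
        cat = gh.majority_category(self._labeled(labels), self._catmap(["M", "W"]),
                                   center=(1.5, 0.5, 0), radius=10)
        assert cat == "W"

    def test_empty_sphere_rejected(self):
        labels = np.zeros((4, 4, 1), int)
        with pytest.raises(ValueError, match="no labeled"):
            gh.majority_category(self._labeled(labels + 0), self._catmap(["M"]),
                                 center=(0, 0, 0), radius=1)


# ---------------------------------------------------------------------------
# K-sample tests


class TestKruskalWallisDunn:
    def test_identical_groups_H_zero(self):
        h, p, dunn = gh.kruskal_wallis_dunn([[1, 2, 3]] * 3)
        assert h == pytest.approx(0.0)
        assert np.all(dunn["p_adjusted"] == 1.0)

    def test_H_matches_rank_formula(self, rng):
        groups = [rng.normal(size=3), rng.normal(1, 1, 3), rng.normal(2, 1, 3)]
        h, _, _ = gh.kruskal_wallis_dunn(groups)
        # hand rank arithmetic (no ties in continuous draws)
        pooled = np.concatenate(groups)
        ranks = sps.rankdata(pooled)
        n = len(pooled)
        r_sums = [ranks[:3].sum(), ranks[3:6].sum(), ranks[6:].sum()]
        h_ref = 12.0 / (n * (n + 1)) * sum(r**2 / 3 for r in r_sums) - 3 * (n + 1)
        assert h == pytest.approx(h_ref)

    def test_shifted_group_has_smallest_dunn_p(self, rng):
        groups = [rng.normal(0, 1, 8), rng.normal(0, 1, 8), rng.normal(12, 1, 8)]
        _, _, dunn = gh.kruskal_wallis_dunn(groups)
        involving_2 = dunn[(dunn["group_i"] == 2) | (dunn["group_j"] == 2)]
        others = dunn[(dunn["group_i"] != 2) & (dunn["group_j"] != 2)]
        assert involving_2["p_adjusted"].max() < others["p_adjusted"].min()

    def test_two_groups_redirected(self):
        with pytest.raises(ValueError, match="mann_whitney_u"):
            gh.kruskal_wallis_dunn([[1, 2], [3, 4]])


class TestAnovaTukey:
    def test_two_group_F_equals_t_squared(self, rng):
        x, y = rng.normal(size=10), rng.normal(0.5, 1.0, 10)
        f, p, _ = gh.anova_tukey([x, y])
        t, _ = sps.ttest_ind(x, y)
        assert f == pytest.approx(t**2, rel=1e-9)

    def test_identical_groups_no_significance(self, rng):
        g = rng.normal(size=12)
        f, p, tbl = gh.anova_tukey([g, g.copy(), g.copy()])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert not tbl["reject"].any()

    def test_planted_shift_flagged(self, rng):
        g1 = rng.normal(0, 1, 12)
        g2 = rng.normal(0, 1, 12)
        g3 = rng.normal(5, 1, 12)  # 5-sd shift
        _, _, tbl = gh.anova_tukey([g1, g2, g3])
        flagged = tbl[tbl["reject"]]
        assert set(map(tuple, flagged[["group_i", "group_j"]].values)) == {(0, 2), (1, 2)}

    def test_degenerate_identical_constant_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            gh.anova_tukey([[1.0, 1.0], [1.0, 1.0]])


# ---------------------------------------------------------------------------
# Histology comparisons


def _records(rng, n_per_cat=6, w_marker_boost=0.0):
    rows = []
    markers = ["HIF1a", "GLUT3", "HK2", "MCT1", "LDHA", "Ki67"]
    sid = 0
    for cat in ["M", "N", "W"]:
        for _ in range(n_per_cat):
            row = {"subject_id": f"s{sid}", "category": cat}
            for m in markers:
                base = abs(rng.normal(5, 2))
                if cat == "W" and m == "HIF1a":
                    base += w_marker_boost
                row[m] = base
            rows.append(row)
            sid += 1
    statuses = {f"s{i}": ("mutant" if i % 2 == 0 else "wildtype")
                for i in range(sid)}
    return pd.DataFrame(rows), markers, statuses


class TestCompareHistology:
    def test_identical_markers_nothing_significant(self, rng):
        records, markers, statuses = _records(rng)
        # identical marker values in every record: no test can fire
        for m in markers:
            records[m] = float(markers.index(m))
        records[markers[0]] = np.tile([1.0, 2.0, 3.0], len(records) // 3)
        res = gh.compare_histology(records, markers, statuses)
        for m in markers[1:]:
            assert res["across_categories"][m]["p"] == pytest.approx(1.0)
        assert res["across_categories"][markers[0]]["p"] > 0.9
        assert (res["overall"]["p"] > 0.9).all()

    def test_planted_W_marker_flagged_vs_M(self, rng):
        records, markers, statuses = _records(rng, w_marker_boost=30.0)
        res = gh.compare_histology(records, markers, statuses)
        dunn = res["across_categories"]["HIF1a"]["dunn"]
        wm = dunn[((dunn["group_i"] == "M") & (dunn["group_j"] == "W")) |
                  ((dunn["group_i"] == "W") & (dunn["group_j"] == "M"))]
        assert (wm["p_adjusted"] < 0.05).all()

    def test_single_category_rejected(self, rng):
        records, markers, statuses = _records(rng)
        only_m = records[records["category"] == "M"]
        with pytest.raises(ValueError, match="categories"):
            gh.compare_histology(only_m, markers, statuses)
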