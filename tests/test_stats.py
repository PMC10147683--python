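"""Bespoke statistics against closed forms, oracles and library cross-checks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from tfdep.stats import (
    bh_adjust,
    gsea_preranked,
    multiset_intersection_test,
    observed_expected_chi2,
    ora_collection,
    ora_test,
    spearman,
)


class TestMultiSet:
    def test_two_set_closed_form(self):
        """m=2, N=10, sizes (5, 4), observed 4: hypergeometric tail 5/210."""
        a = {"g1", "g2", "g3", "g4", "g5"}
        b = {"g1", "g2", "g3", "g4"}
        r = multiset_intersection_test([a, b], 10)
        assert r.expected == pytest.approx(2.0)
        assert r.fold == pytest.approx(2.0)
        assert r.p == pytest.approx(5 / 210, rel=1e-12)

    def test_fold_one_when_observed_equals_expected(self):
        # N=8, sizes 4 and 4 -> expected 2; construct overlap exactly 2
        a = {"a", "b", "c", "d"}
        b = {"c", "d", "e", "f"}
        r = multiset_intersection_test([a, b], 8)
        assert r.fold == pytest.approx(1.0)

    def test_two_set_equals_hypergeom_fuzz(self):
        """Exact DP reduces to the hypergeometric upper tail for m=2."""
        rng = np.random.default_rng(12)
        universe = [f"g{i}" for i in range(200)]
        for _ in range(60):
            N = int(rng.integers(5, 200))
            n1 = int(rng.integers(1, N + 1))
            n2 = int(rng.integers(1, N + 1))
            a = set(rng.choice(universe[:N], size=n1, replace=False))
            b = set(rng.choice(universe[:N], size=n2, replace=False))
            r = multiset_intersection_test([a, b], N)
            k = len(a & b)
            expected_p = float(sps.hypergeom.sf(k - 1, N, n1, n2))
            assert r.p == pytest.approx(expected_p, rel=1e-10, abs=1e-300)

    def test_three_set_monte_carlo_oracle(self):
        """m=3, N=30, sizes (12, 10, 8): exact tail vs simulation."""
        rng = np.random.default_rng(11)
        N, sizes, observed = 30, (12, 10, 8), 6
        n_draws = 100_000
        # vectorized draws: a random n-subset = smallest n keys of a
        # uniform vector; membership indicator per element of the universe
        member = np.ones((n_draws, N), dtype=bool)
        for n in sizes:
            keys = rng.random((n_draws, N))
            thresh = np.partition(keys, n - 1, axis=1)[:, n - 1 : n]
            member &= keys <= thresh
        mc_p = float((member.sum(axis=1) >= observed).mean())
        labels = [f"g{i}" for i in range(N)]
        s1 = set(labels[: sizes[0]])
        s2 = set(labels[: observed]) | set(labels[sizes[0] : sizes[0] + sizes[1] - observed])
        s3 = set(labels[: observed]) | set(labels[20 : 20 + sizes[2] - observed])
        assert len(s1 & s2 & s3) == observed
        r = multiset_intersection_test([s1, s2, s3], N)
        se = math.sqrt(mc_p * (1 - mc_p) / n_draws)
        assert abs(r.p - mc_p) < 3 * se

    def test_p_monotone_in_observed(self):
        labels = [f"g{i}" for i in range(40)]
        ps = []
        for obs in range(2, 9):
            s1 = set(labels[:12])
            s2 = set(labels[:obs]) | set(labels[12 : 12 + 10 - obs])
            ps.append(multiset_intersection_test([s1, s2], 40).p)
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_set_larger_than_universe_rejected(self):
        with pytest.raises(ValueError):
            multiset_intersection_test([{"a", "b"}, {"a"}], 1)


class TestChi2:
    def test_hand_example(self):
        r = observed_expected_chi2([[30, 70], [10, 190]])
        assert r.expected[0, 0] == pytest.approx(100 * 40 / 300)
        assert r.oe_ratio == pytest.approx(30 / (100 * 40 / 300))
        # textbook Pearson: (ad-bc)^2 n / (r1 r2 c1 c2)
        assert r.chi2 == pytest.approx(
            (30 * 190 - 70 * 10) ** 2 * 300 / (100 * 200 * 40 * 260))
        assert r.chi2 == pytest.approx(36.06, abs=0.01)

    def test_independent_table_chi2_zero(self):
        r = observed_expected_chi2([[10, 20], [20, 40]])
        assert r.chi2 == pytest.approx(0.0)
        assert r.oe_ratio == pytest.approx(1.0)
        assert r.p == pytest.approx(1.0)

    def test_transpose_invariance(self):
        t = [[13, 7], [5, 21]]
        assert observed_expected_chi2(t).chi2 == pytest.approx(
            observed_expected_chi2(np.transpose(t)).chi2)

    def test_matches_textbook_formula_fuzz(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            a, b, c, d = rng.integers(1, 500, size=4)
            r = observed_expected_chi2([[a, b], [c, d]])
            n = a + b + c + d
            expected = (a * d - b * c) ** 2 * n / (
                (a + b) * (c + d) * (a + c) * (b + d))
            assert r.chi2 == pytest.approx(expected, rel=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            observed_expected_chi2([[0, 0], [5, 10]])

    def test_extreme_table_keeps_log_p(self):
        """p-values far below float underflow keep a finite magnitude."""
        r = observed_expected_chi2([[4000, 1000], [1000, 4000]])
        assert r.p == 0.0 or r.p < 1e-300
        assert -2000 < r.log10_p < -300


class TestOra:
    def test_query_equals_universe(self):
        u = {f"g{i}" for i in range(12)}
        k, fold, p = ora_test(u, u, u)
        assert k == 12 and p == pytest.approx(1.0)

    def test_perfect_overlap_closed_form(self):
        universe = [f"g{i}" for i in range(20)]
        q = set(universe[:5])
        k, fold, p = ora_test(q, q, universe)
        assert k == 5
        assert p == pytest.approx(1 / math.comb(20, 5), rel=1e-12)

    def test_zero_overlap(self):
        universe = [f"g{i}" for i in range(10)]
        k, fold, p = ora_test(set(universe[:3]), set(universe[5:8]), universe)
        assert k == 0 and fold == 0.0 and p == pytest.approx(1.0)

    def test_collection_bh_adjusted(self):
        universe = [f"g{i}" for i in range(50)]
        coll = {"A": set(universe[:5]), "B": set(universe[10:15])}
        df = ora_collection(set(universe[:5]), coll, universe)
        assert (df["adj_p"] >= df["p"] - 1e-15).all()


class TestGsea:
    RANKED = {"g1": 3.0, "g2": 2.0, "g3": 1.0, "g4": -1.0, "g5": -2.0}

    def test_hand_example_es_one(self):
        r = gsea_preranked(self.RANKED, {"g1", "g2"}, n_perm=10, seed=0)
        assert r.es == pytest.approx(1.0)

    def test_running_sum_intermediate_value(self):
        # set {g1} alone: running sum peaks at 1.0 after the first gene
        r = gsea_preranked(self.RANKED, {"g1"}, n_perm=10, seed=0)
        assert r.es == pytest.approx(1.0)
        # set {g5}: the only hit sits last; sum first dives to -4/4 = -1.0
        r2 = gsea_preranked(self.RANKED, {"g5"}, n_perm=10, seed=0)
        assert r2.es == pytest.approx(-1.0)

    def test_full_set_degenerate(self):
        r = gsea_preranked(self.RANKED, set(self.RANKED), n_perm=10, seed=0)
        assert r.degenerate and r.es == 1.0

    def test_disjoint_set_errors(self):
        with pytest.raises(ValueError, match="no genes"):
            gsea_preranked(self.RANKED, {"zz"}, n_perm=10, seed=0)

    def test_scale_invariance(self):
        scaled = {g: 10.0 * s for g, s in self.RANKED.items()}
        a = gsea_preranked(self.RANKED, {"g1", "g3"}, n_perm=50, seed=4)
        b = gsea_preranked(scaled, {"g1", "g3"}, n_perm=50, seed=4)
        assert a.es == pytest.approx(b.es)
        assert a.p == b.p

    def test_seed_determinism(self):
        a = gsea_preranked(self.RANKED, {"g2", "g4"}, n_perm=200, seed=9)
        b = gsea_preranked(self.RANKED, {"g2", "g4"}, n_perm=200, seed=9)
        assert (a.es, a.p) == (b.es, b.p)

    def test_planted_set_detected(self):
        """A set planted at the top of a 500-gene ranking scores near 1
        with a small permutation p."""
        rng = np.random.default_rng(2)
        scores = np.sort(rng.normal(size=500))[::-1]
        ranked = {f"g{i}": float(s) for i, s in enumerate(scores)}
        r = gsea_preranked(ranked, {f"g{i}" for i in range(15)},
                           n_perm=2000, seed=2)
        assert r.es > 0.8
        assert r.p < 0.01


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman(x, [2 * v for v in x])[0] == pytest.approx(1.0)
        assert spearman(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_hand_rank_example(self):
        """x=(1..5), y=(2,1,4,3,5): d^2 sums to 4, rho = 1 - 24/120 = 0.8."""
        rho, p = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8)
        scipy_rho = sps.spearmanr([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]).statistic
        assert rho == pytest.approx(float(scipy_rho))

    def test_exact_permutation_p_small_n(self):
        # perfectly concordant n=4: only orderings with rho >= 1 count
        rho, p = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert p == pytest.approx(2 / 24)  # +1 and -1 orderings, two-sided

    def test_large_n_matches_scipy(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=60)
        y = x + rng.normal(size=60)
        rho, p = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(float(ref.statistic), rel=1e-12)
        assert p == pytest.approx(float(ref.pvalue), rel=1e-6)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1], [1, 2, 3])


class TestBh:
    def test_hand_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_all_ones_and_singleton(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
        assert bh_adjust([0.3]).tolist() == [0.3]

    def test_never_below_raw_and_order_preserving(self):
        rng = np.random.default_rng(6)
        p = rng.random(500)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_matches_statsmodels(self):
        """Independent library cross-check of the step-up procedure."""
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(9)
        p = rng.random(200) ** 2
        ours = bh_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50))
    def test_output_in_unit_interval(self, p):
        adj = bh_adjust(p)
        assert ((adj >= 0) & (adj <= 1)).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
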