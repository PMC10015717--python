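import math

import numpy as np
import pytest
from scipy import stats as sps

from devstab import compare_groups, kruskal_wallis, spearman_test, steel_dwass


class TestSpearman:
    def test_perfect_monotone(self):
        r = spearman_test([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert r.rho == pytest.approx(1.0)
        r = spearman_test([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert r.rho == pytest.approx(-1.0)

    def test_hand_computed_rho(self):
        # x=(1..5), y=(1,3,2,5,4): d = (0,1,-1,1,-1), sum d^2 = 4
        # -> rho = 1 - 6*4/(5*24) = 0.8
        r = spearman_test([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert r.rho == pytest.approx(0.8)
        assert r.n == 5

    def test_t_approximation_matches_scipy(self, rng):
        x = rng.normal(size=200)
        y = 0.3 * x + rng.normal(size=200)
        mine = spearman_test(x, y)
        ref = sps.spearmanr(x, y)
        assert mine.rho == pytest.approx(ref.statistic)
        assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        r1 = spearman_test(x, y)
        r2 = spearman_test(np.exp(x), y**3)
        assert r1.rho == pytest.approx(r2.rho)

    def test_exact_mode_against_enumeration_probability(self):
        # for n=3 with rho=1 the exact two-sided p is 2/6
        r = spearman_test([1, 2, 3], [1, 2, 3], method="exact")
        assert r.p_value == pytest.approx(2 / 6)

    def test_constant_input_errors(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_test([1, 1, 1], [1, 2, 3])

    def test_short_input_errors(self):
        with pytest.raises(ValueError, match="n >= 3"):
            spearman_test([1, 2], [3, 4])


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        h, p = kruskal_wallis([[1, 1], [1, 1], [1, 1]])
        assert h == 0.0
        assert p == 1.0

    def test_hand_ranked_three_groups(self):
        # ranks 1..6, rank sums (3, 7, 11): H = 12/42*(4.5+24.5+60.5) - 21
        h, p = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert h == pytest.approx(12 / 42 * (4.5 + 24.5 + 60.5) - 21)
        assert p == pytest.approx(float(sps.chi2.sf(h, 2)))

    def test_monotone_transform_invariance(self, rng):
        groups = [rng.normal(size=8), rng.normal(1, 1, size=6), rng.normal(size=7)]
        h1, _ = kruskal_wallis(groups)
        h2, _ = kruskal_wallis([np.exp(g) for g in groups])
        assert h1 == pytest.approx(h2)

    def test_fewer_than_two_groups_errors(self):
        with pytest.raises(ValueError, match=">=2 groups"):
            kruskal_wallis([[1, 2, 3]])


class TestSteelDwass:
    def test_identical_pair_has_p_near_one(self, rng):
        g = rng.normal(size=10)
        res = steel_dwass([g, g.copy(), rng.normal(5, 1, 10), rng.normal(9, 1, 10)])
        by_pair = {(a, b): p for a, b, _, p in res}
        assert by_pair[("group0", "group1")] > 0.99

    def test_fully_separated_pair_significant(self, rng):
        groups = [rng.normal(0, 0.1, 10), rng.normal(5, 0.1, 10),
                  rng.normal(10, 0.1, 10), rng.normal(15, 0.1, 10)]
        res = steel_dwass(groups)
        assert all(p < 0.01 for _, _, _, p in res)

    def test_covers_all_unordered_pairs(self, rng):
        res = steel_dwass([rng.normal(size=5) for _ in range(4)],
                          labels=list("abcd"))
        assert {(a, b) for a, b, _, _ in res} == {
            ("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d"), ("c", "d")
        }

    def test_k2_reduces_to_two_sided_normal(self, rng):
        # for two groups the studentized-range tail equals the two-sided
        # normal tail of z
        a, b = rng.normal(size=12), rng.normal(0.8, 1, size=12)
        ((_, _, z, p),) = steel_dwass([a, b])
        assert p == pytest.approx(2 * float(sps.norm.sf(abs(z))), rel=1e-6)

    def test_permutation_method_deterministic_and_close_to_asymptotic(self, rng):
        groups = [rng.normal(s, 1, 12) for s in (0, 0.5, 1.0, 1.5)]
        p1 = steel_dwass(groups, method="permutation", seed=3)
        p2 = steel_dwass(groups, method="permutation", seed=3)
        assert p1 == p2
        asym = steel_dwass(groups)
        for (_, _, _, pp), (_, _, _, pa) in zip(p1, asym):
            assert pp == pytest.approx(pa, abs=0.06)

    def test_small_group_errors(self, rng):
        with pytest.raises(ValueError, match=">=2 values"):
            steel_dwass([[1.0], rng.normal(size=5)])


class TestCompareGroups:
    def test_bundles_omnibus_and_pairwise(self, rng):
        groups = [rng.normal(s, 1, 10) for s in (0, 0, 3)]
        res = compare_groups(groups, labels=["a", "b", "c"])
        assert 0 <= res.omnibus_p <= 1
        assert len(res.pairwise) == 3
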