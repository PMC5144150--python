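"""Construct aggregation and the Mann-Whitney U machinery."""

import itertools
import math

import numpy as np
import pytest

from chromodyn.morphometry import (
    aggregate_construct,
    compare_to_wt,
    mann_whitney_u,
)
from chromodyn.segmentation import ChromocenterSet
from chromodyn.synthetic import SceneParams, sample_morphometry


def permutation_oracle_p(a, b):
    """Exact two-sided p for untied data by enumerating every assignment of
    the pooled values to the two groups (independent of any rank-sum
    shortcut)."""
    a, b = list(a), list(b)
    pooled = a + b
    n1 = len(a)
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    def u_of(group):
        r = sum(ranks[v] for v in group)
        return r - n1 * (n1 + 1) / 2
    u_obs = u_of(a)
    n1n2 = n1 * len(b)
    us = [sum(ranks[pooled[i]] for i in comb) - n1 * (n1 + 1) / 2
          for comb in itertools.combinations(range(len(pooled)), n1)]
    lo = sum(u <= u_obs for u in us) / len(us)
    hi = sum(u >= u_obs for u in us) / len(us)
    return min(1.0, 2 * min(lo, hi))


class TestAggregateConstruct:
    def test_hand_computed_mean_and_sem(self):
        stats = aggregate_construct(None, "X",
                                    cn=np.array([10, 12, 14]),
                                    cs=np.array([50.0, 60.0, 70.0]))
        assert stats.mean_cn == 12
        assert stats.sem_cn == pytest.approx(2 / math.sqrt(3), abs=1e-4)
        assert stats.sem_cn == pytest.approx(1.1547, abs=1e-4)

    def test_single_cell_rejected(self):
        with pytest.raises(ValueError):
            aggregate_construct(None, "X", cn=np.array([5]), cs=np.array([10.0]))

    def test_cells_without_chromocenters_excluded_from_size(self):
        stats = aggregate_construct(None, "X",
                                    cn=np.array([0, 0, 4]),
                                    cs=np.array([np.nan, np.nan, 30.0]))
        assert stats.mean_cn == pytest.approx(4 / 3)
        assert stats.mean_cs == 30.0

    def test_all_zero_cells_give_zero_cn_and_missing_cs(self):
        stats = aggregate_construct(None, "X",
                                    cn=np.zeros(3), cs=np.full(3, np.nan))
        assert stats.mean_cn == 0
        assert stats.mean_cs is None

    def test_accepts_chromocenter_sets(self):
        cells = [ChromocenterSet(nucleus_label=1),
                 ChromocenterSet(nucleus_label=2)]
        stats = aggregate_construct(cells, "empty")
        assert stats.mean_cn == 0 and stats.mean_cs is None


class TestMannWhitneyU:
    def test_complete_separation_small_n(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.u == 0
        assert res.method == "exact"
        assert res.p_two_sided == pytest.approx(0.1)

    def test_single_observations(self):
        res = mann_whitney_u([1], [2])
        assert res.p_two_sided == pytest.approx(1.0)

    def test_identical_multisets(self):
        a = [3, 3, 5, 7]
        res = mann_whitney_u(a, a)
        assert res.u == len(a) ** 2 / 2
        assert res.method == "normal_approx"  # ties -> approximation
        assert res.p_two_sided == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1, 2])

    @pytest.mark.parametrize("n1,n2", [(2, 2), (3, 3), (3, 5), (4, 6), (6, 6)])
    def test_exact_p_equals_permutation_oracle(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(5):
            a = rng.normal(size=n1)
            b = rng.normal(0.8, size=n2)
            res = mann_whitney_u(a, b)
            assert res.method == "exact"
            assert res.p_two_sided == pytest.approx(
                permutation_oracle_p(a, b), abs=1e-12)

    def test_u_statistics_sum_to_n1_n2(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = rng.integers(0, 6, size=7).astype(float)  # ties likely
            b = rng.integers(0, 6, size=9).astype(float)
            assert mann_whitney_u(a, b).u + mann_whitney_u(b, a).u == \
                pytest.approx(len(a) * len(b))

    def test_normal_approximation_converges_to_exact(self):
        from scipy.stats import mannwhitneyu as scipy_mwu

        rng = np.random.default_rng(42)
        deltas = []
        for _ in range(20):
            a = rng.normal(size=20)
            b = rng.normal(0.3, size=20)
            ours = mann_whitney_u(a, b)
            assert ours.method == "normal_approx"
            exact = scipy_mwu(a, b, alternative="two-sided", method="exact")
            deltas.append(abs(ours.p_two_sided - exact.pvalue))
        assert max(deltas) < 0.01


class TestCompareToWT:
    @staticmethod
    def _stats(name, cn, cs):
        return aggregate_construct(None, name, cn=np.asarray(cn, float),
                                   cs=np.asarray(cs, float))

    def test_large_effect_flags_both_directions(self):
        """A construct drawn with twice the WT spot count and half the WT
        spot area must flag CN up and CS down at the strict tier."""
        wt_p = SceneParams(chromocenters_mean=15, chromocenters_sd=3,
                           radius_mean_px=5, radius_sd_px=0.8)
        mut_p = SceneParams(chromocenters_mean=30, chromocenters_sd=3,
                            radius_mean_px=5 / math.sqrt(2), radius_sd_px=0.6)
        cn_wt, cs_wt = sample_morphometry(wt_p, 20, seed=1)
        cn_m, cs_m = sample_morphometry(mut_p, 20, seed=2)
        comp = compare_to_wt(self._stats("mut", cn_m, cs_m),
                             self._stats("WT", cn_wt, cs_wt))
        assert comp.cn_significant_increase
        assert comp.cs_significant_decrease
        assert comp.cn_test.p_two_sided <= 0.005
        assert comp.cs_test.p_two_sided <= 0.005
        assert comp.tier_cn == "***"

    def test_null_constructs_rarely_flagged(self):
        """Type-I control: replicates drawn from the WT distribution are
        flagged in well under 10% of cases at alpha = 0.05."""
        p = SceneParams()
        false_hits = 0
        n_rep = 100
        for i in range(n_rep):
            cn_wt, cs_wt = sample_morphometry(p, 20, seed=10_000 + 2 * i)
            cn_m, cs_m = sample_morphometry(p, 20, seed=10_001 + 2 * i)
            comp = compare_to_wt(self._stats("m", cn_m, cs_m),
                                 self._stats("WT", cn_wt, cs_wt))
            if comp.cn_significant_increase or comp.cs_significant_decrease:
                false_hits += 1
        assert false_hits <= 0.10 * n_rep

    def test_wt_against_itself_is_null(self):
        cn, cs = sample_morphometry(SceneParams(), 20, seed=3)
        stats = self._stats("WT", cn, cs)
        comp = compare_to_wt(stats, stats)
        assert comp.cn_test.p_two_sided == pytest.approx(1.0)
        assert not comp.cn_significant_increase

    def test_construct_without_foci_is_not_analyzable(self):
        wt = self._stats("WT", [10, 12, 14], [50.0, 60.0, 70.0])
        mut = self._stats("mut", [0, 0, 1], [np.nan, np.nan, 40.0])
        comp = compare_to_wt(mut, wt)
        assert comp.not_analyzable
        assert comp.cs_test is None

    def test_overexpression_clusters_chromocenters(self):
        """Cells with active clustering (fewer, larger spots) versus
        untransfected-like cells (more, smaller spots) reproduce the
        expected direction: transfected CN lower, CS higher."""
        transfected = SceneParams(chromocenters_mean=12, chromocenters_sd=2,
                                  radius_mean_px=6, radius_sd_px=0.8)
        untransfected = SceneParams(chromocenters_mean=22, chromocenters_sd=3,
                                    radius_mean_px=4, radius_sd_px=0.8)
        cn_t, cs_t = sample_morphometry(transfected, 20, seed=5)
        cn_u, cs_u = sample_morphometry(untransfected, 20, seed=6)
        st_t = self._stats("transfected", cn_t, cs_t)
        st_u = self._stats("untransfected", cn_u, cs_u)
        assert st_t.mean_cn < st_u.mean_cn
        assert st_t.mean_cs > st_u.mean_cs
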