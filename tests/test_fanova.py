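import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import f_oneway, kstest

from fanovatest import (
    Strategy,
    distance_matrix,
    fanova_statistic,
    fanova_test,
    permutation_pvalue,
    satterthwaite_pvalue,
    smooth_all,
)
from fanovatest.smoothing import CurveSet


def curveset(values):
    values = np.asarray(values, dtype=float)
    return CurveSet(
        grid=np.linspace(0, 1, values.shape[1]),
        values=values,
        strategy=Strategy.PENALIZED_GCV,
    )


def random_curves(rng, n=12, T=30):
    t = np.linspace(0, 1, T)
    base = np.sin(2 * np.pi * np.outer(rng.uniform(0.5, 2, n), t))
    return curveset(base + 0.3 * rng.standard_normal((n, T)))


class TestStatistic:
    def test_hand_computed_two_group_example(self):
        # group A curves (0,0),(2,2); group B (1,1),(3,3); Delta = 1/2
        cs = curveset([[0, 0], [2, 2], [1, 1], [3, 3]])
        groups = np.array(["A", "A", "B", "B"])
        comp = fanova_statistic(cs, groups)
        assert comp.ssr == pytest.approx(1.0)
        assert comp.sse == pytest.approx(4.0)
        assert comp.F_stat == pytest.approx(0.5)

    def test_identical_curves_give_zero_F(self):
        cs = curveset(np.tile([1.0, 2.0, 1.0], (6, 1)))
        comp = fanova_statistic(cs, ["A"] * 3 + ["B"] * 3)
        assert comp.ssr == 0.0 and comp.F_stat == 0.0 and comp.degenerate

    def test_scalar_reduction_matches_classical_anova(self, rng):
        x = rng.standard_normal(20)
        groups = np.array(["A"] * 8 + ["B"] * 12)
        cs = curveset(x[:, None])
        comp = fanova_statistic(cs, groups)
        res = f_oneway(x[:8], x[8:])
        assert comp.F_stat == pytest.approx(res.statistic, abs=1e-12)
        kappa, p = satterthwaite_pvalue(comp.F_stat, comp.pooled_cov, 2, 20)
        assert kappa == pytest.approx(1.0, abs=1e-12)
        assert p == pytest.approx(res.pvalue, abs=1e-12)

    def test_small_group_rejected(self):
        cs = curveset(np.ones((3, 4)))
        with pytest.raises(ValueError):
            fanova_statistic(cs, ["A", "A", "B"])

    @given(st.floats(min_value=0.1, max_value=50.0))
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(99)
        cs = random_curves(rng)
        groups = ["A"] * 6 + ["B"] * 6
        r1 = fanova_test(cs, groups)
        r2 = fanova_test(curveset(c * cs.values), groups)
        assert r1.F_stat == pytest.approx(r2.F_stat, rel=1e-9)
        assert r1.p_asymptotic == pytest.approx(r2.p_asymptotic, rel=1e-9)


class TestSatterthwaite:
    def test_kappa_plugin_trace_arithmetic(self):
        # naive plug-in on diag(2, 1): (2+1)^2 / (4+1) = 1.8
        kappa, _ = satterthwaite_pvalue(
            1.0, np.diag([2.0, 1.0]), k=2, n=20, bias_reduced=False
        )
        assert kappa == pytest.approx(1.8)

    def test_rank_one_covariance_gives_kappa_one(self):
        S = np.outer([1.0, 2.0], [1.0, 2.0])
        for br in (False, True):
            kappa, _ = satterthwaite_pvalue(1.0, S, k=2, n=30, bias_reduced=br)
            assert kappa == pytest.approx(1.0, abs=1e-10)

    def test_zero_covariance_returns_p_one(self):
        kappa, p = satterthwaite_pvalue(0.0, np.zeros((3, 3)), 2, 10)
        assert p == 1.0

    def test_gaussian_process_null_pvalues_uniform(self):
        # i.i.d. smooth GP curves, no group difference: asymptotic p-values
        # should be Uniform(0,1); KS test not rejected at the 0.01 level
        rng = np.random.default_rng(5)
        T, n = 60, 50
        t = np.linspace(0, 1, T)
        C = np.exp(-((t[:, None] - t[None, :]) ** 2) / (2 * 0.1**2))
        L = np.linalg.cholesky(C + 1e-10 * np.eye(T))
        groups = np.array(["a"] * 25 + ["b"] * 25)
        ps = []
        for _ in range(2000):
            cs = curveset(rng.standard_normal((n, T)) @ L.T)
            ps.append(fanova_test(cs, groups).p_asymptotic)
        assert kstest(ps, "uniform").pvalue > 0.01


class TestDistanceMatrix:
    def test_identical_curves_give_zero_matrix(self):
        cs = curveset(np.tile([1.0, 0.0], (4, 1)))
        np.testing.assert_array_equal(distance_matrix(cs), np.zeros((4, 4)))

    def test_hand_computed_pair_distance(self):
        cs = curveset([[0, 0], [2, 2], [1, 1], [3, 3]])
        D2 = distance_matrix(cs)
        assert D2[0, 1] == pytest.approx(4.0)  # (1/2) * (4 + 4)
        assert np.allclose(D2, D2.T) and np.allclose(np.diag(D2), 0.0)

    def test_square_roots_satisfy_triangle_inequality(self, rng):
        D = np.sqrt(distance_matrix(random_curves(rng)))
        n = D.shape[0]
        for i in range(n):
            for j in range(n):
                assert (D[i, :] + D[:, j] >= D[i, j] - 1e-12).all()


class TestPermutation:
    def test_distance_F_equals_direct_F(self, rng):
        for _ in range(10):
            cs = random_curves(rng, n=rng.integers(8, 30), T=rng.integers(5, 100))
            n = cs.n_subjects
            groups = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))
            comp = fanova_statistic(cs, groups)
            F_dist, _ = permutation_pvalue(distance_matrix(cs), groups, B=1)
            assert abs(comp.F_stat - F_dist) < 1e-10

    def test_pvalue_bounds(self, rng):
        cs = random_curves(rng)
        groups = ["A"] * 6 + ["B"] * 6
        _, p = permutation_pvalue(distance_matrix(cs), groups, B=99, seed=0)
        assert 1 / 100 <= p <= 1.0

    def test_matches_exhaustive_enumeration(self, rng):
        from itertools import combinations

        cs = random_curves(rng, n=6, T=10)
        groups = np.array(["A", "A", "A", "B", "B", "B"])
        D2 = distance_matrix(cs)
        comp = fanova_statistic(cs, groups)
        # enumerate all C(6,3) = 20 labelings
        stats = []
        for combo in combinations(range(6), 3):
            lab = np.array(["B"] * 6)
            lab[list(combo)] = "A"
            stats.append(fanova_statistic(cs, lab).F_stat)
        exact_p = np.mean([s >= comp.F_stat - 1e-12 for s in stats])
        _, p_mc = permutation_pvalue(D2, groups, B=10_000, seed=3)
        assert abs(p_mc - exact_p) < 0.02

    def test_agrees_with_permanova_oracle(self, scaled_region):
        """Independent cross-check against scikit-bio's PERMANOVA."""
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        curves = smooth_all(scaled_region, Strategy.SMALL_BASIS)
        D2 = distance_matrix(curves)
        F_ours, p_ours = permutation_pvalue(
            D2, scaled_region.groups, B=999, seed=7
        )
        dm = skbio_distance.DistanceMatrix(np.sqrt(D2))
        res = skbio_distance.permanova(
            dm, grouping=list(scaled_region.groups), permutations=999
        )
        assert F_ours == pytest.approx(res["test statistic"], rel=1e-9)
        assert p_ours == pytest.approx(res["p-value"], abs=0.05)

    def test_all_zero_distances_give_p_one(self):
        D2 = np.zeros((6, 6))
        _, p = permutation_pvalue(D2, ["A"] * 3 + ["B"] * 3, B=99, seed=0)
        assert p == 1.0


def test_fanova_test_report_fields(scaled_region):
    curves = smooth_all(scaled_region, Strategy.PENALIZED_GCV)
    res = fanova_test(curves, scaled_region.groups, B=99, seed=2)
    assert res.n == scaled_region.n_subjects and res.k == 2
    assert res.T == 2 * scaled_region.n_variants
    assert res.df1 == pytest.approx(res.kappa_hat * (res.k - 1))
    assert res.df2 == pytest.approx(res.kappa_hat * (res.n - res.k))
    assert 0 < res.p_asymptotic <= 1 and 0 < res.p_permutation <= 1
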