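"""Checks of the four association strategies against independent oracles:
hand-computed ANOVA decomposition, exhaustive permutation enumeration,
explicit H/E SSCP eigen-computation and statsmodels MANOVA, and the
eigenstructure of equicorrelated data for PCA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import multiphen as mp
from multiphen import GenotypeVector, PhenotypeMatrix

# printed single-trait fixture: three genotype groups of three samples
G9 = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
Y9 = np.array([1.1, 0.8, 1.3, 1.9, 2.2, 1.7, 3.1, 2.6, 3.3])


def _perfect(n_per=20, m=1):
    g = GenotypeVector(np.tile([0, 0, 1, 1, 2, 2], n_per))
    y = PhenotypeMatrix(np.tile(g.counts.astype(float)[:, None], (1, m)))
    return y, g


class TestSingleTrait:
    @pytest.mark.parametrize("mode", ["regression", "anova"])
    def test_perfect_association(self, mode):
        y, g = _perfect()
        assert mp.single_trait_pvalue(y.values[:, 0], g, mode=mode) < 1e-10

    def test_anova_matches_sum_of_squares_oracle(self):
        # brute-force one-way ANOVA decomposition on the printed fixture
        grand = Y9.mean()
        ssb = sum(
            (G9 == k).sum() * (Y9[G9 == k].mean() - grand) ** 2 for k in (0, 1, 2)
        )
        ssw = sum(((Y9[G9 == k] - Y9[G9 == k].mean()) ** 2).sum() for k in (0, 1, 2))
        f_oracle = (ssb / 2) / (ssw / 6)
        p_oracle = stats.f.sf(f_oracle, 2, 6)
        p = mp.single_trait_pvalue(Y9, GenotypeVector(G9), mode="anova")
        assert p == pytest.approx(p_oracle, rel=1e-12)

    def test_regression_matches_scipy_linregress(self):
        p = mp.single_trait_pvalue(Y9, GenotypeVector(G9), mode="regression")
        assert p == pytest.approx(stats.linregress(G9, Y9).pvalue, rel=1e-9)

    @pytest.mark.parametrize("mode", ["regression", "anova"])
    def test_null_pvalues_uniform(self, mode):
        # p-values over 2000 independent null traits are Uniform(0,1)
        rng = np.random.default_rng(21)
        g = GenotypeVector(rng.binomial(2, 0.3, 80))
        pvals = [
            mp.single_trait_pvalue(rng.standard_normal(80), g, mode=mode)
            for _ in range(2000)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_constant_trait_convention(self):
        g = GenotypeVector(np.tile([0, 1, 2], 5))
        assert mp.single_trait_pvalue(np.ones(15), g) == 1.0

    def test_monomorphic_genotype_raises(self):
        g = GenotypeVector(np.ones(15, int))
        with pytest.raises(ValueError):
            mp.single_trait_pvalue(np.random.default_rng(0).normal(size=15), g)

    def test_missing_values_dropped(self, rng):
        g = GenotypeVector(rng.integers(0, 3, 50))
        y = rng.standard_normal(50)
        y_miss = y.copy()
        y_miss[:10] = np.nan
        keep = np.arange(50) >= 10
        expect = mp.single_trait_pvalue(y[keep], GenotypeVector(g.counts[keep]))
        assert mp.single_trait_pvalue(y_miss, g) == pytest.approx(expect)


class TestOneByOne:
    @pytest.mark.parametrize(
        "per_trait,expected", [((0.01, 0.5, 0.2), 0.03), ((0.6, 0.9), 1.0), ((0.2,), 0.2)]
    )
    def test_bonferroni_arithmetic(self, per_trait, expected):
        assert mp.bonferroni_pvalue(per_trait) == pytest.approx(expected)

    def test_single_trait_identity(self, rng):
        g = GenotypeVector(rng.integers(0, 3, 60))
        y = PhenotypeMatrix(rng.standard_normal((60, 1)))
        res = mp.one_by_one_test(y, g)
        assert res.p_value == pytest.approx(
            mp.single_trait_pvalue(y.values[:, 0], g)
        )

    def test_reported_pvalue_is_bonferroni_of_per_trait(self, small_dataset):
        y, g = small_dataset
        res = mp.one_by_one_test(y, g)
        assert res.p_value == pytest.approx(mp.bonferroni_pvalue(res.per_trait_p))
        assert res.statistic == pytest.approx(res.per_trait_p.min())

    def test_pairwise_complete_per_trait(self, rng):
        g = GenotypeVector(rng.integers(0, 3, 80))
        vals = rng.standard_normal((80, 2)) + 0.3 * g.counts[:, None]
        vals[:15, 0] = np.nan
        y = PhenotypeMatrix(vals)
        res = mp.one_by_one_test(y, g)
        keep = ~np.isnan(vals[:, 0])
        assert res.per_trait_p[0] == pytest.approx(
            mp.single_trait_pvalue(vals[keep, 0], GenotypeVector(g.counts[keep]))
        )
        assert res.per_trait_p[1] == pytest.approx(
            mp.single_trait_pvalue(vals[:, 1], g)
        )


class TestPermutation:
    @pytest.mark.parametrize("mode", ["regression", "anova"])
    def test_exhaustive_matches_enumeration_oracle(self, mode):
        g = np.array([0, 0, 1, 1, 2, 2])
        y = np.array(
            [[0.3, 1.2], [-0.6, 0.4], [1.4, 0.9], [0.2, 2.1], [2.2, 1.0], [1.1, 2.5]]
        )

        def minp(gv):
            out = []
            for j in range(2):
                if mode == "regression":
                    out.append(stats.linregress(gv, y[:, j]).pvalue)
                else:
                    out.append(
                        stats.f_oneway(*(y[gv == k, j] for k in np.unique(gv))).pvalue
                    )
            return min(out)

        observed = minp(g)
        tail = np.mean(
            [minp(g[list(perm)]) <= observed + 1e-12
             for perm in itertools.permutations(range(6))]
        )
        res = mp.permutation_minp_test(
            PhenotypeMatrix(y), GenotypeVector(g), mode=mode, exhaustive=True
        )
        assert res.p_value == pytest.approx(tail, abs=1e-12)
        assert res.statistic == pytest.approx(observed, rel=1e-9)

    def test_single_trait_equivalence(self, rng):
        # with m=1 the permutation p converges to the parametric p
        g = GenotypeVector(rng.binomial(2, 0.3, 100))
        y = PhenotypeMatrix(rng.standard_normal((100, 1)) + 0.25 * g.counts[:, None])
        p_param = mp.single_trait_pvalue(y.values[:, 0], g)
        b = 4000
        res = mp.permutation_minp_test(y, g, n_perms=b, seed=77)
        tol = 3 * np.sqrt(p_param * (1 - p_param) / b) + 1 / b
        assert res.p_value == pytest.approx(p_param, abs=tol)

    def test_perfect_association_attains_minimum(self):
        y, g = _perfect(n_per=10, m=3)
        res = mp.permutation_minp_test(y, g, n_perms=200, seed=5)
        assert res.p_value == pytest.approx(1 / 201)

    def test_small_b_warns(self, small_dataset):
        y, g = small_dataset
        with pytest.warns(UserWarning, match="n_perms"):
            mp.permutation_minp_test(y, g, n_perms=50, seed=0)

    def test_complete_case_rows_only(self, rng):
        g = GenotypeVector(rng.integers(0, 3, 60))
        vals = rng.standard_normal((60, 2))
        vals[:5, 0] = np.nan
        res = mp.permutation_minp_test(PhenotypeMatrix(vals), g, n_perms=200, seed=1)
        assert res.n_used == 55


class TestManova:
    @pytest.mark.parametrize("statistic", ["pillai", "wilks"])
    def test_univariate_reduction_equals_anova(self, rng, statistic):
        g = GenotypeVector(rng.integers(0, 3, 50))
        y = PhenotypeMatrix(rng.standard_normal((50, 1)) + 0.3 * g.counts[:, None])
        p_anova = mp.single_trait_pvalue(y.values[:, 0], g, mode="anova")
        res = mp.manova_test(y, g, statistic=statistic)
        assert res.p_value == pytest.approx(p_anova, rel=1e-9)

    def test_pillai_matches_he_eigen_oracle(self, small_dataset):
        y, g = small_dataset
        # explicit group-sum construction of the H and E SSCP matrices
        yv, gc = y.values, g.counts
        grand = yv.mean(axis=0)
        h_mat = np.zeros((3, 3))
        for k in np.unique(gc):
            d = yv[gc == k].mean(axis=0) - grand
            h_mat += (gc == k).sum() * np.outer(d, d)
        e_mat = (yv - grand).T @ (yv - grand) - h_mat
        eigs = np.real(np.linalg.eigvals(np.linalg.inv(h_mat + e_mat) @ h_mat))
        pillai = eigs.sum()
        res = mp.manova_test(y, g, statistic="pillai")
        assert res.statistic == pytest.approx(pillai, rel=1e-9)

    @pytest.mark.parametrize("statistic", ["pillai", "wilks"])
    def test_matches_statsmodels(self, small_dataset, statistic):
        sm = pytest.importorskip("statsmodels.multivariate.manova")
        y, g = small_dataset
        frame = pd.DataFrame(y.values, columns=["t1", "t2", "t3"])
        frame["g"] = pd.Categorical(g.counts)
        table = sm.MANOVA.from_formula("t1 + t2 + t3 ~ g", data=frame).mv_test()
        stat_tbl = table.results["g"]["stat"]
        row = {"pillai": "Pillai's trace", "wilks": "Wilks' lambda"}[statistic]
        res = mp.manova_test(y, g, statistic=statistic)
        assert res.statistic == pytest.approx(stat_tbl.loc[row, "Value"], rel=1e-9)
        assert res.p_value == pytest.approx(stat_tbl.loc[row, "Pr > F"], rel=1e-6)

    def test_singular_covariance_names_collinear_traits(self, rng):
        g = GenotypeVector(rng.integers(0, 3, 40))
        base = rng.standard_normal(40)
        y = PhenotypeMatrix(
            np.column_stack([base, 2 * base, rng.standard_normal(40)]),
            trait_names=["iq", "iq_rescaled", "memory"],
        )
        with pytest.raises(ValueError, match="iq_rescaled"):
            mp.manova_test(y, g)

    def test_type_one_error_rate(self):
        # null simulation: rejection at nominal 0.05 within 3 binomial SEs
        cfg = mp.SimulationConfig(
            n_samples=300, n_phenotypes=3, effect_size=1.0, correlation=0.0, seed=31
        )
        pvals = mp.replicate_pvalues(["manova"], cfg, n_replicates=2000)["manova"]
        rate = np.mean(pvals <= 0.05)
        assert rate == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / 2000))

    def test_too_few_complete_cases(self, rng):
        g = GenotypeVector(np.tile([0, 1, 2], 3))
        y = PhenotypeMatrix(rng.standard_normal((9, 8)))
        with pytest.raises(ValueError):
            mp.manova_test(y, g)


class TestPcScores:
    def test_single_trait_is_standardized_itself(self, rng):
        x = rng.standard_normal(40) * 3 + 7
        y = PhenotypeMatrix(x[:, None])
        scores, loadings, ve = mp.pc_scores(y, k=1)
        z = (x - x.mean()) / x.std(ddof=1)
        assert scores[:, 0] == pytest.approx(z * np.sign(loadings[0, 0]), abs=1e-9)
        assert ve[0] == pytest.approx(1.0)

    def test_duplicated_trait_limit(self, rng):
        base = rng.standard_normal(200)
        y = PhenotypeMatrix(np.column_stack([base, base + 1e-6 * rng.standard_normal(200)]))
        _, _, ve = mp.pc_scores(y, k=2)
        assert ve[0] > 0.999

    def test_equicorrelated_leading_eigenvalue(self):
        # leading eigenvalue of the trait correlation matrix -> 1+(m-1)r
        cfg = mp.SimulationConfig(
            n_samples=20_000, n_phenotypes=10, effect_size=1.0, correlation=0.5, seed=41
        )
        _, y = mp.simulate_dataset(cfg)
        scores, _, ve = mp.pc_scores(y, k=1)
        leading = ve[0] * 10  # eigenvalue = share * m for correlation PCA
        assert leading == pytest.approx(1 + 9 * 0.5, abs=0.15)

    def test_loadings_orthonormal_ordered_signed(self, rng):
        y = PhenotypeMatrix(rng.standard_normal((100, 4)) @ rng.standard_normal((4, 4)))
        scores, loadings, ve = mp.pc_scores(y, k=4)
        assert loadings.T @ loadings == pytest.approx(np.eye(4), abs=1e-9)
        assert np.all(np.diff(ve) <= 1e-12)
        assert np.all(loadings.sum(axis=0) >= -1e-12)

    def test_zero_variance_trait_error(self, rng):
        y = PhenotypeMatrix(np.column_stack([np.ones(30), rng.standard_normal(30)]))
        with pytest.raises(ValueError, match="zero-variance"):
            mp.pc_scores(y, k=1)


class TestPcaTest:
    def test_single_trait_identity(self, rng):
        g = GenotypeVector(rng.integers(0, 3, 60))
        y = PhenotypeMatrix(5 * rng.standard_normal((60, 1)) + 0.4 * g.counts[:, None])
        res = mp.pca_test(y, g, k=1)
        assert res.p_value == pytest.approx(mp.single_trait_pvalue(y.values[:, 0], g))

    def test_perfect_association(self, rng):
        g = GenotypeVector(np.tile([0, 0, 1, 1, 2, 2], 10))
        vals = g.counts.astype(float)[:, None] + 1e-6 * rng.standard_normal((60, 3))
        res = mp.pca_test(PhenotypeMatrix(vals), g, k=1)
        assert res.p_value < 1e-10

    def test_two_pc_joint_test(self, small_dataset):
        y, g = small_dataset
        res = mp.pca_test(y, g, k=2)
        assert res.method == "pca"
        assert 0 <= res.p_value <= 1

    def test_invalid_k(self, small_dataset):
        y, g = small_dataset
        with pytest.raises(ValueError):
            mp.pca_test(y, g, k=3)


_METHOD_FNS = {
    "one_by_one": mp.one_by_one_test,
    "permutation": mp.permutation_minp_test,
    "manova": mp.manova_test,
    "pca": mp.pca_test,
}


class TestSharedProperties:
    @pytest.mark.parametrize("method", ["one_by_one", "manova", "pca"])
    def test_joint_reordering_invariance(self, small_dataset, method, rng):
        y, g = small_dataset
        order = rng.permutation(y.n_samples)
        y2 = PhenotypeMatrix(y.values[order])
        g2 = GenotypeVector(g.counts[order])
        fn = _METHOD_FNS[method]
        assert fn(y, g).p_value == pytest.approx(fn(y2, g2).p_value, rel=1e-9)

    def test_permutation_reordering_invariance_exhaustive(self, rng):
        # exact invariance holds once the permutation null is enumerated
        g = np.array([0, 0, 1, 1, 2, 2, 1])
        y = rng.standard_normal((7, 2)) + 0.5 * g[:, None]
        order = rng.permutation(7)
        r1 = mp.permutation_minp_test(
            PhenotypeMatrix(y), GenotypeVector(g), exhaustive=True
        )
        r2 = mp.permutation_minp_test(
            PhenotypeMatrix(y[order]), GenotypeVector(g[order]), exhaustive=True
        )
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    @pytest.mark.parametrize("method", ["one_by_one", "permutation", "manova", "pca"])
    def test_trait_scale_invariance(self, small_dataset, method):
        y, g = small_dataset
        scaled = y.values.copy()
        scaled[:, 1] *= 37.0
        y2 = PhenotypeMatrix(scaled)
        kwargs = {"n_perms": 300, "seed": 9} if method == "permutation" else {}
        fn = _METHOD_FNS[method]
        assert fn(y, g, **kwargs).p_value == pytest.approx(
            fn(y2, g, **kwargs).p_value, rel=1e-9
        )

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_all_methods_return_valid_pvalues(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(25, 60))
        m = int(rng.integers(1, 4))
        g = GenotypeVector(rng.binomial(2, 0.4, n))
        if np.unique(g.counts).size < 2:
            return
        y = PhenotypeMatrix(rng.standard_normal((n, m)))
        for res in (
            mp.one_by_one_test(y, g),
            mp.permutation_minp_test(y, g, n_perms=120, seed=0),
            mp.manova_test(y, g),
            mp.pca_test(y, g) if n > m else None,
        ):
            if res is not None:
                assert 0.0 <= res.p_value <= 1.0
                assert res.n_used == n
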