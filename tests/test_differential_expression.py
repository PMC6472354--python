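import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from sigcoherence.differential_expression import (
    GammDesign, SplineSpec, bh_adjust, build_spline_basis, fit_all_genes,
    fit_gamm_gene, fit_linear_gene, linear_sweep,
)
from conftest import make_study


class TestSplineBasis:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.ages = rng.uniform(0.05, 1.0, 120)
        self.spec = SplineSpec(k=5)

    def test_polynomials_in_penalty_nullspace_are_reproduced(self):
        X, S = build_spline_basis(self.ages, self.spec)
        for target in (np.ones_like(self.ages), self.ages):
            c, *_ = np.linalg.lstsq(X, target, rcond=None)
            assert np.abs(X @ c - target).max() < 1e-8
            assert c @ S @ c < 1e-10

    def test_penalty_is_positive_semidefinite(self):
        _, S = build_spline_basis(self.ages, self.spec)
        assert np.linalg.eigvalsh(S).min() >= -1e-10

    def test_penalty_equals_integrated_squared_second_derivative(self):
        # quadrature oracle: evaluate the fitted spline on a fine grid,
        # differentiate numerically twice, integrate the square
        grid = np.linspace(0.0, 1.0, 4001)
        X, S = build_spline_basis(grid, SplineSpec(k=6))
        c, *_ = np.linalg.lstsq(X, grid ** 2, rcond=None)
        f = X @ c
        d2 = np.gradient(np.gradient(f, grid), grid)
        quad = np.trapezoid(d2[5:-5] ** 2, grid[5:-5])  # clip edge artifacts
        form = c @ S @ c
        assert abs(quad - form) / form < 1e-3

    def test_too_few_distinct_ages(self):
        with pytest.raises(ValueError, match="smaller k"):
            build_spline_basis(np.array([0.1, 0.1, 0.2, 0.3]), SplineSpec(k=5))

    def test_k_below_three_rejected(self):
        with pytest.raises(ValueError):
            SplineSpec(k=2)


class TestGammEngine:
    def _design_data(self, n_children=60, per_child=2, seed=0):
        rng = np.random.default_rng(seed)
        child = np.repeat([f"c{i}" for i in range(n_children)], per_child)
        n = child.size
        ages = rng.uniform(0.05, 1.0, n)
        x = np.repeat(rng.integers(0, 2, n_children), per_child).astype(float)
        return rng, child, ages, x

    def test_reduces_to_ols_without_variance_components(self):
        rng, child, ages, x = self._design_data()
        y = 1 + 0.5 * x + 0.3 * ages + rng.normal(0, 0.3, ages.size)
        gf = fit_gamm_gene(y, ages, child, x, fix_lambda=np.inf,
                           fix_sigma_id=0)
        lf = fit_linear_gene(y, x, ages)
        assert gf.beta_cs == pytest.approx(lf.estimate, abs=1e-4)
        assert gf.t_cs == pytest.approx(lf.t, abs=1e-3)
        assert gf.p_cs == pytest.approx(lf.p, abs=1e-3)

    def test_constant_response_is_degenerate(self):
        _, child, ages, x = self._design_data()
        fit = fit_gamm_gene(np.full(ages.size, 3.0), ages, child, x)
        assert fit.beta_cs == 0.0
        assert fit.sigma_eps == pytest.approx(0.0, abs=1e-8)
        assert not fit.converged

    def test_constant_factor_rejected(self):
        _, child, ages, _ = self._design_data()
        with pytest.raises(ValueError, match="constant"):
            fit_gamm_gene(np.random.default_rng(0).normal(size=ages.size),
                          ages, child, np.ones(ages.size))

    def test_single_child_factor_level_flagged_not_raised(self):
        rng, child, ages, _ = self._design_data(n_children=10)
        x = (np.asarray(child) == "c0").astype(float)
        fit = fit_gamm_gene(rng.normal(size=ages.size), ages, child, x)
        assert not fit.converged

    def test_parameter_recovery_small_montecarlo(self):
        # 50 replicates at the design of the larger recovery study
        spec = SplineSpec()
        rng = np.random.default_rng(42)
        child = np.repeat([f"d{i}" for i in range(100)], 2)
        ages = rng.uniform(0.04, 1.0, 200)
        cs = np.repeat(rng.integers(0, 2, 100), 2).astype(float)
        design = GammDesign(ages, child, cs, spec)
        ests = []
        for _ in range(50):
            b = np.repeat(rng.normal(0, 0.3, 100), 2)
            y = 7 + 0.8 * cs + b + rng.normal(0, 0.3, 200)
            ests.append(design.fit(y).beta_cs)
        assert np.mean(ests) == pytest.approx(0.8, abs=0.05)

    def test_variance_components_recovered(self):
        rng = np.random.default_rng(3)
        child = np.repeat([f"d{i}" for i in range(120)], 3)
        ages = rng.uniform(0.04, 1.0, 360)
        cs = np.repeat(rng.integers(0, 2, 120), 3).astype(float)
        design = GammDesign(ages, child, cs, SplineSpec())
        sids, seps = [], []
        for _ in range(20):
            b = np.repeat(rng.normal(0, 0.4, 120), 3)
            y = 7 + b + rng.normal(0, 0.25, 360)
            f = design.fit(y)
            sids.append(f.sigma_id)
            seps.append(f.sigma_eps)
        assert np.mean(sids) == pytest.approx(0.4, abs=0.06)
        assert np.mean(seps) == pytest.approx(0.25, abs=0.04)


class TestLinearEngine:
    def test_balanced_groups_equal_ages_give_mean_difference(self):
        # age identical across groups: the factor estimate is exactly the
        # difference of group means
        y = np.array([1.0, 2.0, 3.0, 5.0, 6.0, 7.0])
        x = np.array([0, 0, 0, 1, 1, 1.0])
        age = np.array([0.2, 0.5, 0.8, 0.2, 0.5, 0.8])
        fit = fit_linear_gene(y, x, age)
        assert fit.estimate == pytest.approx(4.0, abs=1e-12)

    def test_pure_age_signal_yields_zero_factor_effect(self):
        rng = np.random.default_rng(0)
        age = np.linspace(0.1, 1.0, 12)
        x = rng.integers(0, 2, 12).astype(float)
        y = 2.0 * age
        fit = fit_linear_gene(y, x, age)
        assert fit.estimate == pytest.approx(0.0, abs=1e-10)
        est, se, t, p = linear_sweep(y[None, :], x, age)
        assert se[0] == pytest.approx(0.0, abs=1e-10)

    def test_normal_equations_oracle_six_points(self):
        y = np.array([2.1, 1.9, 3.2, 4.0, 4.8, 6.1])
        x = np.array([0, 1, 0, 1, 0, 1.0])
        age = np.array([0.1, 0.2, 0.4, 0.5, 0.7, 0.9])
        X = np.column_stack([np.ones(6), x, age])
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)
        fit = fit_linear_gene(y, x, age)
        assert fit.estimate == pytest.approx(beta_oracle[1], abs=1e-10)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(5)
        n = 30
        x = rng.integers(0, 2, n).astype(float)
        age = rng.uniform(0, 1, n)
        y = 1 + 0.4 * x + 0.2 * age + rng.normal(0, 0.5, n)
        fit = fit_linear_gene(y, x, age)
        sm_fit = sm.OLS(y, sm.add_constant(np.column_stack([x, age]))).fit()
        assert fit.estimate == pytest.approx(sm_fit.params[1], rel=1e-10)
        assert fit.se == pytest.approx(sm_fit.bse[1], rel=1e-10)
        assert fit.p == pytest.approx(sm_fit.pvalues[1], rel=1e-8)

    def test_collinear_age_and_factor_rejected(self):
        x = np.array([0, 0, 1, 1.0])
        with pytest.raises(ValueError, match="collinear"):
            fit_linear_gene(np.array([1, 2, 3, 4.0]), x, x * 2.0)


class TestSweep:
    def test_gene_order_equivariance(self):
        study = make_study(n_genes=6, n_children=8, seed=4)
        res = fit_all_genes(study, "ab", model="linear")
        perm = [3, 1, 5, 0, 2, 4]
        shuffled = study.subset_samples([True] * study.n_samples)
        shuffled.gene_ids = [study.gene_ids[i] for i in perm]
        shuffled.values = study.values[perm]
        res2 = fit_all_genes(shuffled, "ab", model="linear")
        merged = res.set_index("gene_id").loc[res2["gene_id"]]
        np.testing.assert_allclose(merged["t"].to_numpy(),
                                   res2["t"].to_numpy(), rtol=1e-12)

    def test_worker_count_does_not_change_results(self):
        study = make_study(n_genes=5, n_children=10, seed=8)
        serial = fit_all_genes(study, "cs", model="gamm")
        parallel = fit_all_genes(study, "cs", model="gamm", workers=4)
        pd.testing.assert_frame_equal(serial, parallel)

    def test_q_column_is_bh_of_p(self):
        study = make_study(n_genes=10, n_children=10, seed=2)
        res = fit_all_genes(study, "ab", model="linear")
        np.testing.assert_allclose(res["q"], bh_adjust(res["p"].to_numpy()))


class TestBhAdjust:
    def test_single_p_is_identity(self):
        np.testing.assert_allclose(bh_adjust([0.05]), [0.05])

    def test_stepup_minima_hand_case(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1,
                    max_size=40))
    def test_matches_statsmodels_and_is_exchangeable(self, pvals):
        from statsmodels.stats.multitest import multipletests
        q = bh_adjust(pvals)
        _, q_sm, _, _ = multipletests(pvals, method="fdr_bh")
        np.testing.assert_allclose(q, q_sm, rtol=1e-12, atol=1e-15)
        order = np.argsort(pvals)
        np.testing.assert_allclose(bh_adjust(np.asarray(pvals)[order]),
                                   q[order], rtol=1e-12)
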