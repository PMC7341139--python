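import numpy as np
import pandas as pd
import pytest

import gremlite as gl
from gremlite.greml import (MixedModelData, VarianceComponents, make_design)

from conftest import simulate_mixed_data


def _random_psd_data(seed, n=50, p=3):
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, 2 * n))
    G = Z @ Z.T / (2 * n)
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
    y = rng.standard_normal(n)
    return MixedModelData(y=y, X=X, G=G)


class TestRemlLoglik:
    def test_identity_grm_depends_only_on_total_variance(self):
        data = _random_psd_data(0)
        data_i = MixedModelData(y=data.y, X=data.X, G=np.eye(data.n))
        a = gl.reml_loglik((0.3, 0.7), data_i, method="direct")
        b = gl.reml_loglik((0.6, 0.4), data_i, method="direct")
        assert a == pytest.approx(b, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_eigen_path_matches_direct_evaluation(self, seed):
        data = _random_psd_data(seed)
        for theta in [(0.2, 0.8), (1.3, 0.4), (1e-6, 1.0)]:
            assert gl.reml_loglik(theta, data, "eig") == pytest.approx(
                gl.reml_loglik(theta, data, "direct"), abs=1e-8)

    def test_rank_deficient_design_rejected(self):
        data = _random_psd_data(1)
        X_bad = np.column_stack([data.X, data.X[:, 0]])
        with pytest.raises(ValueError, match="rank-deficient"):
            MixedModelData(y=data.y, X=X_bad, G=data.G)

    def test_invalid_components_rejected(self):
        data = _random_psd_data(2)
        with pytest.raises(ValueError):
            gl.reml_loglik((-0.1, 1.0), data)
        with pytest.raises(ValueError):
            gl.reml_loglik((0.5, 0.0), data)


class TestAiRemlFit:
    def test_identity_grm_is_unidentifiable(self):
        data = _random_psd_data(3)
        data_i = MixedModelData(y=data.y, X=data.X, G=np.eye(data.n))
        with pytest.raises(ValueError, match="unidentifiable"):
            gl.ai_reml_fit(data_i)

    def test_null_simulation_estimates_near_zero(self):
        data, _ = simulate_mixed_data(seed=31, n=1200, m=1200, h2=0.0)
        fit = gl.ai_reml_fit(data)
        h2 = fit.sigma_u2 / (fit.sigma_u2 + fit.sigma_e2)
        assert h2 <= 0.05

    @pytest.mark.parametrize("seed,h2", [(41, 0.2), (42, 0.5), (43, 0.8)])
    def test_matches_profile_likelihood_argmax(self, seed, h2):
        data, _ = simulate_mixed_data(seed=seed, n=300, m=500, h2=h2)
        fit = gl.ai_reml_fit(data)
        h2_ai = fit.sigma_u2 / (fit.sigma_u2 + fit.sigma_e2)
        h2_grid, ll_grid = gl.profile_h2_argmax(data)
        assert abs(h2_ai - h2_grid) < 1e-3
        assert fit.loglik_reml == pytest.approx(ll_grid, abs=1e-4)

    def test_loglik_never_decreases_across_iterations(self):
        for seed in (51, 52):
            data, _ = simulate_mixed_data(seed=seed, n=400, m=400, h2=0.4)
            fit = gl.ai_reml_fit(data)
            trace = np.array(fit.loglik_trace)
            assert np.all(np.diff(trace) >= -1e-10)
            assert fit.converged

    def test_covariate_design_accepted(self):
        data, _ = simulate_mixed_data(seed=53, n=300, m=300, h2=0.5,
                                      covars=True)
        fit = gl.ai_reml_fit(data)
        assert fit.converged
        assert fit.cov.shape == (2, 2)


class TestHeritability:
    def _vc(self, su2, se2, cov=None):
        cov = cov if cov is not None else np.eye(2) * 1e-4
        return VarianceComponents(su2, se2, np.asarray(cov), -10.0, 5, True)

    def test_equal_components_give_half(self):
        assert gl.heritability(self._vc(0.5, 0.5)).h2 == pytest.approx(0.5)

    def test_zero_genetic_variance_gives_zero(self):
        assert gl.heritability(self._vc(0.0, 1.0)).h2 == pytest.approx(0.0)

    def test_delta_method_matches_finite_differences(self):
        cov = np.array([[4e-4, -1e-4], [-1e-4, 4e-4]])
        su2, se2 = 0.3, 0.7
        est = gl.heritability(self._vc(su2, se2, cov))
        eps = 1e-7
        h = lambda u, e: u / (u + e)
        grad = np.array([
            (h(su2 + eps, se2) - h(su2 - eps, se2)) / (2 * eps),
            (h(su2, se2 + eps) - h(su2, se2 - eps)) / (2 * eps),
        ])
        se_fd = np.sqrt(grad @ cov @ grad)
        assert est.se == pytest.approx(se_fd, abs=1e-10)

    def test_zero_total_variance_rejected(self):
        with pytest.raises(ValueError, match="total variance"):
            gl.heritability(self._vc(0.0, 0.0))


class TestLrt:
    def test_zero_statistic_gives_half(self):
        assert gl.lrt_pvalue(-100.0, -100.0) == pytest.approx(0.5)

    def test_known_quantile(self):
        from scipy.stats import chi2
        crit = chi2.isf(0.1, df=1)  # 2.7055...
        assert gl.lrt_pvalue(-100.0 + crit / 2, -100.0) == pytest.approx(0.05)
        assert gl.lrt_pvalue(-100.0 + 2.706 / 2, -100.0) == pytest.approx(
            0.05, abs=1e-3)

    def test_small_negative_clamped(self):
        assert gl.lrt_pvalue(-100.0 - 1e-6, -100.0) == pytest.approx(0.5)

    def test_large_negative_is_error(self):
        with pytest.raises(ValueError, match="optimizer failure"):
            gl.lrt_pvalue(-101.0, -100.0)


class TestBivariate:
    @staticmethod
    def _pair_data(seed, n=600, m=600, rg=0.6, h2=(0.5, 0.5), covars=False):
        rng = np.random.default_rng(seed)
        geno, _ = gl.simulate_genotypes(gl.GenoSimSpec(n=n, m=m, seed=seed),
                                        rng)
        rmat = np.array([[1.0, rg], [rg, 1.0]])
        pheno, truth = gl.simulate_phenotypes(
            geno, gl.PhenoSimSpec(traits=["a", "b"], h2=list(h2),
                                  n_causal=m // 2, rg=rmat, seed=seed), rng)
        grm = gl.compute_grm(geno)
        X = make_design(n=n)
        out = []
        for tr in ("a", "b"):
            z = gl.adjust_and_zscore(pheno, tr).sort_values("iid")
            out.append(MixedModelData(z["z"].to_numpy(), X, grm.values,
                                      ids=z["iid"].to_numpy()))
        return out[0], out[1], grm, truth

    def test_same_trait_twice_gives_rg_one(self):
        d1, _, grm, _ = self._pair_data(seed=61, n=400)
        d2 = MixedModelData(d1.y.copy(), d1.X.copy(), d1.G, ids=d1.ids)
        fit = gl.bivariate_ai_reml(d1, d2)
        assert fit.rg >= 0.99

    def test_null_genetic_correlation_recovered(self):
        ests, ses = [], []
        for seed in range(5):
            d1, d2, grm, _ = self._pair_data(seed=70 + seed, rg=0.0)
            fit = gl.bivariate_ai_reml(d1, d2)
            ests.append(fit.rg)
            ses.append(fit.rg_se)
        se_emp = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests)) <= max(2 * se_emp, 0.1)

    def test_positive_genetic_correlation_recovered(self):
        d1, d2, grm, truth = self._pair_data(seed=62, n=1500, m=1000, rg=0.8)
        fit = gl.bivariate_ai_reml(d1, d2)
        assert fit.rg == pytest.approx(truth.realized_rg[0, 1], abs=0.15)
        assert fit.converged

    def test_univariate_recovered_when_covariances_fixed_zero(self):
        """With g12 = r12 pinned at 0 the bivariate marginals are univariate."""
        d1, d2, grm, _ = self._pair_data(seed=63)
        fit_b = gl.bivariate_ai_reml(d1, d2, fixed={"g12": 0.0, "r12": 0.0})
        h2_b1 = fit_b.g11 / (fit_b.g11 + fit_b.r11)
        h2_b2 = fit_b.g22 / (fit_b.g22 + fit_b.r22)
        f1 = gl.ai_reml_fit(d1)
        f2 = gl.ai_reml_fit(d2)
        assert h2_b1 == pytest.approx(
            f1.sigma_u2 / (f1.sigma_u2 + f1.sigma_e2), abs=1e-4)
        assert h2_b2 == pytest.approx(
            f2.sigma_u2 / (f2.sigma_u2 + f2.sigma_e2), abs=1e-4)

    def test_rg_invariant_to_positive_rescaling(self):
        d1, d2, grm, _ = self._pair_data(seed=64, n=400)
        fit = gl.bivariate_ai_reml(d1, d2)
        d2s = MixedModelData(3.0 * d2.y, d2.X, d2.G, ids=d2.ids)
        fit_s = gl.bivariate_ai_reml(d1, d2s)
        assert fit_s.rg == pytest.approx(fit.rg, abs=1e-4)

    def test_dense_and_eigen_paths_agree(self):
        from gremlite.greml import _BivarDenseModel, _BivarEigModel
        d1, d2, grm, _ = self._pair_data(seed=65, n=150, m=300)
        theta = np.array([0.4, 0.2, 0.5, 0.6, 0.1, 0.5])
        ll_e, s_e, ai_e = _BivarEigModel(d1, d2.y).evaluate(theta)
        ll_d, s_d, ai_d = _BivarDenseModel(d1, d2, grm).evaluate(theta)
        assert ll_e == pytest.approx(ll_d, abs=1e-8)
        assert np.allclose(s_e, s_d, atol=1e-8)
        assert np.allclose(ai_e, ai_d, atol=1e-8)

    def test_overlapping_sample_fit_runs(self):
        d1, d2, grm, _ = self._pair_data(seed=66, n=200, m=400, rg=0.5)
        keep = np.arange(180)
        d2_sub = MixedModelData(d2.y[keep], d2.X[keep],
                                grm.values[np.ix_(keep, keep)],
                                ids=np.asarray(d2.ids)[keep])
        fit = gl.bivariate_ai_reml(d1, d2_sub, grm=grm)
        assert np.isfinite(fit.rg)
        assert fit.loglik_trace == sorted(fit.loglik_trace)

    def test_disjoint_samples_fix_r12(self):
        d1, d2, grm, _ = self._pair_data(seed=67, n=200, m=400, rg=0.5)
        lo, hi = np.arange(100), np.arange(100, 200)
        d1s = MixedModelData(d1.y[lo], d1.X[lo],
                             grm.values[np.ix_(lo, lo)],
                             ids=np.asarray(d1.ids)[lo])
        d2s = MixedModelData(d2.y[hi], d2.X[hi],
                             grm.values[np.ix_(hi, hi)],
                             ids=np.asarray(d2.ids)[hi])
        with pytest.warns(RuntimeWarning, match="r12"):
            fit = gl.bivariate_ai_reml(d1s, d2s, grm=grm)
        assert fit.r12 == 0.0


class TestPhenotypicCorrelation:
    def _z(self, vals, ids=None):
        ids = ids or [f"I{i}" for i in range(len(vals))]
        return pd.DataFrame({"iid": ids, "z": vals})

    def test_identical_gives_one(self):
        z = self._z([0.1, -0.5, 1.2, 0.3])
        assert gl.phenotypic_correlation(z, z) == pytest.approx(1.0)

    def test_negated_gives_minus_one(self):
        z = self._z([0.1, -0.5, 1.2, 0.3])
        z2 = self._z([-0.1, 0.5, -1.2, -0.3])
        assert gl.phenotypic_correlation(z, z2) == pytest.approx(-1.0)

    def test_hand_computed_five_points(self):
        """r = 10 / sqrt(10 * 14.8) for (1..5) vs (2,1,4,3,6), by the
        definitional sum formula."""
        z1 = self._z([1.0, 2.0, 3.0, 4.0, 5.0])
        z2 = self._z([2.0, 1.0, 4.0, 3.0, 6.0])
        assert gl.phenotypic_correlation(z1, z2) == pytest.approx(
            10.0 / np.sqrt(148.0), abs=1e-12)

    def test_few_shared_individuals_rejected(self):
        z1 = self._z([1.0, 2.0, 3.0], ids=["a", "b", "c"])
        z2 = self._z([1.0, 2.0, 3.0], ids=["c", "d", "e"])
        with pytest.raises(ValueError, match="shared"):
            gl.phenotypic_correlation(z1, z2)

    def test_zero_variance_rejected(self):
        z1 = self._z([1.0, 1.0, 1.0, 1.0])
        z2 = self._z([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="variance"):
            gl.phenotypic_correlation(z1, z2)
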