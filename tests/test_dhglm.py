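import numpy as np
import pandas as pd
import pytest

from sirevar import SimConfig, SireDHGLM, fit_mean_model, simulate_study, working_response
from sirevar.dhglm import MixedModelFit


def _tiny_pheno(rng, n_sires=3, per_sire=4, n_cg=2):
    n = n_sires * per_sire
    return pd.DataFrame(
        {
            "animal_id": [f"a{i}" for i in range(n)],
            "sire_id": [f"s{i % n_sires}" for i in range(n)],
            "cg": [f"c{i % n_cg}" for i in range(n)],
            "sex": ["M", "F"] * (n // 2),
            "age": rng.uniform(300, 420, n),
            "y": rng.normal(280, 20, n),
        }
    )


def _gls_oracle(pheno, phi, sigma2_s):
    """Dense GLS on the marginal covariance V = Z G Z' + R; the independent
    check for the mixed-model-equation solver on small instances."""
    from sirevar.dhglm import _Design

    d = _Design(pheno)
    Z = np.zeros((d.n, d.q))
    Z[np.arange(d.n), d.sire_idx] = 1.0
    V = sigma2_s * Z @ Z.T + np.diag(np.broadcast_to(phi, (d.n,)))
    Vi = np.linalg.inv(V)
    X = d.X
    # drop redundant columns (CG dummies span the intercept) via pinv
    b = np.linalg.pinv(X.T @ Vi @ X) @ X.T @ Vi @ d.y
    s = sigma2_s * Z.T @ Vi @ (d.y - X @ b)
    return b, s, d


class TestFitMeanModel:
    def test_matches_dense_gls_oracle(self, rng):
        pheno = _tiny_pheno(rng)
        phi = rng.uniform(0.5, 2.0, len(pheno))
        fit = fit_mean_model(pheno, phi, sigma2_s=3.0)
        b, s, d = _gls_oracle(pheno, phi, 3.0)
        # fitted values and EBVs are the comparable quantities (X may be
        # rank-deficient so b itself is only identified up to contrasts)
        np.testing.assert_allclose(fit.s.to_numpy(), s, atol=1e-8)
        fitted_mme = d.X @ fit.b.to_numpy() + fit.s.to_numpy()[d.sire_idx]
        fitted_gls = d.X @ b + s[d.sire_idx]
        np.testing.assert_allclose(fitted_mme, fitted_gls, atol=1e-8)

    def test_single_sire_large_variance_limit(self, rng):
        # one sire, huge sire variance: fitted family mean = data mean,
        # residuals centred
        n = 40
        pheno = pd.DataFrame(
            {
                "animal_id": [f"a{i}" for i in range(n)],
                "sire_id": "s0",
                "cg": "c0",
                "sex": "M",
                "age": 360.0,
                "y": rng.normal(280, 15, n),
            }
        )
        fit = fit_mean_model(pheno, 1.0, sigma2_s=1e3)
        assert abs(fit.residuals.mean()) < 1e-2
        assert fit.b.iloc[0] + fit.s.iloc[0] == pytest.approx(pheno["y"].mean(), abs=0.05)

    def test_zero_sire_variance_reduces_to_wls(self, rng):
        pheno = _tiny_pheno(rng)
        phi = rng.uniform(0.5, 2.0, len(pheno))
        fit = fit_mean_model(pheno, phi, sigma2_s=0.0)
        np.testing.assert_array_equal(fit.s.to_numpy(), 0.0)
        # residuals orthogonal to X in the W metric (WLS normal equations)
        from sirevar.dhglm import _Design

        d = _Design(pheno)
        np.testing.assert_allclose(d.X.T @ (fit.residuals / phi), 0.0, atol=1e-8)

    def test_leverages_in_unit_interval(self, rng):
        pheno = _tiny_pheno(rng, n_sires=5, per_sire=6)
        fit = fit_mean_model(pheno, 1.0, sigma2_s=2.0)
        assert (fit.leverages >= 0).all() and (fit.leverages < 1).all()


class TestWorkingResponse:
    def test_fixed_point_when_variance_explains_residual(self, rng):
        pheno = _tiny_pheno(rng)
        fit = fit_mean_model(pheno, 1.0, sigma2_s=2.0)
        phi = rng.uniform(0.5, 2.0, len(pheno))
        fit.residuals = np.sqrt((1 - fit.leverages) * phi)  # e^2 = (1-h) phi
        psi, w = working_response(fit, phi)
        np.testing.assert_allclose(psi, np.log(phi), atol=1e-12)
        np.testing.assert_allclose(w, (1 - fit.leverages) / 2)

    def test_plug_in_values(self):
        fit = MixedModelFit(
            b=pd.Series(dtype=float),
            s=pd.Series(dtype=float),
            residuals=np.array([0.0]),
            leverages=np.array([0.0]),
            pev=pd.Series(dtype=float),
            sigma2_s=1.0,
            resid_variances=np.array([1.0]),
        )
        psi, w = working_response(fit, np.array([1.0]))
        assert psi[0] == pytest.approx(-1.0)
        assert w[0] == pytest.approx(0.5)

    def test_unbiased_for_true_log_variance(self, rng):
        # E[psi] -> eta for residuals ~ N(0, e^eta) with h = 0
        eta = 1.7
        n = 100_000
        resid = rng.normal(0, np.exp(eta / 2), n)
        fit = MixedModelFit(
            b=pd.Series(dtype=float),
            s=pd.Series(dtype=float),
            residuals=resid,
            leverages=np.zeros(n),
            pev=pd.Series(dtype=float),
            sigma2_s=1.0,
            resid_variances=np.full(n, np.exp(eta)),
        )
        psi, _ = working_response(fit, np.full(n, np.exp(eta)))
        assert abs(psi.mean() - eta) < 0.02

    def test_saturated_record_rejected(self):
        fit = MixedModelFit(
            b=pd.Series(dtype=float),
            s=pd.Series(dtype=float),
            residuals=np.array([1.0]),
            leverages=np.array([1.0]),
            pev=pd.Series(dtype=float),
            sigma2_s=1.0,
            resid_variances=np.array([1.0]),
        )
        with pytest.raises(ValueError, match="saturated"):
            working_response(fit, np.array([1.0]))


class TestFitDhglm:
    def test_rmv_zero_pins_covariance(self, fitted_pair):
        _, fit_zero = fitted_pair
        assert fit_zero.cov_s_sv == 0.0
        assert fit_zero.r_mv == 0.0

    def test_rmv_zero_mean_part_decouples(self, fitted_pair, small_study):
        # with the covariance pinned, the mean part equals a stand-alone
        # weighted sire LMM at the same phi and sigma2_s
        _, fit_zero = fitted_pair
        _, _, pheno = small_study
        alone = fit_mean_model(pheno, fit_zero.phi, fit_zero.sigma2_s)
        np.testing.assert_allclose(alone.s.to_numpy(), fit_zero.mean_part.s.to_numpy(), atol=1e-8)
        np.testing.assert_allclose(alone.residuals, fit_zero.mean_part.residuals, atol=1e-8)

    def test_null_variance_heterogeneity_shrinks_sigma2_sv(self):
        hits = 0
        for seed in range(5):
            cfg = SimConfig(
                n_sires=150, progeny_min=60, progeny_max=60, n_chr=1, snps_per_chr=10,
                sigma2_sv=0.0, n_qtl_var=0, n_cg=10, seed=500 + seed,
            )
            _, _, pheno = simulate_study(cfg, family_sizes=np.full(150, 60))
            fit = SireDHGLM(pheno).fit(mode="rmv_zero")
            hits += fit.sigma2_sv <= 0.01 * np.var(fit.psi)
        assert hits >= 4

    def test_recovers_baseline_log_variance(self, fitted_pair, small_cfg):
        fit_free, _ = fitted_pair
        assert abs(np.mean(np.log(fit_free.phi)) - small_cfg.eta0) < 0.15

    def test_phi_positive_and_rmv_bounded(self, fitted_pair):
        fit_free, _ = fitted_pair
        assert (fit_free.phi > 0).all()
        assert abs(fit_free.r_mv) <= 1.0

    def test_unknown_mode_rejected(self, small_study):
        _, _, pheno = small_study
        with pytest.raises(ValueError, match="mode"):
            SireDHGLM(pheno).fit(mode="both")

    def test_summary_mentions_components(self, fitted_pair):
        fit_free, _ = fitted_pair
        text = fit_free.summary()
        assert "sigma2_sv" in text and "r_mv" in text


class TestReliabilities:
    def test_bounds_and_monotonicity_in_family_size(self, fitted_pair):
        fit_free, _ = fitted_pair
        rel = fit_free.reliabilities()
        assert ((rel["r2_m"] >= 0) & (rel["r2_m"] < 1)).all()
        big = rel.nlargest(10, "n_progeny")["r2_m"].mean()
        small = rel.nsmallest(10, "n_progeny")["r2_m"].mean()
        assert big > small

    def test_zero_variance_errors(self, fitted_pair):
        fit_free, _ = fitted_pair
        import dataclasses

        broken = dataclasses.replace(fit_free, sigma2_s=0.0)
        with pytest.raises(ValueError, match="reliability"):
            broken.reliabilities()
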