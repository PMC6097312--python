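import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sirevar import (
    bayes_factor,
    genotype_summary,
    response_correlations,
    scale_effect_test,
    top_windows_overlap,
    window_variance,
)
from sirevar.postgwas import window_index


def _le_genotypes(rng, n, m, maf_low=0.1):
    freqs = rng.uniform(maf_low, 0.5, m)
    return rng.binomial(2, freqs[None, :], size=(n, m)).astype(float)


def _map(m, n_chr=2, spacing=500_000):
    per = m // n_chr
    return pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(m)],
            "chromosome": np.repeat(np.arange(1, n_chr + 1), per),
            "bp": np.tile(spacing * np.arange(per) + 1, n_chr),
        }
    )


class TestBayesFactor:
    def test_posterior_equals_prior(self):
        assert bayes_factor(0.001, 0.001) == pytest.approx(1.0)

    def test_zero_posterior(self):
        assert bayes_factor(0.0, 0.001) == 0.0

    def test_odds_arithmetic(self):
        # (0.5/0.5)/(0.001/0.999) = 999
        assert bayes_factor(0.5, 0.001) == pytest.approx(999.0)

    def test_p_one_capped_finite(self, caplog):
        with caplog.at_level("INFO"):
            bf = bayes_factor(1.0, 0.001, n_kept=999)
        assert np.isfinite(bf)
        assert bf == pytest.approx(999 * 999.0)
        assert "capped" in caplog.text

    def test_invalid_prior_rejected(self):
        with pytest.raises(ValueError):
            bayes_factor(0.5, 0.0)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.0, 0.99), st.floats(0.001, 0.01))
    def test_strictly_increasing_in_p(self, p, prior):
        assert bayes_factor(p + 0.005, prior) > bayes_factor(p, prior)


class TestWindowVariance:
    def test_single_causal_snp_takes_all(self, rng):
        Z = _le_genotypes(rng, 200, 20)
        a = np.zeros(20)
        a[7] = 1.0
        wv = window_variance(Z, a, _map(20))
        top = wv.iloc[0]
        assert top["pct_genetic_variance"] == pytest.approx(100.0)
        assert (wv["pct_genetic_variance"].iloc[1:] == 0).all()

    def test_two_equal_snps_split_evenly(self, rng):
        Z = rng.binomial(2, 0.3, size=(10_000, 2)).astype(float)
        snp_map = pd.DataFrame(
            {"snp_id": ["a", "b"], "chromosome": [1, 2], "bp": [500_000, 500_000]}
        )
        wv = window_variance(Z, np.array([0.5, 0.5]), snp_map)
        np.testing.assert_allclose(wv["pct_genetic_variance"], [50, 50], atol=2)

    def test_additive_under_linkage_equilibrium(self, rng):
        Z = _le_genotypes(rng, 2000, 200)
        a = np.zeros(200)
        hot = rng.choice(200, 40, replace=False)
        a[hot] = rng.normal(0, 1, 40)
        wv = window_variance(Z, a, _map(200, n_chr=4))
        assert 95 <= wv["pct_genetic_variance"].sum() <= 105

    def test_window_sum_denominator_sums_to_100(self, rng):
        Z = _le_genotypes(rng, 500, 60)
        a = rng.normal(0, 1, 60)
        wv = window_variance(Z, a, _map(60), denominator="window_sum")
        assert wv["pct_genetic_variance"].sum() == pytest.approx(100.0)

    def test_translation_invariance_of_shares(self, rng):
        Z = _le_genotypes(rng, 300, 30)
        a = rng.normal(0, 1, 30)
        wv1 = window_variance(Z, a, _map(30))
        wv2 = window_variance(Z + 1.0, a, _map(30))
        pd.testing.assert_series_equal(
            wv1["pct_genetic_variance"], wv2["pct_genetic_variance"]
        )

    def test_all_zero_effects_warns_zero_shares(self, rng, caplog):
        Z = _le_genotypes(rng, 100, 10)
        with caplog.at_level("WARNING"):
            wv = window_variance(Z, np.zeros(10), _map(10))
        assert (wv["pct_genetic_variance"] == 0).all()

    def test_window_indexing_convention(self):
        # 1-based bp: positions 1..1e6 fall in window 0, 1e6+1 in window 1
        np.testing.assert_array_equal(
            window_index([1, 1_000_000, 1_000_001, 52_000_001]), [0, 0, 1, 52]
        )


class TestTopWindowsOverlap:
    def _wv(self, labels, pcts):
        chrom = [int(l.split("_")[0][3:]) for l in labels]
        widx = [int(l.split("_")[1]) for l in labels]
        return pd.DataFrame(
            {
                "chromosome": chrom,
                "window_index": widx,
                "label": labels,
                "pct_genetic_variance": pcts,
            }
        )

    def test_identical_rankings_full_overlap(self):
        a = self._wv([f"Chr1_{i}" for i in range(30)], np.arange(30)[::-1])
        rep = top_windows_overlap(a, a, k=20)
        assert rep.n_shared == rep.k == 20

    def test_disjoint_genomes(self):
        a = self._wv([f"Chr1_{i}" for i in range(10)], range(10))
        b = self._wv([f"Chr2_{i}" for i in range(10)], range(10))
        assert top_windows_overlap(a, b, k=5).n_shared == 0

    def test_rank_swap_within_top_k_irrelevant(self):
        labels = [f"Chr1_{i}" for i in range(25)]
        pcts = np.arange(25.0)[::-1]
        swapped = pcts.copy()
        swapped[[9, 10]] = swapped[[10, 9]]
        rep = top_windows_overlap(self._wv(labels, pcts), self._wv(labels, swapped), k=20)
        assert rep.n_shared == 20

    def test_symmetric_and_k_clipped(self, caplog):
        a = self._wv([f"Chr1_{i}" for i in range(8)], range(8))
        b = self._wv([f"Chr1_{i}" for i in range(4, 12)], range(8))
        with caplog.at_level("WARNING"):
            r1 = top_windows_overlap(a, b, k=20)
        r2 = top_windows_overlap(b, a, k=20)
        assert r1.n_shared == r2.n_shared
        assert r1.k == 8


class TestResponseCorrelations:
    def test_self_and_anti_correlation(self):
        df = pd.DataFrame({"dEBV_m": [1.0, 2, 3, 4], "dEBV_v": [-1.0, -2, -3, -4]})
        r, se = response_correlations(df, columns=["dEBV_m", "dEBV_v"])
        assert r.loc["dEBV_m", "dEBV_m"] == 1.0
        assert r.loc["dEBV_m", "dEBV_v"] == pytest.approx(-1.0)

    def test_standard_error_formula(self, rng):
        x = rng.standard_normal(50)
        df = pd.DataFrame({"a": x, "b": x + rng.standard_normal(50)})
        r, se = response_correlations(df, columns=["a", "b"])
        rho = r.loc["a", "b"]
        assert se.loc["a", "b"] == pytest.approx(np.sqrt((1 - rho**2) / 48))

    def test_degenerate_pair_is_na(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [5.0, 5, 5]})
        r, _ = response_correlations(df, columns=["a", "b"])
        assert np.isnan(r.loc["a", "b"])


class TestScaleEffectTest:
    def test_equal_standardised_effects_not_flagged(self):
        # boundary is a strict inequality
        sm, sv, beyond = scale_effect_test(3.0, 6.0, 300.0, 600.0)
        assert sm == sv == pytest.approx(0.01)
        assert beyond is False

    def test_variance_dominant_effect_flagged(self):
        _, _, beyond = scale_effect_test(3.0, 12.0, 300.0, 600.0)
        assert beyond is True

    def test_invalid_denominator_rejected(self):
        with pytest.raises(ValueError):
            scale_effect_test(1.0, 1.0, 0.0, 600.0)


class TestGenotypeSummary:
    def test_constant_response(self, rng):
        codes = rng.integers(0, 3, 100).astype(float)
        out = genotype_summary(np.ones(100), codes)
        assert out["mean"].dropna().nunique() == 1

    def test_response_equal_to_code(self, rng):
        codes = np.repeat([0.0, 1.0, 2.0], 10)
        out = genotype_summary(codes.copy(), codes)
        np.testing.assert_allclose(out["mean"], [0, 1, 2])

    def test_empty_class_reported_not_raised(self):
        codes = np.array([0.0, 0.0, 1.0, 1.0])
        out = genotype_summary(np.array([1.0, 2, 3, 4]), codes)
        assert out.loc[out["genotype"] == 2, "n"].iloc[0] == 0

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            genotype_summary(np.ones(5), np.zeros(5))

    def test_variance_qtl_direction(self, rng):
        # carriers of the variance-increasing allele show larger spread
        n = 3000
        codes = rng.binomial(2, 0.5, n).astype(float)
        a_v = 0.8
        lnvar = 6.0 + a_v * codes + rng.standard_normal(n) * 0.1
        out = genotype_summary(lnvar, codes)
        assert out["mean"].iloc[0] < out["mean"].iloc[2]
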