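"""Canonical synthetic study designs for validating the pipeline.

Each function returns a :class:`~sirevar.simulate.SimConfig` describing one
regime of the emulated progeny-test design.  The generator's variance
parameters live on the sire's full genetic-value scale; a sire model sees a
quarter of them (the sire transmits half his genetic value), so a
"sire-scale variance ratio of 0.05" corresponds to ``sigma2_s = 0.2 *
sigma2_p`` here.

* :func:`recovery_design` — strong mean/variance genetics with genetic
  correlation 0.76 and sire-scale variance ratios ~0.05 on both parts; the
  regime for checking that the DHGLM recovers its own generating
  parameters.
* :func:`variance_qtl_design` — a single log-variance QTL explaining a
  target share of the between-sire variance of the log family variance;
  the regime for GWAS power and localisation.
* :func:`weak_variance_design` — genetic correlation 0.76 but nearly no
  genetic variance in the dispersion (the regime reported for yearling
  weight, where the heritability of residual variance is of order 0.01);
  under it the raw log family variance is dominated by sampling noise and
  decorrelates from the mean response while the deregressed variance EBV,
  which borrows mean information through the fitted covariance, does not.
"""

from __future__ import annotations

from dataclasses import replace

from sirevar.simulate import SimConfig

#: baseline residual variance on the yearling-weight scale, log(kg^2)
_ETA0 = 6.3
#: generator-scale genetic variance giving a sire-scale ratio of ~0.05
_SIGMA2_S = 126.0


def recovery_design(seed: int, n_sires: int = 500) -> SimConfig:
    """Strong-signal regime: sire-scale ratios ~0.05, r_mv = 0.76."""
    return SimConfig(
        n_sires=n_sires,
        n_chr=2,
        snps_per_chr=50,
        n_cg=40,
        sigma2_s=_SIGMA2_S,
        sigma2_sv=0.2,  # sire scale 0.05
        r_mv=0.76,
        eta0=_ETA0,
        seed=seed,
    )


def variance_qtl_design(
    seed: int,
    n_sires: int = 423,
    progeny_per_sire: int = 100,
    m_snps: int = 1000,
    lnvar_share: float = 0.2,
    sigma2_sv: float = 0.2,
) -> SimConfig:
    """One log-variance QTL explaining ``lnvar_share`` of Var(lnvar).

    The between-sire variance of the log family variance is approximately
    ``sigma2_sv/4 + 2/(n-1)`` (genetics plus sampling), so the QTL fraction
    of the genetic variance that yields the requested share is
    ``share * (1 + 8 / ((n-1) * sigma2_sv))``.
    """
    frac = lnvar_share * (1.0 + 8.0 / ((progeny_per_sire - 1) * sigma2_sv))
    if not frac < 1.0:
        raise ValueError("requested share unreachable at this family size")
    return SimConfig(
        n_sires=n_sires,
        progeny_min=progeny_per_sire,
        progeny_max=progeny_per_sire,
        n_chr=5,
        snps_per_chr=m_snps // 5,
        n_cg=40,
        sigma2_s=_SIGMA2_S,
        sigma2_sv=sigma2_sv,
        r_mv=0.76,
        n_qtl_mean=5,
        n_qtl_var=1,
        qtl_frac_var=frac,
        qtl_pleiotropy=False,
        eta0=_ETA0,
        seed=seed,
    )


def weak_variance_design(seed: int, n_sires: int = 300, m_snps: int = 500) -> SimConfig:
    """High r_mv but near-zero dispersion genetics (sire scale 0.001)."""
    return SimConfig(
        n_sires=n_sires,
        progeny_min=50,
        progeny_max=250,
        n_chr=5,
        snps_per_chr=m_snps // 5,
        n_cg=30,
        sigma2_s=_SIGMA2_S,
        sigma2_sv=0.004,  # sire scale 0.001
        r_mv=0.76,
        eta0=_ETA0,
        seed=seed,
    )


def sire_scale(cfg: SimConfig) -> dict[str, float]:
    """Generator variances translated to the sire-model scale."""
    return {"sigma2_s": cfg.sigma2_s / 4.0, "sigma2_sv": cfg.sigma2_sv / 4.0, "r_mv": cfg.r_mv}
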