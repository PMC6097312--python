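"""Synthetic half-sib data with genetic heterogeneity of residual variance.

The generator emulates a progeny-tested beef-cattle sire population: a few
hundred genotyped sires, each with a large group of phenotyped but
ungenotyped half-sib progeny, a trait on the yearling-weight scale, and
sire genetic effects on both the trait mean and the log residual variance.

Generative model, per progeny *j* of sire *i*::

    y_ij = mu + cg_j + beta1(sex_j) * age_j + beta2(sex_j) * age_j^2
           + 0.5 * A_m[i] + e_ij,
    e_ij ~ Normal(0, exp(eta0 + 0.5 * A_v[i]))

where ``A_m`` and ``A_v`` are the sire's total genetic values for the mean
(kg) and the log residual variance (log kg^2).  Each is the sum of a marked
part ``Z a`` over QTL genotypes and a polygenic part ``u``; the pair
``(u_m, u_v)`` is drawn jointly so that the total genetic correlation
targets ``r_mv`` and the total variances target ``sigma2_s`` / ``sigma2_sv``
in expectation.  The sire transmits half his genetic value, so the sire
(transmitting-ability) variance seen by a sire model is a quarter of the
configured genetic variance; Mendelian-sampling variation is absorbed into
the residual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sirevar.io import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mimic a Nellore yearling-weight design at desk scale: trait
    mean ``mu`` = 280 kg, baseline residual variance ``exp(eta0)`` ≈ 545 kg²
    (``eta0`` = 6.3), genetic correlation between mean and log residual
    variance ``r_mv`` = 0.76, and family sizes log-uniform on [50, 800].
    """

    n_sires: int = 423
    progeny_min: int = 50
    progeny_max: int = 800
    n_chr: int = 5
    snps_per_chr: int = 400
    chr_length_bp: int = 100_000_000
    maf_range: tuple[float, float] = (0.02, 0.5)
    #: number of QTL with an effect on the trait mean / on log residual variance
    n_qtl_mean: int = 10
    n_qtl_var: int = 10
    #: fraction of each genetic variance explained by the marked QTL
    qtl_frac_mean: float = 0.5
    qtl_frac_var: float = 0.5
    #: if True, mean- and variance-QTL positions coincide where set sizes
    #: allow and their effect pairs are drawn with correlation r_mv, so the
    #: total genetic correlation targets r_mv regardless of the QTL fraction
    qtl_pleiotropy: bool = True
    #: genetic variance of A_m (kg^2); sire-model scale is a quarter of this
    sigma2_s: float = 126.0
    #: genetic variance of A_v (log kg^2 squared); sire-model scale is a quarter
    sigma2_sv: float = 0.2
    r_mv: float = 0.76
    #: baseline log residual variance, log(kg^2)
    eta0: float = 6.3
    mu: float = 280.0
    n_cg: int = 40
    sigma2_cg: float = 100.0
    age_range: tuple[float, float] = (300.0, 420.0)
    #: (linear, quadratic) age coefficients per sex, on centred age (days)
    beta_age_m: tuple[float, float] = (0.45, -0.002)
    beta_age_f: tuple[float, float] = (0.40, -0.0018)
    #: probability a neighbouring SNP is copied (block-LD mode); 0 = LE
    ld_rho: float = 0.0
    seed: int = 2024

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if abs(self.r_mv) > 1.0:
            raise ValueError(f"|r_mv| must be <= 1, got {self.r_mv}")
        for name in ("sigma2_s", "sigma2_sv", "sigma2_cg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.progeny_min <= self.progeny_max):
            raise ValueError("need 0 < progeny_min <= progeny_max")
        if not (0.0 <= self.qtl_frac_mean <= 1.0 and 0.0 <= self.qtl_frac_var <= 1.0):
            raise ValueError("qtl_frac_* must lie in [0, 1]")


@dataclass
class SimTruth:
    """The latent state of one simulated study (the answer key).

    ``a_m`` / ``a_v`` are per-SNP true effects (zero off-QTL); ``u_m`` /
    ``u_v`` the polygenic parts and ``A_m`` / ``A_v`` the total genetic
    values per sire.  Fixed effects as realised are kept so a fitted model
    can be checked against the generating values.
    """

    a_m: np.ndarray
    a_v: np.ndarray
    qtl_mean_idx: np.ndarray
    qtl_var_idx: np.ndarray
    u_m: np.ndarray
    u_v: np.ndarray
    A_m: np.ndarray
    A_v: np.ndarray
    sire_ids: list[str]
    cg_effects: np.ndarray
    config: SimConfig = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sire_id": self.sire_ids, "u_m": self.u_m, "u_v": self.u_v, "A_m": self.A_m, "A_v": self.A_v}
        )


def _rng(cfg: SimConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed) % (2**31), salt]))


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Draw sire genotypes at Hardy-Weinberg proportions.

    Allele frequencies are uniform on ``maf_range``; SNPs are in linkage
    equilibrium unless ``ld_rho > 0``, in which case a SNP copies its left
    neighbour's genotype column with probability ``ld_rho`` (block LD).
    Positions are evenly spaced along each chromosome.
    """
    cfg.validate()
    rng = _rng(cfg, 1)
    m = cfg.n_chr * cfg.snps_per_chr
    freqs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    codes = rng.binomial(2, freqs[None, :], size=(cfg.n_sires, m)).astype(float)
    if cfg.ld_rho > 0:
        copy = rng.random(m) < cfg.ld_rho
        for j in range(1, m):
            if copy[j] and (j % cfg.snps_per_chr) != 0:  # never across a chromosome break
                codes[:, j] = codes[:, j - 1]
    spacing = cfg.chr_length_bp // cfg.snps_per_chr
    snp_map = pd.DataFrame(
        {
            "snp_id": [f"snp{j:06d}" for j in range(m)],
            "chromosome": np.repeat(np.arange(1, cfg.n_chr + 1), cfg.snps_per_chr),
            "bp": np.tile(spacing * np.arange(cfg.snps_per_chr) + spacing // 2 + 1, cfg.n_chr),
        }
    )
    sire_ids = [f"sire{int(i):04d}" for i in range(cfg.n_sires)]
    return GenotypeMatrix(sire_ids=sire_ids, snp_map=snp_map, codes=codes)


def _rescale_to_genic_var(codes_c: np.ndarray, idx: np.ndarray, effects: np.ndarray, target_var: float) -> np.ndarray:
    """Rescale a QTL effect vector so the realised genic variance hits target."""
    g = codes_c[:, idx] @ effects
    v = g.var()
    if v > 0 and target_var > 0:
        return effects * np.sqrt(target_var / v)
    return np.zeros_like(effects)


def simulate_truth(geno: GenotypeMatrix, cfg: SimConfig) -> SimTruth:
    """Draw QTL effects and polygenic values for every sire.

    QTL positions are sampled without replacement.  With pleiotropy on
    (the default) the two scales share positions where the set sizes allow
    and their effect pairs are drawn with correlation ``r_mv``; otherwise
    the sets are disjoint and only the polygenic parts are correlated (the
    total correlation is then attenuated by the QTL fractions).  Effects
    are rescaled so the marked parts explain ``qtl_frac_*`` of each genetic
    variance exactly in-sample, and the polygenic pair takes up the
    remainder with correlation ``r_mv``.
    """
    cfg.validate()
    rng = _rng(cfg, 2)
    m = geno.n_snps
    if cfg.n_qtl_mean + cfg.n_qtl_var > m:
        raise ValueError("more QTL requested than SNPs available")
    perm = rng.permutation(m)
    n_m, n_v = cfg.n_qtl_mean, cfg.n_qtl_var
    if cfg.qtl_pleiotropy:
        qtl_m_idx = np.sort(perm[:n_m])
        qtl_v_idx = np.sort(perm[:n_v])  # shared prefix: pleiotropic where possible
    else:
        qtl_m_idx = np.sort(perm[:n_m])
        qtl_v_idx = np.sort(perm[n_m : n_m + n_v])

    codes = geno.codes.copy()
    col_mean = np.nanmean(codes, axis=0)
    inds = np.where(np.isnan(codes))
    codes[inds] = np.take(col_mean, inds[1])
    codes_c = codes - codes.mean(axis=0)

    a_m = np.zeros(m)
    a_v = np.zeros(m)
    vq_m = cfg.qtl_frac_mean * cfg.sigma2_s if n_m > 0 else 0.0
    vq_v = cfg.qtl_frac_var * cfg.sigma2_sv if n_v > 0 else 0.0
    # raw effect pairs: correlated at the shared positions when pleiotropic
    raw_m = rng.standard_normal(max(n_m, n_v))
    raw_v_ind = rng.standard_normal(max(n_m, n_v))
    if cfg.qtl_pleiotropy:
        raw_v = cfg.r_mv * raw_m + np.sqrt(max(1.0 - cfg.r_mv**2, 0.0)) * raw_v_ind
    else:
        raw_v = raw_v_ind
    if n_m > 0:
        a_m[qtl_m_idx] = _rescale_to_genic_var(codes_c, qtl_m_idx, raw_m[:n_m], vq_m)
    if n_v > 0:
        a_v[qtl_v_idx] = _rescale_to_genic_var(codes_c, qtl_v_idx, raw_v[:n_v], vq_v)
    g_m = codes_c @ a_m
    g_v = codes_c @ a_v

    # polygenic remainder with correlation r_mv
    s2u_m = max(cfg.sigma2_s - vq_m, 0.0)
    s2u_v = max(cfg.sigma2_sv - vq_v, 0.0)
    cov_u = cfg.r_mv * np.sqrt(s2u_m * s2u_v)
    cov_mat = np.array([[s2u_m, cov_u], [cov_u, s2u_v]])
    u = rng.multivariate_normal([0.0, 0.0], cov_mat, size=geno.n_sires, method="svd")
    u_m, u_v = u[:, 0], u[:, 1]

    return SimTruth(
        a_m=a_m,
        a_v=a_v,
        qtl_mean_idx=qtl_m_idx,
        qtl_var_idx=qtl_v_idx,
        u_m=u_m,
        u_v=u_v,
        A_m=g_m + u_m,
        A_v=g_v + u_v,
        sire_ids=list(geno.sire_ids),
        cg_effects=rng.normal(0.0, np.sqrt(cfg.sigma2_cg), size=cfg.n_cg),
        config=cfg,
    )


def _draw_family_sizes(cfg: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Log-uniform family sizes on [progeny_min, progeny_max] (right-skewed,
    like real progeny-test data)."""
    lo, hi = np.log(cfg.progeny_min), np.log(cfg.progeny_max + 1)
    return np.minimum(np.floor(np.exp(rng.uniform(lo, hi, size=n))).astype(int), cfg.progeny_max)


def simulate_progeny(
    truth: SimTruth, cfg: SimConfig, family_sizes: np.ndarray | None = None
) -> pd.DataFrame:
    """Generate the progeny phenotype table for a simulated truth.

    Family sizes default to the configured log-uniform distribution; an
    explicit per-sire array may be supplied.  A sire given zero progeny is
    absent from the table (with a logged warning).
    """
    cfg.validate()
    rng = _rng(cfg, 3)
    n_sires = len(truth.sire_ids)
    if family_sizes is None:
        family_sizes = _draw_family_sizes(cfg, n_sires, rng)
    family_sizes = np.asarray(family_sizes, dtype=int)
    if (family_sizes == 0).any():
        for i in np.where(family_sizes == 0)[0]:
            logger.warning("simulate_progeny: sire %s has zero progeny and is absent", truth.sire_ids[i])

    sire_idx = np.repeat(np.arange(n_sires), family_sizes)
    n = len(sire_idx)
    cg = rng.integers(0, cfg.n_cg, size=n)
    sex = rng.integers(0, 2, size=n)  # 0 = F, 1 = M
    age = rng.uniform(cfg.age_range[0], cfg.age_range[1], size=n)
    age_c = age - 0.5 * (cfg.age_range[0] + cfg.age_range[1])

    b1 = np.where(sex == 1, cfg.beta_age_m[0], cfg.beta_age_f[0])
    b2 = np.where(sex == 1, cfg.beta_age_m[1], cfg.beta_age_f[1])
    resid_sd = np.exp(0.5 * (cfg.eta0 + 0.5 * truth.A_v[sire_idx]))
    y = (
        cfg.mu
        + truth.cg_effects[cg]
        + b1 * age_c
        + b2 * age_c**2
        + 0.5 * truth.A_m[sire_idx]
        + rng.standard_normal(n) * resid_sd
    )
    return pd.DataFrame(
        {
            "animal_id": [f"prog{k:07d}" for k in range(n)],
            "sire_id": [truth.sire_ids[i] for i in sire_idx],
            "cg": [f"cg{c:03d}" for c in cg],
            "sex": np.where(sex == 1, "M", "F"),
            "age": age,
            "y": y,
        }
    )


def simulate_study(cfg: SimConfig, family_sizes: np.ndarray | None = None):
    """Convenience wrapper: genotypes, truth and progeny table in one call."""
    geno = simulate_genotypes(cfg)
    truth = simulate_truth(geno, cfg)
    pheno = simulate_progeny(truth, cfg, family_sizes=family_sizes)
    return geno, truth, pheno
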