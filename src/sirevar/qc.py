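"""Chip-genotype quality control for the sire panel.

Filters, applied in this order: sex-chromosome removal, per-sire call
rate, minor allele frequency, Hardy-Weinberg equilibrium (1-df chi-square)
and LD pruning (r² within a sliding window of 100 consecutive retained
SNPs).  Each removed SNP is attributed to the first filter that caught it,
so the report's counts add up exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from sirevar.io import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class QcThresholds:
    maf_min: float = 0.02
    hwe_p_min: float = 1e-5
    ld_r2_max: float = 0.99
    ld_window: int = 100
    callrate_min: float = 0.90
    drop_sex_chr: bool = True
    #: chromosome codes treated as sex chromosomes (cattle: X=30, Y=31)
    sex_chromosomes: tuple[int, ...] = (30, 31)


@dataclass
class QcReport:
    n_input_snps: int
    n_removed_sex_chr: int
    n_removed_maf: int
    n_removed_hwe: int
    n_removed_ld: int
    n_removed_callrate_sires: int
    n_output_snps: int

    def __post_init__(self) -> None:
        removed = self.n_removed_sex_chr + self.n_removed_maf + self.n_removed_hwe + self.n_removed_ld
        assert self.n_output_snps == self.n_input_snps - removed


def compute_maf(codes: np.ndarray) -> float:
    """Minor allele frequency of one SNP from 0/1/2 codes (NaN = missing).

    Returns ``min(f, 1-f)`` with ``f`` the B-allele frequency; NaN if no
    calls at all (such a SNP is flagged for removal by the MAF filter).
    """
    codes = np.asarray(codes, dtype=float)
    called = codes[~np.isnan(codes)]
    if called.size == 0:
        return np.nan
    f = called.sum() / (2.0 * called.size)
    return float(min(f, 1.0 - f))


def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """One-df chi-square goodness-of-fit p-value against Hardy-Weinberg.

    Expected genotype counts come from the estimated allele frequency.
    Monomorphic SNPs return p = 1 by convention (the MAF filter handles
    them).
    """
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    f = (2 * n_bb + n_ab) / (2.0 * n)
    if f <= 0.0 or f >= 1.0:
        return 1.0
    expected = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2]) * n
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def _hwe_p_per_snp(codes: np.ndarray) -> np.ndarray:
    """Vectorised HWE p-values over the columns of a codes matrix."""
    n_aa = np.nansum(codes == 0, axis=0)
    n_ab = np.nansum(codes == 1, axis=0)
    n_bb = np.nansum(codes == 2, axis=0)
    n = n_aa + n_ab + n_bb
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (2 * n_bb + n_ab) / (2.0 * n)
        e_aa = (1 - f) ** 2 * n
        e_ab = 2 * f * (1 - f) * n
        e_bb = f**2 * n
        chi2 = (n_aa - e_aa) ** 2 / e_aa + (n_ab - e_ab) ** 2 / e_ab + (n_bb - e_bb) ** 2 / e_bb
    p = stats.chi2.sf(chi2, df=1)
    p[(f <= 0) | (f >= 1) | ~np.isfinite(chi2)] = 1.0
    return p


def ld_r2(codes_a: np.ndarray, codes_b: np.ndarray) -> float:
    """Squared Pearson correlation of two SNPs' codes over pairwise-complete
    sires; 0 if either SNP has no variance (nothing to prune on)."""
    a = np.asarray(codes_a, dtype=float)
    b = np.asarray(codes_b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _ld_prune(codes: np.ndarray, chrom: np.ndarray, candidate: np.ndarray, r2_max: float, window: int) -> np.ndarray:
    """Greedy scan in map order: drop the later SNP of any pair with
    r² > r2_max among the last ``window`` retained SNPs of the chromosome."""
    keep_mask = candidate.copy()
    for c in np.unique(chrom[candidate]):
        idx = np.where(candidate & (chrom == c))[0]
        retained: list[int] = []
        for j in idx:
            drop = False
            for k in retained[-(window - 1) :]:
                if ld_r2(codes[:, k], codes[:, j]) > r2_max:
                    drop = True
                    break
            if drop:
                keep_mask[j] = False
            else:
                retained.append(j)
    return keep_mask


def apply_qc(geno: GenotypeMatrix, thresholds: QcThresholds | None = None) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the full QC cascade and return the filtered panel plus report.

    The map must be sorted by (chromosome, bp).  Sires failing the call-rate
    threshold are removed before any SNP statistic is computed.
    """
    th = thresholds or QcThresholds()
    m = geno.snp_map
    if not m.sort_values(["chromosome", "bp"], kind="stable").index.equals(m.index):
        raise ValueError("SNP map must be sorted by (chromosome, bp)")

    n_input = geno.n_snps
    sire_keep = geno.call_rate >= th.callrate_min
    n_sires_removed = int((~sire_keep).sum())
    if n_sires_removed:
        logger.info("apply_qc: removed %d sire(s) below call rate %.2f", n_sires_removed, th.callrate_min)
    geno = geno.subset(sire_mask=sire_keep)

    chrom = geno.snp_map["chromosome"].to_numpy()
    alive = np.ones(geno.n_snps, dtype=bool)

    if th.drop_sex_chr:
        sex = np.isin(chrom, th.sex_chromosomes)
        n_sex = int((alive & sex).sum())
        alive &= ~sex
    else:
        n_sex = 0

    codes = geno.codes
    mafs = np.array([compute_maf(codes[:, j]) if alive[j] else np.nan for j in range(geno.n_snps)])
    maf_fail = alive & (np.isnan(mafs) | (mafs < th.maf_min))
    n_maf = int(maf_fail.sum())
    alive &= ~maf_fail

    hwe_p = _hwe_p_per_snp(codes)
    hwe_fail = alive & (hwe_p < th.hwe_p_min)
    n_hwe = int(hwe_fail.sum())
    alive &= ~hwe_fail

    if th.ld_r2_max < 1.0:
        pruned = _ld_prune(codes, chrom, alive, th.ld_r2_max, th.ld_window)
    else:
        pruned = alive
    n_ld = int(alive.sum() - pruned.sum())
    alive = pruned

    n_out = int(alive.sum())
    if n_out == 0:
        raise ValueError("no SNPs survive QC")
    report = QcReport(
        n_input_snps=n_input,
        n_removed_sex_chr=n_sex,
        n_removed_maf=n_maf,
        n_removed_hwe=n_hwe,
        n_removed_ld=n_ld,
        n_removed_callrate_sires=n_sires_removed,
        n_output_snps=n_out,
    )
    return geno.subset(snp_mask=alive), report
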