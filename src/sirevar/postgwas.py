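"""Inferential summaries of sampler output.

Bayes factors per SNP, genetic-variance partitioning over non-overlapping
1-Mb windows, top-window overlaps between response variables, pairwise
response correlations, a scale-effect test for shared mean/variance
signals, and per-genotype summaries for box plots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Bayes-factor classification thresholds: suggestive / strong
BF_SUGGESTIVE = 3.0
BF_STRONG = 20.0


def bayes_factor(p, prior_inclusion: float, n_kept: int | None = None):
    """Posterior odds of SNP inclusion over prior odds.

    ``BF = (p/(1-p)) / (q/(1-q))`` with ``q`` the prior inclusion
    probability (``1 - pi``).  A posterior probability of exactly 1 is
    capped at ``1 - 1/(n_kept+1)`` (one phantom excluded sample) so the BF
    stays finite; the cap is logged when applied.
    """
    if not (0.0 < prior_inclusion < 1.0):
        raise ValueError(f"prior inclusion probability must be in (0,1), got {prior_inclusion}")
    p = np.asarray(p, dtype=float)
    scalar = p.ndim == 0
    p = np.atleast_1d(p).copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("posterior probabilities must lie in [0, 1]")
    at_one = p >= 1.0
    if at_one.any():
        if n_kept is None:
            raise ValueError("p = 1 needs n_kept to apply the finite-BF cap")
        p[at_one] = 1.0 - 1.0 / (n_kept + 1.0)
        logger.info("bayes_factor: capped %d posterior probabilities of 1", int(at_one.sum()))
    prior_odds = prior_inclusion / (1.0 - prior_inclusion)
    bf = (p / (1.0 - p)) / prior_odds
    return float(bf[0]) if scalar else bf


def window_index(bp) -> np.ndarray:
    """0-based 1-Mb window index from 1-based physical position."""
    return ((np.asarray(bp, dtype=np.int64) - 1) // 1_000_000).astype(np.int64)


def window_label(chromosome, widx) -> pd.Series:
    return pd.Series([f"Chr{c}_{w}" for c, w in zip(np.atleast_1d(chromosome), np.atleast_1d(widx))])


def window_variance(
    Z: np.ndarray,
    a_hat: np.ndarray,
    snp_map: pd.DataFrame,
    bf: np.ndarray | None = None,
    denominator: str = "total",
) -> pd.DataFrame:
    """Percent of genetic variance explained by each 1-Mb window.

    The window genomic value is ``g_w = Z_w a_w`` over the realised
    genotypes; ``pct = Var(g_w) / D * 100`` where the denominator ``D`` is
    the variance of the total genomic value ``Z a`` (``denominator="total"``,
    GenSel-style) or the sum of the per-window variances
    (``denominator="window_sum"``, which forces the shares to add to 100).
    Windows are returned sorted by share, descending; ties and the ordering
    of equal shares are broken by (chromosome, window_index).
    """
    if denominator not in ("total", "window_sum"):
        raise ValueError("denominator must be 'total' or 'window_sum'")
    Z = np.asarray(Z, dtype=float)
    a_hat = np.asarray(a_hat, dtype=float)
    if Z.shape[1] != len(a_hat) or Z.shape[1] != len(snp_map):
        raise ValueError("Z columns, effects and map must align")
    Zc = Z - Z.mean(axis=0)
    g_total = Zc @ a_hat
    var_total = float(g_total.var(ddof=1))

    chrom = snp_map["chromosome"].to_numpy()
    widx = window_index(snp_map["bp"].to_numpy())
    keys = pd.DataFrame({"chromosome": chrom, "window_index": widx})
    rows = []
    all_zero = not np.any(a_hat != 0.0)
    if all_zero:
        logger.warning("window_variance: all effects are zero; reporting zero shares")
    var_windows = {}
    for (c, w), idx in keys.groupby(["chromosome", "window_index"], sort=True).groups.items():
        idx = np.asarray(idx)
        g_w = Zc[:, idx] @ a_hat[idx]
        var_w = float(g_w.var(ddof=1))
        var_windows[(c, w)] = (idx, var_w)
    denom = var_total if denominator == "total" else sum(v for _, v in var_windows.values())
    for (c, w), (idx, var_w) in var_windows.items():
        pct = 0.0 if (denom <= 0 or all_zero) else 100.0 * var_w / denom
        if bf is not None:
            top_local = idx[int(np.argmax(bf[idx]))]
            top_id = snp_map["snp_id"].iloc[top_local]
            top_bf = float(bf[top_local])
        else:
            top_id, top_bf = None, np.nan
        rows.append(
            {
                "chromosome": int(c),
                "window_index": int(w),
                "label": f"Chr{c}_{w}",
                "n_snps": int(len(idx)),
                "pct_genetic_variance": pct,
                "top_snp_id": top_id,
                "top_snp_BF": top_bf,
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["pct_genetic_variance", "chromosome", "window_index"],
        ascending=[False, True, True],
        kind="stable",
    )
    return out.reset_index(drop=True)


@dataclass
class OverlapReport:
    """Shared top-K 1-Mb windows between two responses."""

    k: int
    n_shared: int
    shared: list[str]

    def __post_init__(self) -> None:
        assert 0 <= self.n_shared <= self.k


def _top_k_labels(summary: pd.DataFrame, k: int) -> set[str]:
    ranked = summary.sort_values(
        ["pct_genetic_variance", "chromosome", "window_index"],
        ascending=[False, True, True],
        kind="stable",
    )
    return set(ranked["label"].head(k))


def top_windows_overlap(summary_a: pd.DataFrame, summary_b: pd.DataFrame, k: int = 20) -> OverlapReport:
    """Count the windows shared by both top-K lists (set semantics).

    Ties at rank K are broken by (chromosome, window_index) ascending, so
    the result is deterministic.  K larger than the available window count
    is clipped with a warning.
    """
    n_avail = min(len(summary_a), len(summary_b))
    if k > n_avail:
        logger.warning("top_windows_overlap: K=%d clipped to %d available windows", k, n_avail)
        k = n_avail
    shared = sorted(_top_k_labels(summary_a, k) & _top_k_labels(summary_b, k))
    return OverlapReport(k=k, n_shared=len(shared), shared=shared)


def response_correlations(responses: pd.DataFrame, columns=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlations between response columns.

    Returns (r, se) matrices with ``se = sqrt((1-r^2)/(n-2))``.  Pairs with
    fewer than 3 complete sires or a zero-variance member are NA.
    """
    if columns is None:
        from sirevar.responses import RESPONSE_NAMES

        columns = [c for c in RESPONSE_NAMES if c in responses.columns]
    k = len(columns)
    r = pd.DataFrame(np.eye(k), index=columns, columns=columns)
    se = pd.DataFrame(np.zeros((k, k)), index=columns, columns=columns)
    for i in range(k):
        for j in range(i + 1, k):
            sub = responses[[columns[i], columns[j]]].dropna()
            n = len(sub)
            if n < 3 or sub[columns[i]].std() == 0 or sub[columns[j]].std() == 0:
                rij, seij = np.nan, np.nan
            else:
                rij = float(sub[columns[i]].corr(sub[columns[j]]))
                seij = float(np.sqrt((1.0 - rij**2) / (n - 2)))
            r.iloc[i, j] = r.iloc[j, i] = rij
            se.iloc[i, j] = se.iloc[j, i] = seij
    return r, se


def scale_effect_test(a_mean: float, a_var: float, mean_trait: float, mean_resid_var: float):
    """Test whether a shared signal exceeds a pure scale effect.

    The absolute SNP effect on the mean response is standardised by the
    trait mean, the effect on the variance response by the mean residual
    variance.  If variance signals were mere scaling of the mean, the
    standardised mean effect would be at least as large; a strictly larger
    standardised variance effect flags an effect on dispersion beyond
    scale.

    Returns ``(std_mean, std_var, beyond_scale)``.
    """
    if mean_trait <= 0 or mean_resid_var <= 0:
        raise ValueError("standardising denominators must be positive")
    std_mean = abs(float(a_mean)) / float(mean_trait)
    std_var = abs(float(a_var)) / float(mean_resid_var)
    return std_mean, std_var, bool(std_var > std_mean)


def genotype_summary(values, codes) -> pd.DataFrame:
    """Per-genotype-class summaries of a response (box-plot-ready).

    One row per code in {0, 1, 2} with n, mean, quartiles and SD; an empty
    class yields an all-NA row rather than an error.
    """
    values = np.asarray(values, dtype=float)
    codes = np.asarray(codes, dtype=float)
    if len(values) != len(codes):
        raise ValueError("values and codes must align")
    called = codes[~np.isnan(codes)]
    if np.unique(called).size < 2:
        raise ValueError("SNP is monomorphic")
    rows = []
    for g in (0.0, 1.0, 2.0):
        v = values[codes == g]
        v = v[~np.isnan(v)]
        if v.size == 0:
            rows.append({"genotype": int(g), "n": 0, "mean": np.nan, "q1": np.nan, "median": np.nan, "q3": np.nan, "sd": np.nan})
        else:
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            rows.append(
                {
                    "genotype": int(g),
                    "n": int(v.size),
                    "mean": float(v.mean()),
                    "q1": float(q1),
                    "median": float(med),
                    "q3": float(q3),
                    "sd": float(v.std(ddof=1)) if v.size > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)
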