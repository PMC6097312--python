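"""GWAS response variables built from a pair of DHGLM fits.

Four per-sire responses are produced:

* ``dEBV_m`` — deregressed EBV for the trait mean, from the fit with the
  mean/variance genetic correlation free;
* ``dEBV_v`` — deregressed EBV for the log residual variance, same fit;
* ``dEBV_v_r0`` — deregressed EBV for the log residual variance from the
  fit with the correlation constrained to zero;
* ``lnvar`` — natural log of the sample variance of the zero-correlation
  fit's mean-part residuals within each sire family.

Deregression follows the no-parent-information Garrick procedure:
``dEBV = EBV / r²`` with weight ``w = (1-h²) / ((c + (1-r²)/r²) h²)``,
where ``c`` is the fraction of genetic variance not captured by markers.
The heritability plugged into the weights is derived from the DHGLM's own
components via the sire-model identity ``h² = 4 s2_s / (4 s2_s + mean phi)``
per part.  ``lnvar`` records are weighted by family size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sirevar.dhglm import DHGLMResults

logger = logging.getLogger(__name__)

RESPONSE_NAMES = ("dEBV_m", "dEBV_v", "dEBV_v_r0", "lnvar")


def deregress(ebv, r2, h2: float, c: float = 0.5):
    """Deregress EBVs (no-parent-information Garrick variant).

    Parameters
    ----------
    ebv, r2
        EBV and reliability per sire (scalars or arrays); requires
        ``0 < r2 <= 1``.
    h2
        Heritability of the response on the record scale, in (0, 1).
    c
        Fraction of genetic variance not captured by markers, in [0, 1).

    Returns
    -------
    (dEBV, w)
        ``dEBV = ebv / r2`` and the residual weight
        ``w = (1-h2) / ((c + (1-r2)/r2) * h2)``.
    """
    ebv = np.asarray(ebv, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if not (0.0 < h2 < 1.0):
        raise ValueError(f"h2 must be in (0,1), got {h2}")
    if not (0.0 <= c < 1.0):
        raise ValueError(f"c must be in [0,1), got {c}")
    if (r2 <= 0).any() or (r2 > 1).any():
        raise ValueError("reliabilities must lie in (0, 1]")
    debv = ebv / r2
    # perfect reliability with c = 0 leaves no residual term in the weight
    # denominator; by convention the factor is then 1 (shrinkage-free weight)
    factor = c + (1.0 - r2) / r2
    factor = np.where(factor <= 0, 1.0, factor)
    w = (1.0 - h2) / (factor * h2)
    return debv, w


def ln_residual_variance(residuals: pd.DataFrame, min_progeny: int = 2) -> pd.Series:
    """Per-sire log sample variance of mean-model residuals.

    ``residuals`` needs columns ``sire_id`` and ``resid``.  Uses the n-1
    denominator and the natural log.  Families with fewer than two progeny,
    or with a degenerate (zero) variance, are excluded with a log entry.
    """
    grouped = residuals.groupby("sire_id")["resid"]
    n = grouped.size()
    var = grouped.var(ddof=1)
    small = n[n < min_progeny].index
    for sire in small:
        logger.info("ln_residual_variance: sire %s excluded (%d progeny)", sire, n[sire])
    degenerate = var[(var <= 0) & ~var.index.isin(small)].index
    for sire in degenerate:
        logger.info("ln_residual_variance: sire %s excluded (degenerate family)", sire)
    keep = var.index.difference(small).difference(degenerate)
    return np.log(var.loc[keep]).rename("lnvar")


def _part_h2(sigma2_s: float, mean_resid_var: float) -> float:
    """Record-scale heritability from sire components: 4 s2_s/(4 s2_s + phi)."""
    h2 = 4.0 * sigma2_s / (4.0 * sigma2_s + mean_resid_var)
    return float(np.clip(h2, 1e-6, 1.0 - 1e-6))


@dataclass
class SireResponseSet:
    """The four GWAS responses with their residual weights, one row per sire."""

    table: pd.DataFrame  # sire_id, n_progeny, dEBV_m, w_m, dEBV_v, w_v, dEBV_v_r0, w_v_r0, lnvar
    h2_m: float
    h2_v: float
    c: float

    @property
    def sire_ids(self) -> list[str]:
        return list(self.table["sire_id"])

    def response(self, name: str) -> tuple[pd.Series, pd.Series]:
        """Return (values, weights) for one response, complete cases only.

        The lnvar weight is the family size (its sampling variance scales
        as 1/n), matching a residual matrix with elements 1/n per sire.
        """
        if name not in RESPONSE_NAMES:
            raise KeyError(f"unknown response {name!r}; choose from {RESPONSE_NAMES}")
        t = self.table.set_index("sire_id")
        weights = {
            "dEBV_m": "w_m",
            "dEBV_v": "w_v",
            "dEBV_v_r0": "w_v_r0",
            "lnvar": "n_progeny",
        }
        sub = t[[name, weights[name]]].dropna()
        return sub[name], sub[weights[name]].astype(float)

    def descriptives(self) -> pd.DataFrame:
        """N / mean / SD / min / max per response (a Table-6-style layout)."""
        rows = []
        for name in RESPONSE_NAMES:
            v = self.table[name].dropna()
            rows.append(
                {
                    "response": name,
                    "N": int(len(v)),
                    "mean": v.mean(),
                    "SD": v.std(ddof=1),
                    "min": v.min(),
                    "max": v.max(),
                }
            )
        return pd.DataFrame(rows)


def assemble_responses(
    fit_free: DHGLMResults,
    fit_zero: DHGLMResults,
    h2_m: float | None = None,
    h2_v: float | None = None,
    c: float = 0.5,
) -> SireResponseSet:
    """Build all four responses from the two DHGLM fits.

    ``fit_free`` supplies dEBV_m and dEBV_v; ``fit_zero`` supplies
    dEBV_v_r0 (its variance part) and lnvar (its mean-part residuals).
    Heritabilities default to values derived from ``fit_free``'s own
    variance components.  Sires present in only one fit, or with zero
    reliability, are excluded with a log entry.
    """
    if fit_zero.mode != "rmv_zero":
        raise ValueError("fit_zero must come from mode='rmv_zero'")
    common = fit_free.mean_part.s.index.intersection(fit_zero.mean_part.s.index)
    dropped = fit_free.mean_part.s.index.symmetric_difference(fit_zero.mean_part.s.index)
    for sire in dropped:
        logger.info("assemble_responses: sire %s present in one fit only, excluded", sire)

    if h2_m is None:
        h2_m = _part_h2(fit_free.sigma2_s, float(np.mean(fit_free.phi)))
    if h2_v is None:
        h2_v = _part_h2(fit_free.sigma2_sv, float(np.mean(fit_free.var_part.resid_variances)))

    rel_free = fit_free.reliabilities().set_index("sire_id").loc[common]
    rel_zero = fit_zero.reliabilities().set_index("sire_id").loc[common]

    def _dereg(ebv: pd.Series, r2: pd.Series, h2: float):
        ok = r2 > 0
        for sire in r2.index[~ok]:
            logger.info("assemble_responses: sire %s has zero reliability, excluded", sire)
        d = pd.Series(np.nan, index=r2.index)
        w = pd.Series(np.nan, index=r2.index)
        d[ok], w[ok] = deregress(ebv[ok].to_numpy(), r2[ok].clip(upper=1.0).to_numpy(), h2, c)
        return d, w

    debv_m, w_m = _dereg(fit_free.mean_part.s.loc[common], rel_free["r2_m"], h2_m)
    debv_v, w_v = _dereg(fit_free.var_part.s.loc[common], rel_free["r2_v"], h2_v)
    debv_v_r0, w_v_r0 = _dereg(fit_zero.var_part.s.loc[common], rel_zero["r2_v"], h2_v)

    # lnvar: log family variance of the zero-correlation mean-model residuals
    resid_df = pd.DataFrame(
        {"sire_id": fit_zero.record_sire_ids, "resid": fit_zero.mean_part.residuals}
    )
    lnvar = ln_residual_variance(resid_df)

    table = pd.DataFrame(
        {
            "sire_id": common,
            "n_progeny": fit_free.n_progeny.loc[common].to_numpy(),
            "dEBV_m": debv_m.to_numpy(),
            "w_m": w_m.to_numpy(),
            "dEBV_v": debv_v.to_numpy(),
            "w_v": w_v.to_numpy(),
            "dEBV_v_r0": debv_v_r0.to_numpy(),
            "w_v_r0": w_v_r0.to_numpy(),
        }
    )
    table["lnvar"] = lnvar.reindex(common).to_numpy()
    return SireResponseSet(table=table, h2_m=h2_m, h2_v=h2_v, c=c)
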