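"""Bivariate sire DHGLM: joint mixed models for a trait's mean and its log
residual variance.

The model couples two sire linear mixed models.  The mean part is

    y = X b + Z s + e,        Var(e_ij) = phi_ij,

with ``phi`` itself modelled on the log scale through the variance part

    psi = X_v b_v + Z_v s_v + e_v,

where ``psi`` is a linearised working response built from the mean part's
squared residuals (``psi_ij = log phi_ij + e_ij^2 / ((1-h_ij) phi_ij) - 1``)
and each psi-record carries a fixed residual variance ``2/(1-h_ij)``, the
asymptotic gamma-GLM value.  The sire effect pair ``(s_i, s_vi)`` is
bivariate normal with covariance matrix ``G0``; the genetic correlation
between mean and log residual variance is ``r_mv = cov / sqrt(s2_s s2_sv)``.
``G0`` is updated by EM-REML, which keeps the variances non-negative; a
2x2 update leaving the parameter space is bent back (eigenvalue floor).

Fixed effects in both parts: contemporary group, plus linear and quadratic
age nested within sex.  With ``mode="rmv_zero"`` the covariance is pinned
to zero and the two parts decouple exactly into stand-alone weighted sire
LMMs.

The fitted sire solutions ``s`` are used directly as EBVs; the factor-2
transmitting-ability rescaling is a global constant that cancels in the
deregression-based GWAS downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

logger = logging.getLogger(__name__)

_LOGVAR_CLIP = 30.0  # guard on fitted log-variances before exponentiation


class ConfoundingError(ValueError):
    """The fixed-effect block is singular (e.g. a confounded CG level)."""


@dataclass
class MixedModelFit:
    """Solutions of one weighted sire LMM (one part of the DHGLM)."""

    b: pd.Series  # fixed-effect solutions, indexed by column name
    s: pd.Series  # sire solutions (EBVs), indexed by sire id
    residuals: np.ndarray  # per record, in data order
    leverages: np.ndarray  # hat-matrix diagonal per record
    pev: pd.Series  # prediction error variance per sire
    sigma2_s: float  # sire variance used
    resid_variances: np.ndarray  # per-record residual variances used


class _Design:
    """Shared design matrices: CG one-hot plus age/age^2 within sex, and a
    sire index.  Age is centred and scaled by 100 days for conditioning."""

    def __init__(self, pheno: pd.DataFrame, trait: str = "y"):
        pheno = pheno.reset_index(drop=True)
        self.y = pheno[trait].to_numpy(dtype=float)
        self.n = len(pheno)
        if self.n == 0:
            raise ValueError("empty phenotype table")

        sire_cat = pd.Categorical(pheno["sire_id"].astype(str))
        self.sire_ids = list(sire_cat.categories)
        self.sire_idx = np.asarray(sire_cat.codes, dtype=np.int64)
        self.q = len(self.sire_ids)
        self.n_progeny = np.bincount(self.sire_idx, minlength=self.q)

        cg_cat = pd.Categorical(pheno["cg"].astype(str))
        sex_cat = pd.Categorical(pheno["sex"].astype(str))
        age = pheno["age"].to_numpy(dtype=float)
        age_c = (age - age.mean()) / 100.0

        cols = []
        names = []
        cg_codes = np.asarray(cg_cat.codes)
        for k, lev in enumerate(cg_cat.categories):
            cols.append((cg_codes == k).astype(float))
            names.append(f"cg[{lev}]")
        sex_codes = np.asarray(sex_cat.codes)
        for k, lev in enumerate(sex_cat.categories):
            ind = (sex_codes == k).astype(float)
            cols.append(ind * age_c)
            names.append(f"age[{lev}]")
            cols.append(ind * age_c**2)
            names.append(f"age2[{lev}]")
        X = np.column_stack(cols)
        # degenerate covariate columns (e.g. constant age) carry no signal
        keep = np.abs(X).max(axis=0) > 0
        self.X = X[:, keep]
        self.x_names = [n for n, k in zip(names, keep) if k]
        self.p = self.X.shape[1]

    def _part_blocks(self, w: np.ndarray, resp: np.ndarray):
        """Normal-equation blocks for one part given record weights w."""
        Xw = self.X * w[:, None]
        XtWX = self.X.T @ Xw
        XtWZ = np.column_stack(
            [np.bincount(self.sire_idx, weights=Xw[:, k], minlength=self.q) for k in range(self.p)]
        )
        ZtWZ = np.bincount(self.sire_idx, weights=w, minlength=self.q)
        XtWy = Xw.T @ resp
        ZtWy = np.bincount(self.sire_idx, weights=w * resp, minlength=self.q)
        return XtWX, XtWZ, ZtWZ, XtWy, ZtWy


def _bend_psd(G: np.ndarray, floor_frac: float = 1e-8) -> np.ndarray:
    """Project a symmetric 2x2 onto the PSD cone with a small eigen floor."""
    vals, vecs = np.linalg.eigh(G)
    floor = floor_frac * max(vals.max(), 1e-30)
    if vals.min() >= floor:
        return G
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T


def _solve_univariate(design: _Design, resp: np.ndarray, resid_var: np.ndarray, sigma2_s: float):
    """Solve one weighted sire LMM's MME; returns solutions, per-record
    leverages, per-sire PEV."""
    w = 1.0 / resid_var
    p, q = design.p, design.q
    XtWX, XtWZ, ZtWZ, XtWy, ZtWy = design._part_blocks(w, resp)
    if sigma2_s <= 0:
        # ridge limit: random effects vanish, pure WLS
        try:
            b = linalg.solve(XtWX, XtWy, assume_a="pos")
        except linalg.LinAlgError as exc:
            raise ConfoundingError(f"singular fixed-effect block: {exc}") from exc
        fitted = design.X @ b
        Cxx_inv = linalg.inv(XtWX)
        h = np.einsum("np,pq,nq->n", design.X, Cxx_inv, design.X) * w
        return b, np.zeros(q), resp - fitted, h, np.zeros(q)
    C = np.zeros((p + q, p + q))
    C[:p, :p] = XtWX
    C[:p, p:] = XtWZ.T
    C[p:, :p] = XtWZ
    C[p:, p:] = np.diag(ZtWZ + 1.0 / sigma2_s)
    rhs = np.concatenate([XtWy, ZtWy])
    try:
        cf = linalg.cho_factor(C)
    except linalg.LinAlgError as exc:
        raise ConfoundingError(
            "singular mixed-model equations; a contemporary-group level is "
            f"likely confounded ({exc})"
        ) from exc
    sol = linalg.cho_solve(cf, rhs)
    Cinv = linalg.cho_solve(cf, np.eye(p + q))
    b, s = sol[:p], sol[p:]
    fitted = design.X @ b + s[design.sire_idx]
    resid = resp - fitted
    h = _record_leverages(design, Cinv[:p, :p], Cinv[:p, p:], np.diag(Cinv[p:, p:]), w)
    pev = np.diag(Cinv)[p:]
    return b, s, resid, h, pev


def _record_leverages(design: _Design, Cxx: np.ndarray, Cxs: np.ndarray, Css_diag: np.ndarray, w: np.ndarray) -> np.ndarray:
    """h_ij = w_ij * t_ij' Cinv t_ij for records t = (x_row, sire indicator)."""
    X, sidx = design.X, design.sire_idx
    quad = ((X @ Cxx) * X).sum(axis=1)
    quad += 2.0 * (X * Cxs[:, sidx].T).sum(axis=1)
    quad += Css_diag[sidx]
    return quad * w


def fit_mean_model(
    pheno: pd.DataFrame, phi: np.ndarray | float, sigma2_s: float, trait: str = "y"
) -> MixedModelFit:
    """Fit the mean part alone: a weighted sire LMM with known per-record
    residual variances ``phi`` and sire variance ``sigma2_s``.

    Solves Henderson's mixed-model equations with record weights ``1/phi``;
    leverages are the hat-matrix diagonal of the fitted values (fixed plus
    random), and PEV comes from the inverse coefficient matrix.
    """
    design = _Design(pheno, trait=trait)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (design.n,)).copy()
    if (phi <= 0).any():
        raise ValueError("phi must be positive")
    b, s, resid, h, pev = _solve_univariate(design, design.y, phi, sigma2_s)
    return MixedModelFit(
        b=pd.Series(b, index=design.x_names),
        s=pd.Series(s, index=design.sire_ids),
        residuals=resid,
        leverages=h,
        pev=pd.Series(pev, index=design.sire_ids),
        sigma2_s=float(sigma2_s),
        resid_variances=phi,
    )


def working_response(fit: MixedModelFit, phi: np.ndarray | float) -> tuple[np.ndarray, np.ndarray]:
    """Linearised log-variance response and record weights.

    ``psi_ij = log(phi_ij) + e_ij^2 / ((1-h_ij) phi_ij) - 1`` with record
    weight ``(1-h_ij)/2`` (the psi-record residual variance is fixed at
    ``2/(1-h_ij)``).
    """
    phi = np.broadcast_to(np.asarray(phi, dtype=float), fit.residuals.shape)
    h = fit.leverages
    if (h >= 1.0).any():
        raise ValueError("saturated record: leverage >= 1")
    psi = np.log(phi) + fit.residuals**2 / ((1.0 - h) * phi) - 1.0
    weight = (1.0 - h) / 2.0
    return psi, weight


@dataclass
class DHGLMResults:
    """Converged (or best-so-far) state of a bivariate sire DHGLM fit."""

    mean_part: MixedModelFit
    var_part: MixedModelFit
    sigma2_s: float
    sigma2_sv: float
    cov_s_sv: float
    pev_cross: pd.Series  # prediction error covariance per sire (s, s_v)
    phi: np.ndarray  # fitted residual variance per record
    psi: np.ndarray  # final working response
    record_sire_ids: np.ndarray  # sire id of each record, in data order
    n_progeny: pd.Series
    mode: str
    converged: bool
    n_iter: int
    delta_trace: list = field(repr=False, default_factory=list)

    @property
    def r_mv(self) -> float:
        denom = np.sqrt(self.sigma2_s * self.sigma2_sv)
        return float(self.cov_s_sv / denom) if denom > 0 else 0.0

    def reliabilities(self) -> pd.DataFrame:
        """Per-sire reliabilities r² = 1 - PEV/sigma²_s for both parts."""
        if self.sigma2_s <= 0 or self.sigma2_sv <= 0:
            raise ValueError("reliability undefined: a sire variance is zero")
        r2_m = 1.0 - self.mean_part.pev / self.sigma2_s
        r2_v = 1.0 - self.var_part.pev / self.sigma2_sv
        return pd.DataFrame(
            {
                "sire_id": self.mean_part.s.index,
                "n_progeny": self.n_progeny.to_numpy(),
                "r2_m": r2_m.to_numpy(),
                "r2_v": r2_v.to_numpy(),
            }
        )

    def summary(self) -> str:
        lines = [
            "Bivariate sire DHGLM" + (" (r_mv constrained to 0)" if self.mode == "rmv_zero" else ""),
            "=" * 58,
            f"records: {len(self.phi):>10d}    sires: {len(self.mean_part.s):>6d}",
            f"converged: {self.converged}    iterations: {self.n_iter}",
            "-" * 58,
            f"sigma2_s  (sire var, mean part)      {self.sigma2_s:12.6g}",
            f"sigma2_sv (sire var, log-var part)   {self.sigma2_sv:12.6g}",
            f"cov_s_sv                             {self.cov_s_sv:12.6g}",
            f"r_mv                                 {self.r_mv:12.4f}",
            f"mean fitted residual variance        {float(np.mean(self.phi)):12.6g}",
            f"mean log residual variance           {float(np.mean(np.log(self.phi))):12.4f}",
            "-" * 58,
            "fixed effects (mean | log-variance part):",
        ]
        for name in self.mean_part.b.index:
            lines.append(f"  {name:<16s} {self.mean_part.b[name]:12.5g} | {self.var_part.b[name]:12.5g}")
        return "\n".join(lines)


class SireDHGLM:
    """Bivariate sire DHGLM for a progeny phenotype table.

    Parameters
    ----------
    pheno
        Progeny records with columns ``sire_id, cg, sex, age`` and the trait.
    trait
        Trait column name (default ``"y"``).

    Examples
    --------
    >>> fit = SireDHGLM(pheno).fit(mode="rmv_free")
    >>> fit.r_mv, fit.sigma2_sv     # doctest: +SKIP
    """

    def __init__(self, pheno: pd.DataFrame, trait: str = "y"):
        self.pheno = pheno.reset_index(drop=True)
        self.trait = trait
        self._design = _Design(self.pheno, trait=trait)
        if self._design.q < 2:
            logger.warning("fewer than 2 sires; variance components are not identifiable")

    @classmethod
    def from_dataframe(cls, pheno: pd.DataFrame, trait: str = "y") -> "SireDHGLM":
        return cls(pheno, trait=trait)

    # ------------------------------------------------------------------
    def _solve_stacked(self, phi, psi, w_v, G0):
        """One joint solve of the stacked bivariate MME given the current
        working response and weights; returns solutions and the pieces of
        the inverse coefficient matrix needed for leverages and PEV."""
        d = self._design
        p, q = d.p, d.q
        w_m = 1.0 / phi
        Am, Bm, Dm, rxm, rzm = d._part_blocks(w_m, d.y)
        Av, Bv, Dv, rxv, rzv = d._part_blocks(w_v, psi)
        Ginv = np.linalg.inv(G0)

        dim = 2 * (p + q)
        C = np.zeros((dim, dim))
        # order: [b_m (p), s_m (q), b_v (p), s_v (q)]
        sl_bm = slice(0, p)
        sl_sm = slice(p, p + q)
        sl_bv = slice(p + q, 2 * p + q)
        sl_sv = slice(2 * p + q, dim)
        C[sl_bm, sl_bm] = Am
        C[sl_bm, sl_sm] = Bm.T
        C[sl_sm, sl_bm] = Bm
        C[sl_sm, sl_sm] = np.diag(Dm + Ginv[0, 0])
        C[sl_bv, sl_bv] = Av
        C[sl_bv, sl_sv] = Bv.T
        C[sl_sv, sl_bv] = Bv
        C[sl_sv, sl_sv] = np.diag(Dv + Ginv[1, 1])
        idx_sm = np.arange(p, p + q)
        idx_sv = np.arange(2 * p + q, dim)
        C[idx_sm, idx_sv] = Ginv[0, 1]
        C[idx_sv, idx_sm] = Ginv[0, 1]
        rhs = np.concatenate([rxm, rzm, rxv, rzv])
        try:
            cf = linalg.cho_factor(C)
        except linalg.LinAlgError as exc:
            raise ConfoundingError(
                "singular stacked mixed-model equations; check for a "
                f"confounded contemporary-group level ({exc})"
            ) from exc
        sol = linalg.cho_solve(cf, rhs)
        Cinv = linalg.cho_solve(cf, np.eye(dim))
        out = {
            "b_m": sol[sl_bm],
            "s_m": sol[sl_sm],
            "b_v": sol[sl_bv],
            "s_v": sol[sl_sv],
            "pev_m": np.diag(Cinv)[sl_sm],
            "pev_v": np.diag(Cinv)[sl_sv],
            "pev_cross": Cinv[idx_sm, idx_sv],
            "h_m": _record_leverages(self._design, Cinv[sl_bm, sl_bm], Cinv[sl_bm, sl_sm], np.diag(Cinv)[sl_sm], w_m),
            "h_v": _record_leverages(self._design, Cinv[sl_bv, sl_bv], Cinv[sl_bv, sl_sv], np.diag(Cinv)[sl_sv], w_v),
        }
        return out

    def fit(
        self,
        mode: str = "rmv_free",
        tol: float = 1e-6,
        vc_tol: float = 1e-5,
        max_iter: int = 100,
        init: dict | None = None,
    ) -> DHGLMResults:
        """Iterate the DHGLM to joint convergence.

        Outer loop: joint solve of the stacked system given ``phi``; rebuild
        the working response ``psi`` and its weights from the new residuals
        and leverages; EM-REML update of the sire covariance matrix; update
        ``phi`` from the variance part's fitted values.  Convergence when
        ``max |delta log phi| < tol`` and the relative change of every
        variance component is below ``vc_tol``.

        With ``mode="rmv_zero"`` the sire covariance is pinned at zero so
        the two parts decouple exactly.
        """
        if mode not in ("rmv_free", "rmv_zero"):
            raise ValueError(f"unknown mode {mode!r}")
        d = self._design
        y = d.y
        init = dict(init or {})

        # --- initialisation: phi from fixed-effect-adjusted variance
        try:
            b_ols = linalg.lstsq(d.X, y)[0]
        except linalg.LinAlgError as exc:  # pragma: no cover
            raise ConfoundingError(str(exc)) from exc
        resid0 = y - d.X @ b_ols
        phi0 = float(init.get("phi0", resid0.var()))
        sigma2_s = float(init.get("sigma2_s", 0.05 * y.var()))
        phi = np.full(d.n, phi0)

        b, s, resid, h, _ = _solve_univariate(d, y, phi, sigma2_s)
        boot = MixedModelFit(
            b=pd.Series(b, index=d.x_names),
            s=pd.Series(s, index=d.sire_ids),
            residuals=resid,
            leverages=h,
            pev=pd.Series(np.zeros(d.q), index=d.sire_ids),
            sigma2_s=sigma2_s,
            resid_variances=phi,
        )
        psi, w_v = working_response(boot, phi)
        sigma2_sv = float(init.get("sigma2_sv", 0.05 * psi.var()))
        cov_s_sv = float(init.get("cov_s_sv", 0.0))
        if mode == "rmv_zero":
            cov_s_sv = 0.0
        G0 = _bend_psd(np.array([[sigma2_s, cov_s_sv], [cov_s_sv, sigma2_sv]]))

        converged = False
        delta_trace: list[float] = []
        n_iter = 0
        sol = None
        for n_iter in range(1, max_iter + 1):
            sol = self._solve_stacked(phi, psi, w_v, G0)
            resid = y - d.X @ sol["b_m"] - sol["s_m"][d.sire_idx]
            h = np.clip(sol["h_m"], 0.0, 1.0 - 1e-10)
            eta = np.clip(d.X @ sol["b_v"] + sol["s_v"][d.sire_idx], -_LOGVAR_CLIP, _LOGVAR_CLIP)
            phi_new = np.exp(eta)

            # EM-REML update of the 2x2 sire covariance
            S = np.column_stack([sol["s_m"], sol["s_v"]])
            pev_mat = np.array(
                [
                    [sol["pev_m"].sum(), sol["pev_cross"].sum()],
                    [sol["pev_cross"].sum(), sol["pev_v"].sum()],
                ]
            )
            G0_new = (S.T @ S + pev_mat) / d.q
            if mode == "rmv_zero":
                G0_new[0, 1] = G0_new[1, 0] = 0.0
            G0_new = _bend_psd(G0_new)

            delta_phi = float(np.max(np.abs(np.log(phi_new) - np.log(phi))))
            old_vc = np.array([G0[0, 0], G0[1, 1], G0[0, 1]])
            new_vc = np.array([G0_new[0, 0], G0_new[1, 1], G0_new[0, 1]])
            denom = np.maximum(np.abs(old_vc), 1e-12)
            delta_vc = float(np.max(np.abs(new_vc - old_vc) / denom))
            delta_trace.append(delta_phi)

            phi = phi_new
            G0 = G0_new
            psi = np.log(phi) + resid**2 / ((1.0 - h) * phi) - 1.0
            w_v = (1.0 - h) / 2.0
            if delta_phi < tol and delta_vc < vc_tol:
                converged = True
                break
        if not converged:
            logger.warning("DHGLM did not converge in %d iterations (last delta %.3g)", n_iter, delta_trace[-1])

        # final solve at the converged phi/psi so the reported solutions,
        # residuals and leverages are mutually consistent
        sol = self._solve_stacked(phi, psi, w_v, G0)
        resid = y - d.X @ sol["b_m"] - sol["s_m"][d.sire_idx]
        h = np.clip(sol["h_m"], 0.0, 1.0 - 1e-10)
        resid_v = psi - d.X @ sol["b_v"] - sol["s_v"][d.sire_idx]
        mean_part = MixedModelFit(
            b=pd.Series(sol["b_m"], index=d.x_names),
            s=pd.Series(sol["s_m"], index=d.sire_ids),
            residuals=resid,
            leverages=h,
            pev=pd.Series(sol["pev_m"], index=d.sire_ids),
            sigma2_s=float(G0[0, 0]),
            resid_variances=phi,
        )
        var_part = MixedModelFit(
            b=pd.Series(sol["b_v"], index=d.x_names),
            s=pd.Series(sol["s_v"], index=d.sire_ids),
            residuals=resid_v,
            leverages=np.clip(sol["h_v"], 0.0, 1.0 - 1e-10),
            pev=pd.Series(sol["pev_v"], index=d.sire_ids),
            sigma2_s=float(G0[1, 1]),
            resid_variances=2.0 / (1.0 - h),
        )
        return DHGLMResults(
            mean_part=mean_part,
            var_part=var_part,
            sigma2_s=float(G0[0, 0]),
            sigma2_sv=float(G0[1, 1]),
            cov_s_sv=float(G0[0, 1]),
            pev_cross=pd.Series(sol["pev_cross"], index=d.sire_ids),
            phi=phi,
            psi=psi,
            record_sire_ids=np.asarray(d.sire_ids, dtype=object)[d.sire_idx],
            n_progeny=pd.Series(d.n_progeny, index=d.sire_ids),
            mode=mode,
            converged=converged,
            n_iter=n_iter,
            delta_trace=delta_trace,
        )
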