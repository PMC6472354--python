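"""Per-gene effect estimation for cohort expression studies.

Two engines are provided:

* a generalized additive mixed model (GAMM) for longitudinal, child-level
  factors: ``y = b0 + b_f*x + s(age) + child intercept + noise`` with the
  smooth ``s`` a penalized cubic regression spline and the child intercept a
  Gaussian random effect, fitted by restricted maximum likelihood (REML)
  over the smoothing parameter and the two variance components;
* an ordinary age-adjusted linear model for cross-sectional group factors:
  ``y = b0 + b_f*x + b_age*age + noise``.

Both report the factor coefficient, its standard error, the Wald
t-statistic, a two-sided p-value, and (via :func:`bh_adjust`) a
Benjamini-Hochberg q-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "SplineSpec",
    "GammFit",
    "GeneFit",
    "build_spline_basis",
    "fit_gamm_gene",
    "fit_linear_gene",
    "linear_sweep",
    "fit_all_genes",
    "bh_adjust",
]


@dataclass(frozen=True)
class SplineSpec:
    """Cubic regression spline specification.

    ``k`` basis functions with knots at quantiles of the observed ages; the
    penalty is the integrated squared second derivative (order 2). Small k
    is appropriate for an age span of about one year with few samples per
    child.
    """

    basis: str = "cubic_regression"
    k: int = 5
    penalty_order: int = 2

    def __post_init__(self) -> None:
        if self.basis != "cubic_regression":
            raise ValueError(f"unsupported basis {self.basis!r}")
        if self.k < 3:
            raise ValueError("k must be >= 3")
        if self.penalty_order != 2:
            raise ValueError(
                "cubic regression splines support penalty_order=2 only"
            )


@dataclass
class GammFit:
    """Result of a single-gene GAMM fit."""

    gene_id: str
    beta0: float
    beta_cs: float
    se_cs: float
    t_cs: float
    p_cs: float
    spline_coefs: np.ndarray
    lam: float            # smoothing parameter sigma_eps^2 / sigma_spline^2
    sigma_id: float       # random-intercept sd
    sigma_eps: float      # residual sd
    edf: float            # effective degrees of freedom of the whole fit
    converged: bool
    residuals: np.ndarray | None = None


@dataclass
class GeneFit:
    """Per-gene factor effect: estimate, se, t, p and BH q."""

    gene_id: str
    estimate: float
    se: float
    t: float
    p: float
    q: float = np.nan


# ---------------------------------------------------------------------------
# cubic regression spline basis


def _pick_knots(ages: np.ndarray, k: int) -> np.ndarray:
    uniq = np.unique(ages)
    if uniq.size < k:
        raise ValueError(
            f"only {uniq.size} distinct ages for k={k} basis functions; "
            f"use a smaller k"
        )
    knots = np.quantile(uniq, np.linspace(0.0, 1.0, k))
    if np.any(np.diff(knots) <= 0):
        # quantiles collided; fall back to evenly spaced order statistics
        idx = np.linspace(0, uniq.size - 1, k).round().astype(int)
        knots = uniq[idx]
    return knots


def build_spline_basis(
    ages: Sequence[float] | np.ndarray, spec: SplineSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Natural cubic regression spline basis and its curvature penalty.

    Returns ``(X, S)`` where ``X`` is n x k (the j-th basis function is the
    cardinal natural cubic spline taking value 1 at knot j and 0 at the
    others) and ``S`` is the k x k positive semidefinite matrix such that
    ``c @ S @ c`` equals the integrated squared second derivative of the
    spline with knot values ``c``. The penalty nullspace is exactly the
    linear functions, so constants and straight lines are unpenalized and
    reproduced exactly.
    """
    ages = np.asarray(ages, dtype=float)
    knots = _pick_knots(ages, spec.k)
    k = spec.k
    h = np.diff(knots)

    # map knot values to second derivatives at the interior knots
    D = np.zeros((k - 2, k))
    B = np.zeros((k - 2, k - 2))
    for i in range(k - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < k - 2:
            B[i, i + 1] = B[i + 1, i] = h[i + 1] / 6.0
    Binv_D = np.linalg.solve(B, D)
    S = D.T @ Binv_D
    S = (S + S.T) / 2.0
    F_full = np.zeros((k, k))
    F_full[1:-1] = Binv_D  # natural: second derivative zero at the ends

    x = np.clip(ages, knots[0], knots[-1])
    j = np.clip(np.searchsorted(knots, x, side="right") - 1, 0, k - 2)
    hj = h[j]
    dl = x - knots[j]
    dr = knots[j + 1] - x
    a_minus = dr / hj
    a_plus = dl / hj
    c_minus = (dr ** 3 / hj - hj * dr) / 6.0
    c_plus = (dl ** 3 / hj - hj * dl) / 6.0

    n = ages.size
    X = np.zeros((n, k))
    X[np.arange(n), j] += a_minus
    X[np.arange(n), j + 1] += a_plus
    X += c_minus[:, None] * F_full[j] + c_plus[:, None] * F_full[j + 1]
    return X, S


# ---------------------------------------------------------------------------
# GAMM by REML


class GammDesign:
    """Shared design for a GAMM sweep: one study layout, many genes.

    Precomputes the fixed-effect matrix, the spline's penalized directions,
    the child-intercept indicators and all design cross-products, so a
    per-gene fit only touches gene-specific inner products. The penalized
    spline is reparameterized through the eigendecomposition of the penalty
    so both smooth and child blocks enter as i.i.d. variance components with
    ratio parameters gamma = sigma_component^2 / sigma_eps^2; REML maximizes
    over log gamma with the residual variance profiled out.
    """

    def __init__(
        self,
        ages: np.ndarray,
        child_ids: Sequence[str],
        x_factor: np.ndarray | None,
        spec: SplineSpec | None = None,
        fix_lambda: float | None = None,
        fix_sigma_id: float | None = None,
        reference: str = "t",
    ) -> None:
        spec = spec or SplineSpec()
        self.spec = spec
        self.reference = reference
        self.fix_sigma_id = fix_sigma_id
        ages = np.asarray(ages, dtype=float)
        n = ages.size
        if len(child_ids) != n:
            raise ValueError("ages and child_ids must be aligned")
        self.n = n
        self.has_factor = x_factor is not None
        self.flagged = False
        if self.has_factor:
            x_factor = np.asarray(x_factor, dtype=float)
            if x_factor.size != n:
                raise ValueError("x_factor must be aligned with ages")
            if np.all(x_factor == x_factor[0]):
                raise ValueError("factor is constant across samples")
            # a factor level carried by a single child cannot be separated
            # from that child's random intercept: flag, do not raise
            cf = pd.DataFrame({"c": list(child_ids), "x": x_factor})
            if fix_sigma_id != 0 and cf.groupby("x")["c"].nunique().min() < 2:
                self.flagged = True

        cols = [np.ones(n), ages - ages.mean()]
        if self.has_factor:
            cols.insert(1, x_factor)
        self.F = np.column_stack(cols)
        self.p = self.F.shape[1]

        Xs, S = build_spline_basis(ages, spec)
        evals, evecs = np.linalg.eigh(S)
        pos = evals > evals.max() * 1e-10
        Zu = Xs @ evecs[:, pos] / np.sqrt(evals[pos])

        child_ids = np.asarray(child_ids)
        uchild, child_idx = np.unique(child_ids, return_inverse=True)
        Zid = np.zeros((n, uchild.size))
        Zid[np.arange(n), child_idx] = 1.0

        # block bookkeeping: which variance ratios are free vs pinned
        blocks: list[np.ndarray] = []
        self.block_names: list[str] = []
        self.block_free: list[bool] = []
        self.block_fixed_loggamma: list[float] = []
        self.use_spline = not (fix_lambda is not None and np.isinf(fix_lambda))
        if self.use_spline:
            blocks.append(Zu)
            self.block_names.append("spline")
            if fix_lambda is None:
                self.block_free.append(True)
                self.block_fixed_loggamma.append(np.nan)
            else:
                self.block_free.append(False)
                self.block_fixed_loggamma.append(-np.log(fix_lambda))
        self.use_id = not (fix_sigma_id is not None and fix_sigma_id == 0)
        if self.use_id:
            blocks.append(Zid)
            self.block_names.append("child")
            if fix_sigma_id is None:
                self.block_free.append(True)
                self.block_fixed_loggamma.append(np.nan)
            else:
                # gamma for a pinned positive sigma_id depends on sigma_eps,
                # which is profiled out; treat it as free instead
                self.block_free.append(True)
                self.block_fixed_loggamma.append(np.nan)

        self.n_spline = Zu.shape[1] if self.use_spline else 0
        Z = np.hstack(blocks) if blocks else np.zeros((n, 0))
        self.Z = Z
        self.q = Z.shape[1]
        self.sizes = [b.shape[1] for b in blocks]
        # per-column block index, for vectorized gamma expansion
        self.col_block = np.repeat(np.arange(len(blocks)), self.sizes)
        self.ZtZ = Z.T @ Z
        self.ZtF = Z.T @ self.F
        self.FtF = self.F.T @ self.F
        self.n_free = sum(self.block_free)

        # cross-products for the fast block solver: the child block of Z'Z
        # is diagonal (disjoint indicator groups), so the restricted
        # likelihood needs only an s x s Schur complement per evaluation
        self.Zu = Zu if self.use_spline else np.zeros((n, 0))
        self.Zid = Zid if self.use_id else np.zeros((n, 0))
        self.UtU = self.Zu.T @ self.Zu
        self.UtI = self.Zu.T @ self.Zid
        self.counts = np.einsum("ij,ij->j", self.Zid, self.Zid)
        self.UtF = self.Zu.T @ self.F
        self.ItF = self.Zid.T @ self.F
        self.s = self.Zu.shape[1]
        self.c = self.Zid.shape[1]
        self.eye_s = np.eye(self.s)

    # -- restricted likelihood ------------------------------------------

    def _loggamma_blocks(self, theta_free: np.ndarray) -> np.ndarray:
        per_block = np.array(self.block_fixed_loggamma, dtype=float)
        per_block[np.asarray(self.block_free, dtype=bool)] = theta_free
        return np.clip(per_block, -30.0, 30.0)

    def _block_gammas(self, lg_blocks: np.ndarray) -> tuple[float, float]:
        gu = gi = 0.0
        for name, lg in zip(self.block_names, lg_blocks):
            if name == "spline":
                gu = float(np.exp(lg))
            else:
                gi = float(np.exp(lg))
        return gu, gi

    def _gene_crossprods(self, y: np.ndarray):
        """Per-gene stacked cross-products reused by every REML evaluation."""
        p = self.p
        Fty = self.F.T @ y
        T0 = np.empty((p + 1, p + 1))
        T0[:p, :p] = self.FtF
        T0[:p, p] = T0[p, :p] = Fty
        T0[p, p] = y @ y
        UtFy = np.column_stack([self.UtF, self.Zu.T @ y])
        ItFy = np.column_stack([self.ItF, self.Zid.T @ y])
        return T0, UtFy, ItFy

    def _pieces(self, gu: float, gi: float, T0, UtFy, ItFy):
        """([F y]'V^{-1}[F y], logdet_V) at variance ratios (gu, gi).

        Works on cross-products only. With R = Gamma^{1/2} Z'[F y] and
        A = I + Gamma^{1/2} Z'Z Gamma^{1/2}, the block [F y]'V^{-1}[F y]
        equals [F y]'[F y] - R'A^{-1}R; A is solved by eliminating the
        diagonal child block first, leaving an s x s Schur complement for
        the spline block.
        """
        have_u = self.s > 0 and gu > 0
        have_i = self.c > 0 and gi > 0
        logdet = 0.0
        T = T0
        if have_i:
            D = 1.0 + gi * self.counts
            logdet += float(np.log(D).sum())
            RiD = ItFy / D[:, None]
        if have_u:
            S3 = self.eye_s + gu * self.UtU
            rhs = UtFy
            if have_i:
                C = gi * (self.UtI / D)               # s x c
                S3 = S3 - gu * (C @ self.UtI.T)
                rhs = UtFy - C @ ItFy
            sign, ld3 = np.linalg.slogdet(S3)
            if sign <= 0:
                raise np.linalg.LinAlgError("indefinite Schur block")
            logdet += ld3
            Xu = np.linalg.solve(S3, rhs)
            T = T - gu * (rhs.T @ Xu)
            if have_i:
                T = T - gi * (ItFy.T @ RiD)
        elif have_i:
            T = T - gi * (ItFy.T @ RiD)
        return T, logdet

    def _neg2reml(self, theta_free, T0, UtFy, ItFy):
        lg = self._loggamma_blocks(np.asarray(theta_free, dtype=float))
        gu, gi = self._block_gammas(lg)
        try:
            T, logdet_v = self._pieces(gu, gi, T0, UtFy, ItFy)
        except np.linalg.LinAlgError:
            return np.inf
        p = self.p
        FVF = T[:p, :p]
        FVy = T[:p, p]
        yVy = T[p, p]
        sign, logdet_fvf = np.linalg.slogdet(FVF)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(FVF, FVy)
        quad = max(yVy - FVy @ beta, 1e-300)
        sigma2 = quad / (self.n - self.p)
        return (self.n - self.p) * np.log(sigma2) + logdet_v + logdet_fvf

    # -- per-gene fit ---------------------------------------------------

    def fit(self, y: np.ndarray, gene_id: str = "",
            keep_residuals: bool = False) -> GammFit:
        y = np.asarray(y, dtype=float)
        if y.size != self.n:
            raise ValueError("y is not aligned with the design")
        if np.ptp(y) < 1e-12:
            return GammFit(gene_id, float(y[0]), 0.0, np.nan, 0.0, 1.0,
                           np.zeros(self.n_spline), np.nan, 0.0, 0.0, 0.0,
                           converged=False,
                           residuals=np.zeros(self.n) if keep_residuals
                           else None)
        T0, UtFy, ItFy = self._gene_crossprods(y)
        Fty = T0[: self.p, self.p]
        Zty = np.concatenate([UtFy[:, self.p], ItFy[:, self.p]])

        converged = True
        if self.n_free:
            starts = [np.zeros(self.n_free),
                      np.array([4.0, -4.0][: self.n_free])]
            best = None
            for start in starts:
                res = optimize.minimize(
                    self._neg2reml, start, args=(T0, UtFy, ItFy),
                    method="Nelder-Mead",
                    options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 400})
                if best is None or res.fun < best.fun:
                    best = res
            converged = bool(best.success) and np.isfinite(best.fun)
            theta_free = np.asarray(best.x, dtype=float)
        else:
            theta_free = np.zeros(0)

        lg_blocks = self._loggamma_blocks(theta_free)
        gam_cols = np.exp(lg_blocks[self.col_block]) if self.q else np.zeros(0)

        # final penalized least-squares solve; Bayesian covariance
        p, q = self.p, self.q
        CtC = np.empty((p + q, p + q))
        CtC[:p, :p] = self.FtF
        CtC[:p, p:] = self.ZtF.T
        CtC[p:, :p] = self.ZtF
        CtC[p:, p:] = self.ZtZ
        rhs = np.concatenate([Fty, Zty])
        pen = np.concatenate([np.zeros(p), 1.0 / gam_cols])
        M = CtC + np.diag(pen)
        try:
            Minv = np.linalg.inv(M)
        except np.linalg.LinAlgError:
            Minv = np.linalg.pinv(M)
            converged = False
        coef = Minv @ rhs
        edf = float(np.einsum("ij,ji->", Minv, CtC))

        resid = y - self.F @ coef[:p] - (self.Z @ coef[p:] if q else 0.0)
        gu, gi = self._block_gammas(lg_blocks)
        T, _ = self._pieces(gu, gi, T0, UtFy, ItFy)
        FVF, FVy, yVy = T[:p, :p], T[:p, p], T[p, p]
        beta_gls = np.linalg.solve(FVF, FVy)
        sigma2 = max(yVy - FVy @ beta_gls, 1e-300) / (self.n - p)
        sigma_eps = float(np.sqrt(sigma2))

        beta0 = float(coef[0])
        if self.has_factor:
            beta_f = float(coef[1])
            se_f = float(np.sqrt(max(sigma2 * Minv[1, 1], 0.0)))
            t_f = beta_f / se_f if se_f > 0 else 0.0
            df = max(self.n - edf, 1.0)
            if self.reference == "normal":
                p_f = 2.0 * stats.norm.sf(abs(t_f))
            else:
                p_f = 2.0 * stats.t.sf(abs(t_f), df)
            p_f = float(min(max(p_f, np.finfo(float).tiny), 1.0))
        else:
            beta_f, se_f, t_f, p_f = 0.0, np.nan, 0.0, 1.0

        lam = np.inf
        sigma_id = 0.0
        off = 0
        for name, size in zip(self.block_names, self.sizes):
            g_here = gam_cols[off]
            if name == "spline":
                lam = float(1.0 / g_here) if g_here > 0 else np.inf
            elif name == "child":
                sigma_id = float(np.sqrt(sigma2 * g_here))
            off += size
        if self.fix_sigma_id is not None:
            sigma_id = float(self.fix_sigma_id)

        spl = coef[p:p + self.n_spline].copy()
        return GammFit(
            gene_id=gene_id, beta0=beta0, beta_cs=beta_f, se_cs=se_f,
            t_cs=t_f, p_cs=p_f, spline_coefs=spl, lam=lam,
            sigma_id=sigma_id, sigma_eps=sigma_eps, edf=edf,
            converged=converged and not self.flagged,
            residuals=resid if keep_residuals else None,
        )


def fit_gamm_gene(
    y: np.ndarray,
    ages: np.ndarray,
    child_ids: Sequence[str],
    x_factor: np.ndarray | None,
    spec: SplineSpec | None = None,
    gene_id: str = "",
    fix_lambda: float | None = None,
    fix_sigma_id: float | None = None,
    reference: str = "t",
    keep_residuals: bool = False,
) -> GammFit:
    """Fit the longitudinal GAMM for one gene.

    The penalized spline and the child intercept are treated as variance
    components; the restricted likelihood is maximized over their variance
    ratios with a two-start Nelder-Mead search. The factor test is a Wald t
    with df = n minus the total effective degrees of freedom
    (``reference="normal"`` switches to a normal reference).

    ``x_factor=None`` fits the reduced model without the factor term (used
    for residual-based local statistics). ``fix_lambda`` pins the smoothing
    parameter (``np.inf`` removes the penalized part entirely);
    ``fix_sigma_id=0`` removes the random intercept.
    """
    design = GammDesign(np.asarray(ages, dtype=float), child_ids, x_factor,
                        spec, fix_lambda, fix_sigma_id, reference)
    return design.fit(np.asarray(y, dtype=float), gene_id=gene_id,
                      keep_residuals=keep_residuals)


# ---------------------------------------------------------------------------
# linear engine


def linear_sweep(
    Y: np.ndarray, x_factor: np.ndarray, ages: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Age-adjusted OLS of every row of ``Y`` on a binary factor.

    Returns ``(estimate, se, t, p)`` arrays, one entry per row of ``Y``.
    The factor t uses a t(n-3) reference. Vectorized across genes: the
    design is shared, so a single pseudo-inverse serves all rows.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    x = np.asarray(x_factor, dtype=float)
    a = np.asarray(ages, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 samples")
    if np.all(x == x[0]):
        raise ValueError("factor is constant across samples")
    X = np.column_stack([np.ones(n), x, a])
    XtX = X.T @ X
    # perfect collinearity between age and factor leaves XtX singular
    if np.linalg.matrix_rank(XtX) < 3:
        raise ValueError(
            "age is perfectly collinear with the factor; the model "
            "cannot separate the two effects"
        )
    XtX_inv = np.linalg.inv(XtX)
    coefs = Y @ X @ XtX_inv                     # (G, 3)
    resid = Y - coefs @ X.T
    df = n - 3
    rss = np.einsum("ij,ij->i", resid, resid)
    sigma2 = rss / df
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 0.0))
    est = coefs[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, est / se, 0.0)
    p = np.clip(2.0 * stats.t.sf(np.abs(t), df), np.finfo(float).tiny, 1.0)
    return est, se, t, p


def fit_linear_gene(
    y: np.ndarray, x_factor: np.ndarray, age: np.ndarray, gene_id: str = ""
) -> GeneFit:
    """OLS of ``y = b0 + b_f*x + b_age*age + e`` for one gene."""
    est, se, t, p = linear_sweep(np.asarray(y)[None, :], x_factor, age)
    return GeneFit(gene_id, float(est[0]), float(se[0]), float(t[0]),
                   float(p[0]))


# ---------------------------------------------------------------------------
# whole-study sweeps and FDR


def bh_adjust(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Sort ascending, take ``q_(i) = min_{j>=i} m*p_(j)/j`` capped at 1, and
    return values in the original order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fit_all_genes(
    study,
    factor_name: str,
    model: str = "gamm",
    spec: SplineSpec | None = None,
    workers: int = 1,
    reference: str = "t",
) -> pd.DataFrame:
    """Apply the chosen engine to every gene of a study.

    Returns one row per gene in input gene order with columns ``gene_id,
    estimate, se, t, p, q`` (GAMM adds ``lambda, sigma_id, sigma_eps, edf,
    converged``). Samples missing the factor are dropped with a logged
    count; non-converged genes are flagged rows, never fatal. The result is
    independent of ``workers``.
    """
    if model not in ("gamm", "linear"):
        raise ValueError(f"unknown model {model!r}")
    study = study.drop_missing_factor(factor_name)
    x = study.factor_values(factor_name)
    ages = study.metadata["age_years"].to_numpy(dtype=float)

    if model == "linear":
        est, se, t, p = linear_sweep(study.values, x, ages)
        df = pd.DataFrame({
            "gene_id": study.gene_ids, "estimate": est, "se": se,
            "t": t, "p": p, "q": bh_adjust(p),
        })
        return df

    child = study.metadata["child_id"].to_numpy()
    design = GammDesign(ages, child, x, spec, reference=reference)

    def one(i: int) -> GammFit:
        return design.fit(study.values[i], gene_id=study.gene_ids[i])

    if workers > 1:
        from joblib import Parallel, delayed
        fits = Parallel(n_jobs=workers)(
            delayed(one)(i) for i in range(study.n_genes))
    else:
        fits = [one(i) for i in range(study.n_genes)]

    p = np.array([f.p_cs for f in fits])
    df = pd.DataFrame({
        "gene_id": study.gene_ids,
        "estimate": [f.beta_cs for f in fits],
        "se": [f.se_cs for f in fits],
        "t": [f.t_cs for f in fits],
        "p": p,
        "q": bh_adjust(p),
        "lambda": [f.lam for f in fits],
        "sigma_id": [f.sigma_id for f in fits],
        "sigma_eps": [f.sigma_eps for f in fits],
        "edf": [f.edf for f in fits],
        "converged": [f.converged for f in fits],
    })
    n_bad = int((~df["converged"]).sum())
    if n_bad:
        logger.warning("%d/%d genes flagged non-converged", n_bad, len(df))
    return df
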