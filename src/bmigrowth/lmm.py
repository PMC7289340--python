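"""Linear mixed models by profiled (restricted) maximum likelihood.

The model for child i with n_i BMI observations is

    y_i = X_i beta + Z_i b_i + e_i,   b_i ~ N(0, sigma^2 Psi),   e_i ~ N(0, sigma^2 I)

with an unstructured scaled covariance Psi parameterised through its
Cholesky factor Lambda (Psi = Lambda Lambda'), so Psi stays positive
semi-definite for every parameter value and boundary (singular) fits are
well defined. For fixed Lambda, beta and sigma^2 have closed-form profiled
estimates, leaving a low-dimensional smooth optimisation over Lambda.

All likelihood evaluations run on per-child sufficient statistics
(Z_i'Z_i, Z_i'X_i, Z_i'y_i, X_i'X_i, X_i'y_i, y_i'y_i), batched across
children. Because these statistics are cached per child, refitting the same
model on a cluster-bootstrap resample is a cheap re-indexing plus sums --
the property the bootstrap module relies on.

Likelihood inference here is valid when dropout depends only on observed
covariates (missing at random).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .design import DesignMatrices, ModelSpec

__all__ = ["FittedModel", "GroupStats", "fit_lmm", "fit_design", "fit_from_stats"]

logger = logging.getLogger(__name__)

LOG2PI = np.log(2.0 * np.pi)
#: relative deviance convergence tolerance and iteration cap
FTOL = 1e-8
XTOL = 2e-3
MAX_ITER = 500


class LmmError(RuntimeError):
    pass


@dataclass
class GroupStats:
    """Per-child sufficient statistics for the profiled likelihood."""

    CC: np.ndarray | None  # (G, q, q) Z_i' Z_i
    CU: np.ndarray | None  # (G, q, p) Z_i' X_i
    cv: np.ndarray | None  # (G, q)    Z_i' y_i
    XX: np.ndarray  # (G, p, p)
    Xy: np.ndarray  # (G, p)
    yy: np.ndarray  # (G,)
    ni: np.ndarray  # (G,)
    columns: list[str]
    re_names: list[str]
    group_labels: np.ndarray | None = None
    #: RMS scale of each random-effect column; Z is standardised internally
    #: so the variance parameters are comparably scaled for the optimiser
    z_scale: np.ndarray | None = None

    @property
    def n_groups(self) -> int:
        return len(self.ni)

    @property
    def q(self) -> int:
        return 0 if self.CC is None else self.CC.shape[1]

    @property
    def p(self) -> int:
        return self.XX.shape[1]

    def select(self, idx: np.ndarray) -> "GroupStats":
        """Statistics for a resample of children (with multiplicity).

        Each selected index becomes its own cluster, which is exactly the
        cluster-bootstrap convention: a child drawn twice contributes two
        independent random effects.
        """
        idx = np.asarray(idx)
        return GroupStats(
            CC=None if self.CC is None else self.CC[idx],
            CU=None if self.CU is None else self.CU[idx],
            cv=None if self.cv is None else self.cv[idx],
            XX=self.XX[idx],
            Xy=self.Xy[idx],
            yy=self.yy[idx],
            ni=self.ni[idx],
            columns=self.columns,
            re_names=self.re_names,
            group_labels=None
            if self.group_labels is None
            else self.group_labels[idx],
            z_scale=self.z_scale,
        )

    @classmethod
    def from_arrays(
        cls,
        X: np.ndarray,
        Z: np.ndarray | None,
        y: np.ndarray,
        groups: np.ndarray,
        columns=None,
        re_names=None,
    ) -> "GroupStats":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be (n, p) with y of length n")
        if np.isnan(X).any() or np.isnan(y).any():
            raise ValueError("missing cells in the design or outcome are not allowed")
        codes, labels = pd.factorize(np.asarray(groups), sort=True)
        order = np.argsort(codes, kind="stable")
        Xs, ys, cs = X[order], y[order], codes[order]
        starts = np.flatnonzero(np.r_[True, np.diff(cs) != 0])
        bounds = np.r_[starts, len(cs)]
        G, p = len(starts), X.shape[1]
        q = 0 if Z is None else Z.shape[1]
        z_scale = None
        Zs = None
        if Z is not None:
            Zs = np.asarray(Z, dtype=float)[order]
            z_scale = np.sqrt(np.mean(Zs**2, axis=0))
            z_scale[z_scale == 0] = 1.0
            Zs = Zs / z_scale
        CC = np.zeros((G, q, q)) if q else None
        CU = np.zeros((G, q, p)) if q else None
        cv = np.zeros((G, q)) if q else None
        XX = np.zeros((G, p, p))
        Xy = np.zeros((G, p))
        yy = np.zeros(G)
        ni = np.diff(bounds).astype(float)
        for g in range(G):
            sl = slice(bounds[g], bounds[g + 1])
            Xg, yg = Xs[sl], ys[sl]
            XX[g] = Xg.T @ Xg
            Xy[g] = Xg.T @ yg
            yy[g] = yg @ yg
            if q:
                Zg = Zs[sl]
                CC[g] = Zg.T @ Zg
                CU[g] = Zg.T @ Xg
                cv[g] = Zg.T @ yg
        if columns is None:
            columns = [f"x{j}" for j in range(p)]
        if re_names is None:
            re_names = [f"z{j}" for j in range(q)]
        return cls(
            CC, CU, cv, XX, Xy, yy, ni, list(columns), list(re_names),
            labels.to_numpy() if hasattr(labels, "to_numpy") else np.asarray(labels),
            z_scale,
        )


@dataclass
class FittedModel:
    """Fixed effects with covariance, variance components and fit metadata."""

    coef: pd.Series
    vcov: pd.DataFrame
    re_cov: np.ndarray  # sigma^2 * Psi on the outcome scale
    re_names: list[str]
    sigma2: float
    loglik: float
    method: str
    converged: bool
    n_children: int
    n_obs: int
    spec: ModelSpec | None = None
    message: str = ""
    #: internal variance parameters (Cholesky of Psi on the standardised Z
    #: scale); useful as a warm start when refitting resampled data
    theta: np.ndarray | None = None

    @property
    def columns(self) -> list[str]:
        return list(self.coef.index)

    def predict_fixed(self, rows: np.ndarray) -> np.ndarray:
        return np.asarray(rows) @ self.coef.to_numpy()


# ----------------------------------------------------------------------
# profiled deviance


def _unpack(theta: np.ndarray, q: int) -> np.ndarray:
    lam = np.zeros((q, q))
    lam[np.tril_indices(q)] = theta
    return lam


def _profiled_quantities(theta: np.ndarray, s: GroupStats, sums) -> dict:
    Sxx, Sxy, Syy, n = sums
    q, p = s.q, s.p
    if q == 0:
        XtVX, XtVy, ytVy, logdet = Sxx, Sxy, Syy, 0.0
    elif q == 1:
        # scalar Woodbury path: everything elementwise across children
        lam2 = float(theta[0]) ** 2
        M = 1.0 + lam2 * s.CC[:, 0, 0]
        logdet = float(np.log(M).sum())
        T = s.CU[:, 0, :]  # (G, p) Z_i' X_i
        w = s.cv[:, 0]
        r = lam2 / M
        XtVX = Sxx - np.einsum("gp,gq->pq", T * r[:, None], T, optimize=True)
        XtVy = Sxy - T.T @ (r * w)
        ytVy = Syy - float((r * w * w).sum())
    else:
        lam = _unpack(theta, q)
        A = np.einsum("ba,gbc,cd->gad", lam, s.CC, lam, optimize=True)
        M = A + np.eye(q)
        L = np.linalg.cholesky(M)
        logdet = 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum()
        T = np.einsum("ba,gbp->gap", lam, s.CU)
        w = np.einsum("ba,gb->ga", lam, s.cv)
        S = np.linalg.solve(M, T)
        u = np.linalg.solve(M, w[..., None])[..., 0]
        XtVX = Sxx - np.einsum("gap,gaq->pq", T, S, optimize=True)
        XtVy = Sxy - np.einsum("gap,ga->p", T, u)
        ytVy = Syy - np.einsum("ga,ga->", w, u)
    try:
        c, low = _chol(XtVX)
        from scipy.linalg import cho_solve

        beta = cho_solve((c, low), XtVy)
        logdet_xvx = 2.0 * np.log(np.diag(c)).sum()
    except np.linalg.LinAlgError:
        beta, *_ = np.linalg.lstsq(XtVX, XtVy, rcond=None)
        sign, logdet_xvx = np.linalg.slogdet(XtVX)
    rss = max(ytVy - XtVy @ beta, 1e-12)
    return dict(
        beta=beta, rss=rss, logdet=logdet, logdet_xvx=logdet_xvx, XtVX=XtVX, n=n, p=p
    )


def _chol(a):
    from scipy.linalg import cho_factor

    return cho_factor(a, lower=True)


def _deviance(theta, s: GroupStats, sums, reml: bool) -> float:
    qty = _profiled_quantities(theta, s, sums)
    n, p = qty["n"], qty["p"]
    if reml:
        df = n - p
        return df * (LOG2PI + np.log(qty["rss"] / df) + 1.0) + qty["logdet"] + qty["logdet_xvx"]
    return n * (LOG2PI + np.log(qty["rss"] / n) + 1.0) + qty["logdet"]


def _deviance_and_grad(theta, s: GroupStats, sums, reml: bool):
    """Profiled deviance and its exact gradient in the Cholesky parameters.

    Uses the envelope theorem for the profiled beta and sigma^2, so only
    the explicit Lambda-dependence of log|V|, the residual quadratic form
    and (for REML) log|X'V^-1 X| contributes.
    """
    Sxx, Sxy, Syy, n = sums
    q, p = s.q, s.p
    lam = _unpack(theta, q)
    Itri = np.tril_indices(q)
    A = np.einsum("ba,gbc,cd->gad", lam, s.CC, lam, optimize=True)
    M = A + np.eye(q)
    Lc = np.linalg.cholesky(M)
    logdet = 2.0 * np.log(np.diagonal(Lc, axis1=1, axis2=2)).sum()
    T = np.einsum("ba,gbp->gap", lam, s.CU)  # Lambda' U_i
    w = np.einsum("ba,gb->ga", lam, s.cv)  # Lambda' v_i
    Minv = np.linalg.solve(M, np.broadcast_to(np.eye(q), M.shape).copy())
    S = Minv @ T  # M^-1 Lambda' U_i
    u = (Minv @ w[..., None])[..., 0]
    XtVX = Sxx - np.einsum("gap,gaq->pq", T, S, optimize=True)
    XtVy = Sxy - np.einsum("gap,ga->p", T, u)
    ytVy = Syy - np.einsum("ga,ga->", w, u)
    from scipy.linalg import cho_factor, cho_solve

    try:
        cf = cho_factor(XtVX, lower=True)
        beta = cho_solve(cf, XtVy)
        logdet_xvx = 2.0 * np.log(np.diag(cf[0])).sum()
        Finv = cho_solve(cf, np.eye(p))
    except np.linalg.LinAlgError:
        Finv = np.linalg.pinv(XtVX)
        beta = Finv @ XtVy
        _, logdet_xvx = np.linalg.slogdet(XtVX)
    rss = max(ytVy - XtVy @ beta, 1e-12)

    CLam = np.einsum("gab,bc->gac", s.CC, lam, optimize=True)  # C_i Lambda
    # d(sum log|M_i|)/dLambda = 2 sum C_i Lambda M_i^-1
    G_logdet = 2.0 * np.einsum("gab,gbc->ac", CLam, Minv, optimize=True)
    # residual pieces: a_i = v_i - U_i beta, h_i = M^-1 Lambda' a_i
    a = s.cv - np.einsum("gqp,p->gq", s.CU, beta)
    h = u - np.einsum("gqp,p->gq", S, beta)
    G_rss = -2.0 * (
        np.einsum("ga,gb->ab", a, h)
        - np.einsum("gab,gb,gc->ac", CLam, h, h, optimize=True)
    )
    if reml:
        df = n - p
        dev = df * (LOG2PI + np.log(rss / df) + 1.0) + logdet + logdet_xvx
        FT = np.einsum("pr,gqr->gqp", Finv, S, optimize=True)  # (F^-1 S_i')' as (g,q,p)
        G_f = -2.0 * (
            np.einsum("gap,gbp->ab", s.CU, FT, optimize=True)
            - np.einsum("gab,gbp,gcp->ac", CLam, S, FT, optimize=True)
        )
        grad_mat = G_logdet + (df / rss) * G_rss + G_f
    else:
        dev = n * (LOG2PI + np.log(rss / n) + 1.0) + logdet
        grad_mat = G_logdet + (n / rss) * G_rss
    return dev, grad_mat[Itri]


def fit_from_stats(
    stats: GroupStats,
    estimation: str = "reml",
    spec: ModelSpec | None = None,
    theta0: np.ndarray | None = None,
) -> FittedModel:
    """Fit the mixed model from cached per-child statistics."""
    if estimation not in ("ml", "reml"):
        raise ValueError("estimation must be 'ml' or 'reml'")
    reml = estimation == "reml"
    if stats.n_groups < 2:
        raise LmmError("at least two children are required to fit the model")
    Sxx = stats.XX.sum(axis=0)
    Sxy = stats.Xy.sum(axis=0)
    Syy = stats.yy.sum()
    n = stats.ni.sum()
    sums = (Sxx, Sxy, Syy, n)
    q = stats.q

    converged, message = True, ""
    if q == 0:
        theta = np.zeros(0)
    else:
        tril = list(zip(*np.tril_indices(q)))
        n_par = len(tril)
        if theta0 is None:
            theta0 = np.array([0.7 if i == j else 0.0 for i, j in tril])
        bounds = [(0.0, 1e3) if i == j else (-1e3, 1e3) for i, j in tril]

        def obj(t):
            return _deviance(t, stats, sums, reml)

        if q == 1:
            res = optimize.minimize_scalar(
                lambda t: obj(np.array([t])),
                bounds=(0.0, 1e3),
                method="bounded",
                options={"xatol": 1e-6, "maxiter": MAX_ITER},
            )
            theta = np.array([res.x])
            converged, message = bool(res.success), str(res.message)
        else:
            # quasi-Newton with the exact profiled-deviance gradient; if the
            # line search stalls, fall back to derivative-free Powell
            res = optimize.minimize(
                lambda t: _deviance_and_grad(t, stats, sums, reml),
                theta0,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": MAX_ITER, "ftol": 1e-11, "gtol": 1e-5},
            )
            theta, converged, message = res.x, bool(res.success), str(res.message)
            if not converged:
                res = optimize.minimize(
                    obj,
                    res.x,
                    method="Powell",
                    bounds=bounds,
                    options={"maxiter": MAX_ITER, "ftol": FTOL, "xtol": XTOL},
                )
                if res.fun <= _deviance(theta, stats, sums, reml):
                    theta = res.x
                converged, message = bool(res.success), str(res.message)
        if not converged and q > 1:
            # diagonal-covariance fallback for ill-conditioned fits
            diag_idx = [k for k, (i, j) in enumerate(tril) if i == j]
            mask = np.zeros(n_par, dtype=bool)
            mask[diag_idx] = True

            def obj_diag(td):
                t = np.zeros(n_par)
                t[mask] = td
                return obj(t)

            res2 = optimize.minimize(
                obj_diag,
                np.full(len(diag_idx), 0.7),
                method="Powell",
                bounds=[(0.0, 1e3)] * len(diag_idx),
                options={"maxiter": MAX_ITER, "ftol": FTOL, "xtol": XTOL},
            )
            if res2.success:
                theta = np.zeros(n_par)
                theta[mask] = res2.x
                converged = True
                message = "diagonal random-effect covariance fallback"
                logger.warning("LMM refit with diagonal random-effect covariance")
            else:
                message = f"non-convergence: {res.message}"
                logger.warning("LMM did not converge: %s", res.message)

    qty = _profiled_quantities(theta, stats, sums)
    df = qty["n"] - qty["p"] if reml else qty["n"]
    sigma2 = qty["rss"] / df
    dev = _deviance(theta, stats, sums, reml)
    try:
        c, low = _chol(qty["XtVX"])
        from scipy.linalg import cho_solve

        vcov = sigma2 * cho_solve((c, low), np.eye(stats.p))
    except np.linalg.LinAlgError:
        vcov = sigma2 * np.linalg.pinv(qty["XtVX"])
    vcov = 0.5 * (vcov + vcov.T)
    lam = _unpack(theta, q) if q else np.zeros((0, 0))
    re_cov = sigma2 * lam @ lam.T
    if q and stats.z_scale is not None:
        re_cov = re_cov / np.outer(stats.z_scale, stats.z_scale)
    return FittedModel(
        coef=pd.Series(qty["beta"], index=stats.columns),
        vcov=pd.DataFrame(vcov, index=stats.columns, columns=stats.columns),
        re_cov=re_cov,
        re_names=stats.re_names,
        sigma2=float(sigma2),
        loglik=float(-0.5 * dev),
        method=estimation,
        converged=converged,
        n_children=int(stats.n_groups),
        n_obs=int(n),
        spec=spec,
        message=message,
        theta=np.asarray(theta, dtype=float),
    )


def fit_lmm(
    X: np.ndarray,
    Z: np.ndarray | None,
    y: np.ndarray,
    groups: np.ndarray,
    estimation: str = "reml",
    columns=None,
    re_names=None,
) -> FittedModel:
    """Fit from raw arrays. ``Z=None`` (or zero columns) degenerates to OLS/GLS."""
    if Z is not None and Z.size == 0:
        Z = None
    stats = GroupStats.from_arrays(X, Z, y, groups, columns=columns, re_names=re_names)
    return fit_from_stats(stats, estimation=estimation)


def fit_design(design: DesignMatrices, estimation: str | None = None) -> FittedModel:
    """Fit a :class:`~bmigrowth.design.DesignMatrices` bundle."""
    spec = design.spec
    est = estimation or (spec.estimation if spec else "reml")
    stats = GroupStats.from_arrays(
        design.X,
        design.Z,
        design.y,
        design.group_labels,
        columns=design.columns,
        re_names=design.re_names,
    )
    return fit_from_stats(stats, estimation=est, spec=spec)
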