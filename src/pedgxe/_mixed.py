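"""Dense-REML machinery for small linear mixed models.

Internal support for the stage-one trial models.  The marginal model is

    y = X b + sum_k Z_k u_k + e,   u_k ~ N(0, s2_k I),   e ~ N(0, R)

with R diagonal, either homoscedastic or with one residual variance per
record group (the heteroscedastic combined-trial model).  Variance
components are estimated by maximising the REML log-likelihood profiled
over the fixed effects, optimising over log-variances with L-BFGS-B.
Problem sizes are a few hundred records, so V is handled densely via
Cholesky factorisations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

_LOG_FLOOR = np.log(1e-10)
_LOG_CEIL = np.log(1e4)


class MixedModelError(RuntimeError):
    """REML failure; carries the last parameter vector when available."""

    def __init__(self, message: str, last_params: np.ndarray | None = None):
        super().__init__(message)
        self.last_params = last_params


@dataclass
class RemlFit:
    """REML solution of one mixed model."""

    beta: np.ndarray
    cov_beta: np.ndarray
    varcomps: dict[str, float]
    resid_vars: np.ndarray          # per residual group
    loglik: float
    n: int
    p: int
    # pieces reused for BLUPs / residual diagnostics
    Vinv: np.ndarray = field(repr=False, default=None)
    P: np.ndarray = field(repr=False, default=None)
    X: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)
    Z: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    resid_groups: np.ndarray = field(repr=False, default=None)

    @property
    def fitted_fixed(self) -> np.ndarray:
        return self.X @ self.beta

    def blup(self, term: str) -> np.ndarray:
        """BLUP of the random effects of ``term``: s2 Z' P y."""
        return self.varcomps[term] * self.Z[term].T @ (self.P @ self.y)

    def blup_pev(self, term: str) -> np.ndarray:
        """Prediction-error variance matrix var(u_hat - u) for ``term``."""
        s2 = self.varcomps[term]
        Z = self.Z[term]
        return s2 * np.eye(Z.shape[1]) - s2 * s2 * (Z.T @ self.P @ Z)


def _build_V(
    theta: np.ndarray,
    ZZt: list[np.ndarray],
    resid_groups: np.ndarray,
    n_groups: int,
) -> tuple[np.ndarray, np.ndarray]:
    k = len(ZZt)
    V = np.zeros((len(resid_groups), len(resid_groups)))
    for s2, M in zip(np.exp(theta[:k]), ZZt):
        V += s2 * M
    resid = np.exp(theta[k:])
    V[np.diag_indices_from(V)] += resid[resid_groups]
    return V, resid


def _neg_reml(
    theta: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    ZZt: list[np.ndarray],
    resid_groups: np.ndarray,
    n_groups: int,
) -> float:
    V, _ = _build_V(theta, ZZt, resid_groups, n_groups)
    try:
        cV = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return 1e12
    logdet_V = 2.0 * np.sum(np.log(np.diag(cV[0])))
    Vinv_X = linalg.cho_solve(cV, X, check_finite=False)
    Vinv_y = linalg.cho_solve(cV, y, check_finite=False)
    XtVinvX = X.T @ Vinv_X
    try:
        cX = linalg.cho_factor(XtVinvX, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return 1e12
    logdet_X = 2.0 * np.sum(np.log(np.diag(cX[0])))
    beta = linalg.cho_solve(cX, X.T @ Vinv_y, check_finite=False)
    resid = y - X @ beta
    quad = float(resid @ linalg.cho_solve(cV, resid, check_finite=False))
    return 0.5 * (logdet_V + logdet_X + quad)


def reml(
    y: np.ndarray,
    X: np.ndarray,
    random_terms: dict[str, np.ndarray],
    resid_groups: np.ndarray | None = None,
    max_iter: int = 200,
    n_starts: int = 2,
) -> RemlFit:
    """Fit the mixed model by REML.

    Parameters
    ----------
    y, X
        Response and full-column-rank fixed-effect design.
    random_terms
        name -> Z design matrix; each term has an iid variance component.
    resid_groups
        Integer group per record for group-specific residual variances
        (``None`` = single residual variance).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n != len(y):
        raise ValueError("X and y disagree on record count")
    if np.linalg.matrix_rank(X) < p:
        raise MixedModelError("fixed-effect design is rank deficient")
    if resid_groups is None:
        resid_groups = np.zeros(n, dtype=int)
    resid_groups = np.asarray(resid_groups, dtype=int)
    n_groups = int(resid_groups.max()) + 1

    names = list(random_terms)
    ZZt = [random_terms[t] @ random_terms[t].T for t in names]
    k = len(names)
    vy = max(float(np.var(y)), 1e-12)

    lo = np.log(vy) + _LOG_FLOOR
    hi = np.log(vy) + _LOG_CEIL
    bounds = [(lo, hi)] * (k + n_groups)

    args = (y, X, ZZt, resid_groups, n_groups)
    best = None
    starts = []
    # equal split between all components, then a residual-dominated start
    starts.append(np.log(np.full(k + n_groups, vy / (k + 1))))
    if n_starts > 1:
        s = np.full(k + n_groups, vy * 0.05)
        s[k:] = vy * 0.9
        starts.append(np.log(s))
    last = None
    for x0 in starts[:n_starts]:
        res = optimize.minimize(
            _neg_reml,
            np.clip(x0, lo, hi),
            args=args,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-9},
        )
        last = res.x
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise MixedModelError("REML optimisation failed", last)
    if best.fun >= 1e12:
        raise MixedModelError(
            "REML likelihood not computable at optimum", best.x
        )

    theta = best.x
    V, resid = _build_V(theta, ZZt, resid_groups, n_groups)
    cV = linalg.cho_factor(V, lower=True, check_finite=False)
    Vinv = linalg.cho_solve(cV, np.eye(n), check_finite=False)
    XtVinvX = X.T @ Vinv @ X
    cov_beta = np.linalg.inv(XtVinvX)
    beta = cov_beta @ (X.T @ (Vinv @ y))
    P = Vinv - Vinv @ X @ cov_beta @ X.T @ Vinv

    varcomps = {t: float(np.exp(theta[i])) for i, t in enumerate(names)}
    return RemlFit(
        beta=beta,
        cov_beta=cov_beta,
        varcomps=varcomps,
        resid_vars=resid,
        loglik=-float(best.fun),
        n=n,
        p=p,
        Vinv=Vinv,
        P=P,
        X=X,
        y=y,
        Z={t: random_terms[t] for t in names},
        resid_groups=resid_groups,
    )


def studentized_residuals(fit: RemlFit) -> tuple[np.ndarray, int]:
    """Externally studentized residuals of the whitened model.

    The model is whitened with the Cholesky factor of the fitted V, after
    which ordinary leave-one-out studentisation applies.  Returns the
    residual vector and the t reference degrees of freedom ``n - p - 1``.
    """
    L = np.linalg.cholesky(
        _as_V(fit)
    )
    yt = linalg.solve_triangular(L, fit.y, lower=True)
    Xt = linalg.solve_triangular(L, fit.X, lower=True)
    Q, _ = np.linalg.qr(Xt)
    h = np.sum(Q * Q, axis=1)
    e = yt - Q @ (Q.T @ yt)
    n, p = fit.n, fit.p
    df = n - p
    s2 = float(e @ e) / df
    h = np.clip(h, 0.0, 1.0 - 1e-12)
    r = e / np.sqrt(s2 * (1.0 - h))
    # external (leave-one-out) conversion
    r2 = np.clip(r * r, 0.0, df - 1e-9)
    t = r * np.sqrt((df - 1.0) / (df - r2))
    return t, df - 1


def _as_V(fit: RemlFit) -> np.ndarray:
    V = np.zeros((fit.n, fit.n))
    for name, Z in fit.Z.items():
        V += fit.varcomps[name] * (Z @ Z.T)
    V[np.diag_indices_from(V)] += fit.resid_vars[fit.resid_groups]
    return V
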