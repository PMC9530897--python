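"""Independent oracle implementations used only by the tests.

Each oracle is a deliberately naive, brute-force counterpart of a package
operation: gene-dropping Monte Carlo for the tabular A-matrix, zooming grid
search for REML, direct mixed-model-equation BLUP at fixed variances, and a
full-covariance Gibbs sampler.  They share no code with the implementations
they check.
"""

from __future__ import annotations

import numpy as np

from pedgxe.pedigree import UNKNOWN, Genealogy


# ---------------------------------------------------------------------------
# gene dropping


def gene_drop_A(g: Genealogy, n_reps: int, rng: np.random.Generator):
    """Monte-Carlo expected additive relationship (2 x kinship) by dropping
    founder alleles through the pedigree.

    Returns (A_hat, SE) over the genealogy's ordered ids.
    """
    ids = g.ordered_ids
    n = len(ids)
    index = {i: k for k, i in enumerate(ids)}
    alleles = np.empty((n, 2, n_reps), dtype=np.int32)
    next_label = 0
    for k, line_id in enumerate(ids):
        p1, p2 = g.parents[line_id]
        for slot, parent in enumerate((p1, p2)):
            if parent == UNKNOWN or parent not in index:
                alleles[k, slot, :] = next_label
                next_label += 1
            else:
                pk = index[parent]
                pick = rng.integers(0, 2, n_reps)
                alleles[k, slot, :] = alleles[pk, pick, np.arange(n_reps)]

    A_hat = np.empty((n, n))
    SE = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            # per-rep kinship: average IBD over the four allele pairings
            k_r = np.zeros(n_reps)
            for a in range(2):
                for b in range(2):
                    k_r += alleles[i, a] == alleles[j, b]
            k_r /= 4.0
            A_hat[i, j] = A_hat[j, i] = 2.0 * k_r.mean()
            SE[i, j] = SE[j, i] = 2.0 * k_r.std(ddof=1) / np.sqrt(n_reps)
    return A_hat, SE


# ---------------------------------------------------------------------------
# REML grid search


def reml_neg_loglik(theta, y, X, ZZt, resid_groups=None):
    """Profiled (over fixed effects) negative REML log-likelihood at
    log-variances ``theta`` = (components..., residual groups...)."""
    n = len(y)
    if resid_groups is None:
        resid_groups = np.zeros(n, dtype=int)
    k = len(ZZt)
    V = np.zeros((n, n))
    for s2, M in zip(np.exp(theta[:k]), ZZt):
        V += s2 * M
    resid = np.exp(theta[k:])
    V[np.diag_indices_from(V)] += resid[resid_groups]
    sign, logdet_V = np.linalg.slogdet(V)
    if sign <= 0:
        return np.inf
    Vinv = np.linalg.inv(V)
    XtVX = X.T @ Vinv @ X
    sign2, logdet_X = np.linalg.slogdet(XtVX)
    if sign2 <= 0:
        return np.inf
    beta = np.linalg.solve(XtVX, X.T @ Vinv @ y)
    r = y - X @ beta
    return 0.5 * (logdet_V + logdet_X + float(r @ Vinv @ r))


def grid_reml(y, X, ZZt, lo=-12.0, hi=6.0, pts=13, levels=6):
    """Zooming grid search over log-variances (components + one residual)."""
    n_par = len(ZZt) + 1
    center = np.full(n_par, (lo + hi) / 2.0)
    width = (hi - lo) / 2.0
    best_theta, best_val = None, np.inf
    for _ in range(levels):
        axes = [np.linspace(c - width, c + width, pts) for c in center]
        mesh = np.meshgrid(*axes, indexing="ij")
        thetas = np.stack([m.ravel() for m in mesh], axis=1)
        vals = np.array([reml_neg_loglik(t, y, X, ZZt) for t in thetas])
        i = int(np.argmin(vals))
        best_theta, best_val = thetas[i], float(vals[i])
        center = thetas[i]
        width = 2.0 * width / (pts - 1)   # keep one old grid step each side
    return np.exp(best_theta), best_val


# ---------------------------------------------------------------------------
# mixed-model-equation BLUP at fixed variances


def mme_predictions(kernels, variances, resid_var, y, mask):
    """GLS intercept + conditional-expectation prediction at fixed variance
    components, by direct matrix inversion over the observed records."""
    n = len(y)
    G = np.zeros((n, n))
    for comp in kernels.components:
        G += variances[comp.name] * comp.kernel
    V = G + resid_var * np.eye(n)
    obs = ~mask
    Voo = V[np.ix_(obs, obs)]
    Voo_inv = np.linalg.inv(Voo)
    ones = np.ones(int(obs.sum()))
    mu = float(ones @ Voo_inv @ y[obs]) / float(ones @ Voo_inv @ ones)
    preds = np.empty(n)
    adj = Voo_inv @ (y[obs] - mu)
    preds[obs] = mu + G[np.ix_(obs, obs)] @ adj
    preds[mask] = mu + G[np.ix_(mask, obs)] @ adj
    return preds


# ---------------------------------------------------------------------------
# naive full-covariance Gibbs sampler


def naive_gibbs(
    y,
    kernels,
    iterations,
    burn_in,
    seed,
    prior_df=5.0,
    prior_share=0.5,
    mask=None,
):
    """Gibbs sampler working directly with n x n covariance conditionals
    (no eigenbasis).  Same model and priors as the package sampler."""
    rng = np.random.default_rng(seed)
    n = len(y)
    if mask is None:
        mask = np.zeros(n, dtype=bool)
    comps = kernels.components
    K = len(comps)
    Ks = [c.kernel + 1e-8 * np.eye(n) for c in comps]
    Kinv = [np.linalg.inv(Kk) for Kk in Ks]

    vy = float(np.var(y[~mask]))
    nu0 = prior_df
    tau2_c = (prior_share * vy / K) * (nu0 + 2.0) / nu0
    tau2_e = ((1 - prior_share) * vy) * (nu0 + 2.0) / nu0

    s2 = np.full(K, prior_share * vy / K)
    s2_e = (1 - prior_share) * vy
    u = [np.zeros(n) for _ in range(K)]
    mu = float(np.mean(y[~mask]))
    yw = y.copy()

    keep_lp = np.zeros(n)
    keep_s2 = []
    kept = 0
    for it in range(iterations):
        eta = mu + np.sum(u, axis=0)
        if mask.any():
            yw[mask] = eta[mask] + rng.normal(0, np.sqrt(s2_e), int(mask.sum()))
        r_all = yw - eta
        mu_new = rng.normal((r_all + mu).mean(), np.sqrt(s2_e / n))
        mu = mu_new
        for k in range(K):
            r = yw - mu - np.sum([u[j] for j in range(K) if j != k], axis=0)
            P = Kinv[k] / s2[k] + np.eye(n) / s2_e
            C = np.linalg.inv(P)
            mean = C @ (r / s2_e)
            L = np.linalg.cholesky((C + C.T) / 2.0 + 1e-12 * np.eye(n))
            u[k] = mean + L @ rng.standard_normal(n)
            ss = float(u[k] @ Kinv[k] @ u[k]) + nu0 * tau2_c
            s2[k] = ss / rng.chisquare(nu0 + n)
        resid = yw - mu - np.sum(u, axis=0)
        s2_e = (float(resid @ resid) + nu0 * tau2_e) / rng.chisquare(nu0 + n)
        if it >= burn_in:
            keep_lp += mu + np.sum(u, axis=0)
            keep_s2.append(np.r_[s2, s2_e])
            kept += 1
    return keep_lp / kept, np.array(keep_s2).mean(axis=0)
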