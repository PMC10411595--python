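"""Vectorised negative-binomial GLM fitting with a log link and fixed dispersion.

Bulk RNA-seq differential expression fits the same small design matrix to
thousands of genes. Rather than looping a generic GLM solver over genes, this
module runs iteratively reweighted least squares (Fisher scoring) batched over
the gene axis: one iteration is a handful of einsums plus a batched
``np.linalg.solve`` on G stacked p x p systems.

Model, for gene g and sample j with known size factor s_j and dispersion
``alpha_g``::

    y_gj ~ NB(mu_gj, alpha_g),   Var = mu + alpha * mu^2
    log mu_gj = log s_j + x_j' beta_g

Coefficients are on the natural-log scale here; callers convert to log2.

Degenerate design cells (all observed counts zero) drive the MLE of the cell
mean to zero. Following common DE-package practice the optimiser floors fitted
means at ``minmu`` (default 0.5 counts); the floor acts only inside the
optimiser and the reported likelihood, never on the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

# Fitted means below this floor are clamped inside the optimiser so that
# all-zero design cells yield finite, testable coefficients.
DEFAULT_MINMU = 0.5

# Dispersions below this are treated as Poisson in the likelihood.
_POISSON_ALPHA = 1e-7


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha) -> np.ndarray:
    """Per-gene NB log-likelihood summed over samples.

    ``y`` and ``mu`` are (G, n); ``alpha`` is scalar or (G,). Entries with
    alpha below ``1e-7`` use the Poisson limit.
    """
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-300)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (y.shape[0],))
    out = np.empty(y.shape[0])

    pois = alpha < _POISSON_ALPHA
    if np.any(pois):
        yp, mp = y[pois], mu[pois]
        out[pois] = np.sum(yp * np.log(mp) - mp - special.gammaln(yp + 1.0), axis=1)
    if np.any(~pois):
        yn, mn = y[~pois], mu[~pois]
        a = alpha[~pois][:, None]
        inv_a = 1.0 / a
        out[~pois] = np.sum(
            special.gammaln(yn + inv_a)
            - special.gammaln(inv_a)
            - special.gammaln(yn + 1.0)
            + yn * (np.log(a) + np.log(mn) - np.log1p(a * mn))
            - inv_a * np.log1p(a * mn),
            axis=1,
        )
    return out


@dataclass
class BatchFit:
    """Result of a batched NB GLM fit (natural-log scale)."""

    beta: np.ndarray          # (G, p) coefficients
    se: np.ndarray            # (G, p) standard errors from expected Fisher info
    loglik: np.ndarray        # (G,) maximised log-likelihood
    mu: np.ndarray            # (G, n) fitted means (floored at minmu)
    converged: np.ndarray     # (G,) bool
    degenerate: np.ndarray    # (G,) bool: gene had zero counts in every sample
    alpha: np.ndarray = field(default=None)  # dispersion used, (G,)


def _irls(Y, X, offset, alpha, beta0=None, max_iter=100, tol=1e-10, minmu=DEFAULT_MINMU):
    G, n = Y.shape
    p = X.shape[1]
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (G,)).astype(float)
    a_col = alpha[:, None]

    if beta0 is None:
        # unweighted LS on log(y + 0.5) as a starting value
        z0 = np.log(Y + 0.5) - offset[None, :]
        beta = np.linalg.lstsq(X, z0.T, rcond=None)[0].T
    else:
        beta = beta0.copy()

    converged = np.zeros(G, dtype=bool)
    log_minmu = np.log(minmu)
    XtX_cache = None
    for _ in range(max_iter):
        eta = beta @ X.T + offset[None, :]
        eta = np.maximum(eta, log_minmu)
        eta = np.minimum(eta, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + a_col * mu)
        z = (eta - offset[None, :]) + (Y - mu) / mu
        XtWX = np.einsum("gn,np,nq->gpq", w, X, X, optimize=True)
        XtWz = np.einsum("gn,np->gp", w * z, X)
        # small ridge keeps degenerate (near-zero-weight) systems solvable
        XtWX = XtWX + 1e-10 * np.eye(p)[None, :, :]
        beta_new = np.linalg.solve(XtWX, XtWz[:, :, None])[:, :, 0]
        delta = np.max(np.abs(beta_new - beta), axis=1)
        beta = beta_new
        converged = delta < tol
        if converged.all():
            break

    eta = np.minimum(np.maximum(beta @ X.T + offset[None, :], log_minmu), 30.0)
    mu = np.maximum(np.exp(eta), minmu)
    w = mu / (1.0 + a_col * mu)
    XtWX = np.einsum("gn,np,nq->gpq", w, X, X, optimize=True) + 1e-10 * np.eye(p)[None, :, :]
    cov = np.linalg.inv(XtWX)
    se = np.sqrt(np.maximum(np.einsum("gpp->gp", cov), 0.0))
    ll = nb_loglik(Y, mu, alpha)
    return beta, se, ll, mu, converged


def fit_glm(
    Y: np.ndarray,
    X: np.ndarray,
    size_factors: np.ndarray,
    alpha,
    beta0: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
    minmu: float = DEFAULT_MINMU,
) -> BatchFit:
    """Fit the NB GLM ``log mu = log sf + X beta`` to every row of ``Y``.

    Parameters
    ----------
    Y : (G, n) nonnegative counts.
    X : (n, p) design matrix, full rank.
    size_factors : (n,) positive per-sample scaling constants, used as a
        log offset.
    alpha : scalar or (G,) fixed NB dispersion(s).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[None, :]
    X = np.asarray(X, dtype=float)
    sf = np.asarray(size_factors, dtype=float)
    if np.any(sf <= 0):
        raise ValueError("size factors must be positive")
    if X.shape[0] != Y.shape[1]:
        raise ValueError("design matrix rows must match the number of samples")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear terms)")
    offset = np.log(sf)
    G = Y.shape[0]
    alpha_vec = np.broadcast_to(np.asarray(alpha, dtype=float), (G,)).astype(float)
    beta, se, ll, mu, conv = _irls(
        Y, X, offset, alpha_vec, beta0=beta0, max_iter=max_iter, tol=tol, minmu=minmu
    )
    degenerate = (Y.sum(axis=1) == 0)
    return BatchFit(
        beta=beta, se=se, loglik=ll, mu=mu,
        converged=conv & ~degenerate, degenerate=degenerate, alpha=alpha_vec,
    )


def profile_loglik(Y, X, offset, alpha, beta0=None, minmu=DEFAULT_MINMU):
    """Log-likelihood profiled over beta at fixed per-gene alpha."""
    beta, _, ll, mu, _ = _irls(Y, X, offset, alpha, beta0=beta0, max_iter=60, tol=1e-8, minmu=minmu)
    return ll, beta


def estimate_dispersion_ml(
    Y: np.ndarray,
    X: np.ndarray,
    size_factors: np.ndarray,
    alpha_min: float = 1e-8,
    alpha_max: float = 10.0,
    n_grid: int = 33,
    n_refine: int = 25,
    minmu: float = DEFAULT_MINMU,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene ML dispersion by profile likelihood under the given design.

    A coarse log-spaced grid brackets the optimum per gene; golden-section
    search (vectorised with per-gene brackets) refines it. Genes whose
    profile is maximised at the lower boundary get ``alpha_min`` (the floor);
    genes maximised at the upper boundary are flagged and fall back to a
    moment estimate clipped into range.

    Returns (alpha_hat, fallback_flag).
    """
    Y = np.asarray(Y, dtype=float)
    offset = np.log(np.asarray(size_factors, dtype=float))
    G = Y.shape[0]
    grid = np.geomspace(alpha_min, alpha_max, n_grid)
    lls = np.empty((n_grid, G))
    beta = None
    for i, a in enumerate(grid):
        lls[i], beta = profile_loglik(Y, X, offset, np.full(G, a), beta0=beta, minmu=minmu)
    best = np.argmax(lls, axis=0)

    lo = grid[np.maximum(best - 1, 0)]
    hi = grid[np.minimum(best + 1, n_grid - 1)]
    # golden-section on log(alpha), per-gene brackets
    la, lb = np.log(lo), np.log(hi)
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    lc = lb - invphi * (lb - la)
    ld = la + invphi * (lb - la)
    fc, beta = profile_loglik(Y, X, offset, np.exp(lc), beta0=beta, minmu=minmu)
    fd, beta = profile_loglik(Y, X, offset, np.exp(ld), beta0=beta, minmu=minmu)
    for _ in range(n_refine):
        take_c = fc > fd
        lb = np.where(take_c, ld, lb)
        la = np.where(take_c, la, lc)
        lc_new = lb - invphi * (lb - la)
        ld_new = la + invphi * (lb - la)
        # one new evaluation per gene: c side where take_c, d side otherwise
        lc, ld = lc_new, ld_new
        fc, beta = profile_loglik(Y, X, offset, np.exp(lc), beta0=beta, minmu=minmu)
        fd, beta = profile_loglik(Y, X, offset, np.exp(ld), beta0=beta, minmu=minmu)
    alpha_hat = np.exp(0.5 * (la + lb))
    alpha_hat = np.where(best == 0, alpha_min, alpha_hat)

    at_upper = best == n_grid - 1
    fallback = at_upper.copy()
    if np.any(at_upper):
        mom = _moment_dispersion(Y[at_upper], X, np.exp(offset))
        alpha_hat[at_upper] = np.clip(mom, alpha_min, alpha_max)
    return alpha_hat, fallback


def _moment_dispersion(Y, X, sf):
    """Method-of-moments dispersion from Pearson-style residuals under the design."""
    fit = fit_glm(Y, X, sf, alpha=0.0)
    mu = fit.mu
    n, p = X.shape
    dof = max(n - p, 1)
    num = np.sum(((Y - mu) ** 2 - mu) / (mu ** 2), axis=1)
    return np.maximum(num / dof, 0.0)
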