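"""Count normalisation, NB GLM testing, shrinkage, multiple testing, PCA.

This module implements the expression side of the analysis:

* median-of-ratios size factors,
* per-gene ML dispersion under the full design,
* likelihood-ratio screens for strain and strain x treatment effects,
* within-strain RNAi-vs-control Wald contrasts with normal-prior
  log-fold-change shrinkage,
* Benjamini-Hochberg adjustment with optional independent filtering,
* variance-stabilised PCA of the most variable genes.

All reported coefficients are log2; fitting happens on the natural-log scale
in :mod:`strainexpr.nbglm`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import nbglm
from .containers import ExpressionMatrix, SampleDesign

LOG2 = np.log(2.0)

#: Linear fold-change threshold for a differential-expression call.
FC_THRESHOLD = 1.5
#: Genome-wide FDR threshold for a differential-expression call.
FDR_THRESHOLD = 0.1


@dataclass
class NBFit:
    """Per-gene NB GLM fit with log2-scale coefficients."""

    gene_id: str
    coefficients: np.ndarray      # log2 scale
    se: np.ndarray                # log2 scale
    column_names: list
    size_factors: np.ndarray
    alpha: float
    loglik: float
    converged: bool
    degenerate: bool = False


def filter_low_counts(matrix: ExpressionMatrix, threshold: int = 10) -> ExpressionMatrix:
    """Drop genes whose counts summed over all samples fall below ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    keep = matrix.counts.sum(axis=1) >= threshold
    return matrix.subset_genes(keep)


def size_factors(matrix: ExpressionMatrix) -> np.ndarray:
    """Median-of-ratios per-sample size factors.

    Reference genes are those with strictly positive counts in every sample;
    each sample's factor is the median over reference genes of
    count / geometric-mean-of-that-gene.
    """
    counts = matrix.counts
    allpos = np.all(counts > 0, axis=1)
    if not np.any(allpos):
        raise ValueError(
            "no gene has positive counts in every sample; size factors are "
            "undefined (filter more aggressively or simulate deeper libraries)"
        )
    ref = counts[allpos]
    log_geo = np.mean(np.log(ref), axis=1, keepdims=True)
    ratios = np.log(ref) - log_geo
    return np.exp(np.median(ratios, axis=0))


def estimate_dispersion(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    sf: np.ndarray,
    terms: list[str] = ("strain", "treatment", "strain:treatment"),
    floor: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene ML dispersion under the full design, floored at ``floor``.

    Returns (alpha, fallback_flag); flagged genes hit the profile-likelihood
    boundary and carry a clipped moment estimate instead. No empirical-Bayes
    moderation is applied: estimates are transparent per-gene MLEs.
    """
    X, _ = design.design_matrix(list(terms))
    alpha, fallback = nbglm.estimate_dispersion_ml(matrix.counts, X, sf, alpha_min=floor)
    return np.maximum(alpha, floor), fallback


def fit_nb_glm(gene_counts, X, sf, alpha, gene_id: str = "", column_names=None) -> NBFit:
    """Fit one gene's NB GLM; coefficients and SEs reported on the log2 scale."""
    fit = nbglm.fit_glm(np.atleast_2d(gene_counts), np.asarray(X, float), sf, alpha)
    return NBFit(
        gene_id=gene_id,
        coefficients=fit.beta[0] / LOG2,
        se=fit.se[0] / LOG2,
        column_names=list(column_names) if column_names is not None else [],
        size_factors=np.asarray(sf, float),
        alpha=float(np.ravel(fit.alpha)[0]),
        loglik=float(fit.loglik[0]),
        converged=bool(fit.converged[0]),
        degenerate=bool(fit.degenerate[0]),
    )


def _check_nested(full_terms, reduced_terms):
    if not set(reduced_terms) <= set(full_terms):
        raise ValueError(
            f"reduced terms {sorted(reduced_terms)} are not nested in "
            f"full terms {sorted(full_terms)}"
        )


def base_means(matrix: ExpressionMatrix, sf: np.ndarray) -> np.ndarray:
    """Mean of size-factor-normalised counts per gene."""
    return np.mean(matrix.counts / sf[None, :], axis=1)


def lrt_screen(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    full_terms: list[str],
    reduced_terms: list[str],
    sf: np.ndarray | None = None,
    alpha: np.ndarray | float | None = None,
    independent_filtering: bool = True,
    fdr: float = FDR_THRESHOLD,
) -> pd.DataFrame:
    """Likelihood-ratio test of nested NB GLMs, gene by gene.

    Dispersion is estimated once under the full design (unless supplied) and
    reused for the reduced fit. Returns a DataFrame with columns
    gene_id, stat, df, pvalue, padj, base_mean.
    """
    _check_nested(full_terms, reduced_terms)
    if sf is None:
        sf = size_factors(matrix)
    X_full, _ = design.design_matrix(list(full_terms))
    X_red, _ = design.design_matrix(list(reduced_terms))
    df = X_full.shape[1] - X_red.shape[1]
    if alpha is None:
        alpha, _ = nbglm.estimate_dispersion_ml(matrix.counts, X_full, sf)
    fit_full = nbglm.fit_glm(matrix.counts, X_full, sf, alpha)
    fit_red = nbglm.fit_glm(matrix.counts, X_red, sf, alpha)
    stat = np.maximum(2.0 * (fit_full.loglik - fit_red.loglik), 0.0)
    if df > 0:
        pval = stats.chi2.sf(stat, df)
    else:
        pval = np.ones_like(stat)
    bm = base_means(matrix, sf)
    padj = bh_adjust(pval, base_means=bm,
                     independent_filtering=independent_filtering, fdr=fdr)
    return pd.DataFrame({
        "gene_id": matrix.gene_ids,
        "stat": stat,
        "df": df,
        "pvalue": pval,
        "padj": padj,
        "base_mean": bm,
    })


def shrink_lfc(raw_fc: np.ndarray, se: np.ndarray, prior_sd: float | None = None
               ) -> tuple[np.ndarray, float]:
    """Shrink log2 fold changes toward zero under a normal prior.

    The prior is N(0, prior_sd^2); if ``prior_sd`` is None it is estimated by
    marginal maximum likelihood across genes (raw ~ N(0, prior_sd^2 + se^2)).
    The shrunken estimate is the conjugate posterior mean
    ``raw * prior_sd^2 / (prior_sd^2 + se^2)``. Genes with nonfinite SE get
    NaN and should be excluded from calls.

    Returns (shrunken, prior_sd_used).
    """
    raw = np.asarray(raw_fc, dtype=float)
    se = np.asarray(se, dtype=float)
    ok = np.isfinite(raw) & np.isfinite(se) & (se > 0)
    if prior_sd is None:
        r, s2 = raw[ok], se[ok] ** 2
        if r.size == 0:
            prior_sd = 0.0
        else:
            def nll(log_tau):
                v = np.exp(2.0 * log_tau) + s2
                return float(np.sum(0.5 * np.log(v) + 0.5 * r ** 2 / v))
            res = optimize.minimize_scalar(nll, bounds=(-10.0, 5.0), method="bounded")
            prior_sd = float(np.exp(res.x))
            if nll(np.log(1e-12)) < res.fun:  # boundary: prior degenerate at zero
                prior_sd = 0.0
    tau2 = prior_sd ** 2
    out = np.full_like(raw, np.nan)
    out[ok] = raw[ok] * tau2 / (tau2 + se[ok] ** 2)
    zero_se = np.isfinite(raw) & (se == 0)
    out[zero_se] = raw[zero_se]  # se -> 0 limit: no shrinkage
    return out, prior_sd


def _de_call(lfc, padj, fc_threshold=FC_THRESHOLD, fdr=FDR_THRESHOLD):
    log2_thr = np.log2(fc_threshold)
    call = np.full(len(lfc), "ns", dtype=object)
    sig = np.isfinite(lfc) & np.isfinite(padj) & (padj < fdr)
    call[sig & (lfc > log2_thr)] = "up"
    call[sig & (lfc < -log2_thr)] = "down"
    return call


def wald_contrast(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    strain: str,
    treatment: str,
    sf: np.ndarray | None = None,
    alpha: np.ndarray | float | None = None,
    shrink: bool = True,
    prior_sd: float | None = None,
    independent_filtering: bool = False,
    fdr: float = FDR_THRESHOLD,
    fc_threshold: float = FC_THRESHOLD,
) -> pd.DataFrame:
    """Treatment-vs-control Wald contrast within one strain.

    Fits an intercept + treatment NB GLM to that strain's control and treated
    samples only. ``sf`` and per-gene ``alpha`` must align with the full
    matrix's samples/genes; both are subset internally. Returns a DataFrame
    with gene_id, strain, treatment, lfc_raw, lfc_shrunk, se, pvalue, padj,
    call.
    """
    samp = design.samples
    in_cell = (samp["strain"] == strain) & samp["treatment"].isin(
        [design.control_treatment, treatment])
    if not ((samp["strain"] == strain) & (samp["treatment"] == treatment)).any():
        raise ValueError(f"no samples for cell ({strain}, {treatment})")
    if not ((samp["strain"] == strain)
            & (samp["treatment"] == design.control_treatment)).any():
        raise ValueError(f"no samples for cell ({strain}, {design.control_treatment})")
    ids = samp.index[in_cell].to_numpy()
    sub = matrix.subset_samples(ids)
    if sf is None:
        sf_sub = size_factors(matrix)
    else:
        sf_sub = np.asarray(sf, float)
    pos = {s: j for j, s in enumerate(matrix.sample_ids)}
    sf_sub = sf_sub[[pos[s] for s in ids]]
    treated = (samp.loc[ids, "treatment"] == treatment).to_numpy().astype(float)
    X = np.column_stack([np.ones(len(ids)), treated])
    if alpha is None:
        alpha, _ = nbglm.estimate_dispersion_ml(sub.counts, X, sf_sub)
    fit = nbglm.fit_glm(sub.counts, X, sf_sub, alpha)
    lfc = fit.beta[:, 1] / LOG2
    se = fit.se[:, 1] / LOG2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = lfc / se
    pval = 2.0 * stats.norm.sf(np.abs(z))
    pval = np.where(fit.degenerate, np.nan, pval)
    if shrink:
        lfc_shrunk, _ = shrink_lfc(lfc, se, prior_sd=prior_sd)
    else:
        lfc_shrunk = lfc.copy()
    bm = base_means(sub, sf_sub)
    padj = bh_adjust(pval, base_means=bm,
                     independent_filtering=independent_filtering, fdr=fdr)
    call = _de_call(lfc_shrunk, padj, fc_threshold=fc_threshold, fdr=fdr)
    return pd.DataFrame({
        "gene_id": matrix.gene_ids,
        "strain": strain,
        "treatment": treatment,
        "lfc_raw": lfc,
        "lfc_shrunk": lfc_shrunk,
        "se": se,
        "pvalue": pval,
        "padj": padj,
        "base_mean": bm,
        "call": call,
    })


def _bh(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up with monotonicity; NaNs propagate."""
    p = np.asarray(pvals, dtype=float)
    ok = np.isfinite(p)
    out = np.full(p.shape, np.nan)
    m = int(ok.sum())
    if m == 0:
        return out
    ps = p[ok]
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[ok] = adj
    return out


def bh_adjust(
    pvals,
    base_means=None,
    independent_filtering: bool = False,
    fdr: float = FDR_THRESHOLD,
    quantiles: np.ndarray | None = None,
) -> np.ndarray:
    """BH adjustment, optionally with base-mean independent filtering.

    With filtering on, candidate base-mean thresholds are the 0-95% quantiles
    in 5% steps; the threshold maximising the number of rejections at ``fdr``
    is chosen (ties break toward filtering fewer genes), and genes below it
    receive NaN instead of an adjusted p-value.
    """
    p = np.asarray(pvals, dtype=float)
    finite = p[np.isfinite(p)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if not independent_filtering:
        return _bh(p)
    if base_means is None:
        raise ValueError("independent filtering requires base_means")
    bm = np.asarray(base_means, dtype=float)
    if quantiles is None:
        quantiles = np.arange(0.0, 0.951, 0.05)
    best_adj, best_rej, chosen_q = None, -1, 0.0
    for q in quantiles:
        thr = np.quantile(bm, q)
        keep = bm >= thr
        adj = np.full(p.shape, np.nan)
        adj[keep] = _bh(p[keep])
        rej = int(np.nansum(adj < fdr))
        if rej > best_rej:
            best_adj, best_rej, chosen_q = adj, rej, q
    return best_adj


def vst_pca(
    matrix: ExpressionMatrix,
    sf: np.ndarray,
    n_top: int = 500,
    n_pcs: int = 3,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of variance-stabilised expression for the most variable genes.

    The transform is log2(count / sf + 1), a simple variance-stabilising
    stand-in for package-specific transforms. The ``n_top`` genes with the
    largest cross-sample variance are selected, centred gene-wise, and
    decomposed by SVD. Returns (per-sample PC coordinates, variance-explained
    fractions over all components, truncated to n_pcs).
    """
    if matrix.n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    if n_top > matrix.n_genes:
        raise ValueError(f"n_top={n_top} exceeds gene count {matrix.n_genes}")
    vst = np.log2(matrix.counts / np.asarray(sf, float)[None, :] + 1.0)
    var = np.var(vst, axis=1)
    top = np.argsort(var, kind="mergesort")[::-1][:n_top]
    M = vst[top]
    M = M - M.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(M.T, full_matrices=False)
    n_pcs = min(n_pcs, len(s))
    coords = U[:, :n_pcs] * s[:n_pcs]
    total = np.sum(s ** 2)
    varexp = (s[:n_pcs] ** 2 / total) if total > 0 else np.zeros(n_pcs)
    cols = [f"PC{i + 1}" for i in range(n_pcs)]
    out = pd.DataFrame(coords, index=list(matrix.sample_ids), columns=cols)
    out.index.name = "sample"
    return out, varexp
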