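"""Normalisation, NB GLM fits, LRT/Wald tests, shrinkage, BH, PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from strainexpr import (
    ExpressionMatrix,
    SampleDesign,
    bh_adjust,
    filter_low_counts,
    fit_nb_glm,
    lrt_screen,
    shrink_lfc,
    size_factors,
    vst_pca,
    wald_contrast,
)
from strainexpr import nbglm
from strainexpr.count_model import base_means


def _matrix(counts, genes=None, samples=None):
    counts = np.asarray(counts, dtype=float)
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    samples = samples or [f"s{j}" for j in range(counts.shape[1])]
    return ExpressionMatrix(np.array(genes, object), np.array(samples, object), counts)


def _two_group_design(n_per=3, strains=("A", "B")):
    rows, ids = [], []
    for s in strains:
        for r in range(1, n_per + 1):
            ids.append(f"{s}_control_r{r}")
            rows.append({"strain": s, "treatment": "control", "replicate": r})
    return SampleDesign(pd.DataFrame(rows, index=pd.Index(ids, name="sample")),
                        strains[0], "control")


# --- filtering --------------------------------------------------------------

def test_filter_low_counts_boundary_and_identity():
    m = _matrix([[3, 3, 3], [3, 3, 4], [0, 0, 0]])
    out = filter_low_counts(m, threshold=10)
    assert list(out.gene_ids) == ["g1"]  # sums 9 removed, 10 retained
    allzero = filter_low_counts(_matrix([[0, 0], [0, 0]]), threshold=10)
    assert allzero.n_genes == 0
    ident = filter_low_counts(m, threshold=0)
    assert list(ident.gene_ids) == list(m.gene_ids)


# --- size factors -----------------------------------------------------------

def test_size_factors_hand_example_and_invariances():
    m = _matrix([[2, 8], [2, 8]])
    np.testing.assert_allclose(size_factors(m), [0.5, 2.0])
    # identical samples -> unit factors
    np.testing.assert_allclose(size_factors(_matrix([[5, 5], [9, 9]])), [1, 1])
    # appending an all-zero gene changes nothing
    m2 = _matrix([[2, 8], [2, 8], [0, 0]])
    np.testing.assert_allclose(size_factors(m2), [0.5, 2.0])
    # global rescaling of counts leaves factors unchanged
    m3 = _matrix(np.asarray([[2, 8], [2, 8]]) * 7.0)
    np.testing.assert_allclose(size_factors(m3), [0.5, 2.0])


def test_size_factors_error_without_reference_genes():
    with pytest.raises(ValueError, match="size factors"):
        size_factors(_matrix([[0, 5], [5, 0]]))


# --- single-gene GLM fits ---------------------------------------------------

def test_fit_intercept_closed_form():
    X = np.ones((4, 1))
    fit = fit_nb_glm([6, 6, 6, 6], X, np.ones(4), alpha=0.05, gene_id="g")
    assert fit.converged
    np.testing.assert_allclose(fit.coefficients[0], np.log2(6), atol=1e-6)


def test_fit_two_group_poisson_closed_form():
    X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
    fit = fit_nb_glm([3, 5, 4, 9, 11, 10], X, np.ones(6), alpha=1e-8)
    np.testing.assert_allclose(fit.coefficients[1], np.log2(10 / 4), atol=1e-6)


def test_fit_offset_invariance():
    X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
    y = np.array([3, 5, 4, 9, 11, 10], float)
    f1 = fit_nb_glm(y, X, np.ones(6), alpha=0.1)
    f2 = fit_nb_glm(2 * y, X, 2 * np.ones(6), alpha=0.1)
    np.testing.assert_allclose(f1.coefficients, f2.coefficients, atol=1e-5)


def test_fit_all_zero_gene_flagged_degenerate():
    X = np.ones((3, 1))
    fit = fit_nb_glm([0, 0, 0], X, np.ones(3), alpha=0.1)
    assert fit.degenerate and not fit.converged


def test_fit_rank_deficient_design_rejected():
    X = np.column_stack([np.ones(4), np.ones(4)])
    with pytest.raises(ValueError, match="rank deficient"):
        fit_nb_glm([1, 2, 3, 4], X, np.ones(4), alpha=0.1)


def test_fit_matches_statsmodels_oracle():
    """Dual route: our batched IRLS vs statsmodels GLM, coefficient,
    SE and log-likelihood."""
    import statsmodels.api as sm

    rng = np.random.default_rng(3)
    X = np.column_stack([np.ones(12), np.repeat([0, 1], 6),
                         np.tile([0, 1], 6)])
    sf = np.exp(rng.uniform(-0.3, 0.3, 12))
    alpha = 0.08
    for _ in range(5):
        mu = sf * np.exp(1.5 + 0.8 * X[:, 1] - 0.5 * X[:, 2])
        y = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu))
        ours = nbglm.fit_glm(y[None, :], X, sf, alpha)
        ref = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha),
                     offset=np.log(sf)).fit()
        np.testing.assert_allclose(ours.beta[0], ref.params, atol=1e-5)
        np.testing.assert_allclose(ours.se[0], ref.bse, rtol=1e-3)
        np.testing.assert_allclose(ours.loglik[0], ref.llf, atol=1e-5)


# --- dispersion -------------------------------------------------------------

def test_dispersion_poisson_limit_hits_floor():
    rng = np.random.default_rng(0)
    Y = rng.poisson(400, size=(300, 45)).astype(float)
    alpha, _ = nbglm.estimate_dispersion_ml(Y, np.ones((45, 1)), np.ones(45))
    assert np.median(alpha) < 0.01


def test_dispersion_recovery_alpha_point_one():
    rng = np.random.default_rng(5)
    a, mu = 0.1, 500.0
    Y = rng.negative_binomial(1 / a, (1 / a) / (1 / a + mu), size=(2000, 45))
    alpha, fb = nbglm.estimate_dispersion_ml(Y.astype(float), np.ones((45, 1)),
                                             np.ones(45))
    assert 0.07 <= np.median(alpha) <= 0.13
    assert fb.sum() == 0


def test_dispersion_constant_counts_at_floor():
    Y = np.full((1, 12), 7.0)
    X = np.column_stack([np.ones(12), np.repeat([0, 1], 6)])
    alpha, _ = nbglm.estimate_dispersion_ml(Y, X, np.ones(12))
    assert alpha[0] <= 1e-7


# --- LRT screen -------------------------------------------------------------

def test_lrt_full_equals_reduced_gives_unit_pvalues():
    m = _matrix(np.arange(1, 13).reshape(2, 6))
    design = _two_group_design()
    res = lrt_screen(m, design, ["strain"], ["strain"],
                     independent_filtering=False)
    np.testing.assert_allclose(res["stat"], 0.0, atol=1e-6)
    np.testing.assert_allclose(res["pvalue"], 1.0)


def test_lrt_non_nested_terms_rejected():
    m = _matrix(np.arange(1, 13).reshape(2, 6))
    with pytest.raises(ValueError, match="nested"):
        lrt_screen(m, _two_group_design(), ["strain"], ["treatment"])


def test_lrt_invariant_to_sample_and_gene_order(fitted_bundle):
    _, filtered, design, truth, sf, alpha = fitted_bundle
    ctl = design.control_samples()
    cm = filtered.subset_samples(ctl).subset_genes(
        np.arange(filtered.n_genes) < 80)
    cd = design.subset(ctl)
    res = lrt_screen(cm, cd, ["strain"], [], alpha=alpha[:80],
                     independent_filtering=False)
    perm = np.random.default_rng(0).permutation(cm.n_samples)
    cm2 = ExpressionMatrix(cm.gene_ids, cm.sample_ids[perm], cm.counts[:, perm])
    cd2 = SampleDesign(cd.samples.iloc[perm], cd.reference_strain,
                       cd.control_treatment)
    res2 = lrt_screen(cm2, cd2, ["strain"], [], alpha=alpha[:80],
                      independent_filtering=False)
    np.testing.assert_allclose(res["stat"], res2["stat"], rtol=1e-6, atol=1e-8)
    gperm = np.random.default_rng(1).permutation(cm.n_genes)
    cm3 = ExpressionMatrix(cm.gene_ids[gperm], cm.sample_ids,
                           cm.counts[gperm])
    res3 = lrt_screen(cm3, cd, ["strain"], [], alpha=alpha[:80][gperm],
                      independent_filtering=False)
    merged = res.set_index("gene_id").join(res3.set_index("gene_id"),
                                           rsuffix="_p")
    np.testing.assert_allclose(merged["stat"], merged["stat_p"],
                               rtol=1e-6, atol=1e-8)


def test_lrt_power_on_planted_strain_effects(fitted_bundle):
    """Planted 4-fold strain effects at the default study scale are
    essentially always detected at FDR 0.1."""
    _, filtered, design, truth, sf, alpha = fitted_bundle
    ctl = design.control_samples()
    res = lrt_screen(filtered.subset_samples(ctl), design.subset(ctl),
                     ["strain"], [], alpha=alpha, independent_filtering=False)
    de_true = set(truth.beta1.index[truth.is_strain_de]) & set(res["gene_id"])
    called = set(res.loc[res["padj"] < 0.1, "gene_id"])
    assert len(called & de_true) / len(de_true) >= 0.90


def test_wald_and_lrt_pvalues_agree_in_rank_for_two_groups():
    from scipy import stats as sps

    rng = np.random.default_rng(8)
    mu1 = rng.uniform(50, 500, size=300)
    mu2 = mu1 * np.exp(rng.normal(0, 0.5, size=300))
    r = 1 / 0.05
    g1 = rng.negative_binomial(r, r / (r + mu1[:, None]), size=(300, 3))
    g2 = rng.negative_binomial(r, r / (r + mu2[:, None]), size=(300, 3))
    Y = np.hstack([g1, g2]).astype(float)
    m = _matrix(Y)
    design = _two_group_design()
    res_l = lrt_screen(m, design, ["strain"], [], sf=np.ones(6), alpha=0.05,
                       independent_filtering=False)
    X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
    fit = nbglm.fit_glm(Y, X, np.ones(6), 0.05)
    z = fit.beta[:, 1] / fit.se[:, 1]
    wald_p = 2 * sps.norm.sf(np.abs(z))
    rho = sps.spearmanr(res_l["pvalue"], wald_p).statistic
    assert rho > 0.99


# --- Wald contrasts ---------------------------------------------------------

def _rnai_design():
    rows, ids = [], []
    for s in ("A", "B"):
        for t in ("control", "rnai"):
            for r in (1, 2, 3):
                ids.append(f"{s}_{t}_r{r}")
                rows.append({"strain": s, "treatment": t, "replicate": r})
    return SampleDesign(pd.DataFrame(rows, index=pd.Index(ids, name="sample")),
                        "A", "control")


def test_wald_identical_treatment_counts_give_zero_fc():
    design = _rnai_design()
    counts = np.tile([5, 7, 6], (3, 4))
    m = _matrix(counts, samples=list(design.sample_ids))
    res = wald_contrast(m, design, "A", "rnai", sf=np.ones(12), alpha=0.05,
                        shrink=False)
    np.testing.assert_allclose(res["lfc_raw"], 0.0, atol=1e-6)
    assert (res["call"] == "ns").all()


def test_wald_sign_flip_antisymmetry():
    design = _rnai_design()
    rng = np.random.default_rng(2)
    m = _matrix(rng.poisson(40, size=(20, 12)), samples=list(design.sample_ids))
    res = wald_contrast(m, design, "B", "rnai", sf=np.ones(12), alpha=0.05,
                        shrink=False)
    # swap treatment and control labels within strain B
    flipped = design.samples.copy()
    mask = flipped["strain"] == "B"
    flipped.loc[mask, "treatment"] = flipped.loc[mask, "treatment"].map(
        {"control": "rnai", "rnai": "control"})
    design2 = SampleDesign(flipped, "A", "control")
    res2 = wald_contrast(m, design2, "B", "rnai", sf=np.ones(12), alpha=0.05,
                         shrink=False)
    np.testing.assert_allclose(res["lfc_raw"], -res2["lfc_raw"], atol=1e-6)


def test_wald_missing_cell_is_an_error():
    design = _rnai_design()
    m = _matrix(np.ones((2, 12)), samples=list(design.sample_ids))
    with pytest.raises(ValueError, match="no samples for cell"):
        wald_contrast(m, design, "A", "nonexistent")


# --- shrinkage --------------------------------------------------------------

def test_shrink_lfc_fixed_prior_conjugate_example():
    shrunk, _ = shrink_lfc([2.0], [1.0], prior_sd=0.5)
    np.testing.assert_allclose(shrunk, [0.4])


def test_shrink_lfc_zero_raw_and_small_se_limits():
    shrunk, _ = shrink_lfc([0.0, 1.0], [1.0, 1e-12], prior_sd=0.5)
    np.testing.assert_allclose(shrunk[0], 0.0)
    np.testing.assert_allclose(shrunk[1], 1.0, atol=1e-6)
    exact, _ = shrink_lfc([1.0], [0.0], prior_sd=0.5)
    np.testing.assert_allclose(exact, [1.0])


def test_shrink_lfc_marginal_ml_recovers_prior_scale():
    rng = np.random.default_rng(6)
    tau = 0.8
    se = rng.uniform(0.1, 0.5, size=4000)
    raw = rng.normal(0, tau, size=4000) + rng.normal(0, se)
    shrunk, tau_hat = shrink_lfc(raw, se)
    assert abs(tau_hat - tau) < 0.1
    assert np.all(np.abs(shrunk) <= np.abs(raw) + 1e-12)


def test_shrink_lfc_nonfinite_se_excluded():
    shrunk, _ = shrink_lfc([1.0, 2.0], [0.5, np.inf], prior_sd=0.5)
    assert np.isnan(shrunk[1]) and np.isfinite(shrunk[0])


# --- BH adjustment ----------------------------------------------------------

def _bh_oracle(pvals):
    """Brute-force BH: padj_i = min over candidate thresholds t >= p_i of
    m*t / #{p <= t}."""
    p = np.asarray(pvals, float)
    m = len(p)
    out = np.empty(m)
    for i in range(m):
        cands = [t for t in p if t >= p[i]]
        out[i] = min(min(m * t / np.sum(p <= t) for t in cands), 1.0)
    return out


def test_bh_hand_examples():
    np.testing.assert_allclose(bh_adjust([0.03]), [0.03])
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04])


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50))
def test_bh_matches_brute_force_oracle(pvals):
    np.testing.assert_allclose(bh_adjust(pvals), _bh_oracle(pvals), atol=1e-12)


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(1)
    p = rng.uniform(size=200) ** 2
    ours = bh_adjust(p)
    ref = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(ours, ref, atol=1e-12)


def test_bh_filtering_off_adjusts_every_gene():
    p = np.linspace(0.001, 0.9, 40)
    adj = bh_adjust(p, independent_filtering=False)
    assert np.isfinite(adj).all()


def test_bh_independent_filtering_maximises_rejections():
    rng = np.random.default_rng(0)
    n = 400
    bm = np.concatenate([rng.uniform(0, 5, n // 2), rng.uniform(50, 500, n // 2)])
    p = np.concatenate([rng.uniform(size=n // 2),
                        rng.uniform(size=n // 2) ** 6])
    adj_f = bh_adjust(p, base_means=bm, independent_filtering=True)
    adj_n = bh_adjust(p, independent_filtering=False)
    assert np.nansum(adj_f < 0.1) >= np.nansum(adj_n < 0.1)
    assert np.isnan(adj_f).sum() > 0  # some genes were filtered out


def test_bh_rejects_out_of_range_pvalues():
    with pytest.raises(ValueError, match="p-values"):
        bh_adjust([0.2, 1.7])


# --- PCA --------------------------------------------------------------------

def test_vst_pca_identical_samples_give_zero_coordinates():
    m = _matrix(np.tile([[5.0], [9.0], [2.0]], (1, 6)))
    coords, varexp = vst_pca(m, np.ones(6), n_top=3, n_pcs=2)
    np.testing.assert_allclose(coords.to_numpy(), 0.0, atol=1e-10)


def test_vst_pca_separates_two_planted_groups():
    rng = np.random.default_rng(4)
    base = rng.poisson(100, size=(600, 10)).astype(float)
    base[:500, 5:] *= 4.0  # 500 genes shifted in the second group
    m = _matrix(base)
    coords, varexp = vst_pca(m, np.ones(10), n_top=500, n_pcs=3)
    pc1 = coords["PC1"].to_numpy()
    g1, g2 = pc1[:5], pc1[5:]
    assert max(g1) < min(g2) or max(g2) < min(g1)
    assert np.all(np.diff(varexp) <= 1e-12)
    assert varexp.sum() <= 1.0 + 1e-9


def test_vst_pca_requires_two_samples():
    m = _matrix([[1.0], [2.0]])
    with pytest.raises(ValueError, match="2 samples"):
        vst_pca(m, np.ones(1), n_top=2)
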