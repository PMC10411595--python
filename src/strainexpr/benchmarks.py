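"""Self-validation scenarios run on synthetic data with known truth.

Each function simulates a scenario at desk scale, runs the relevant part of
the pipeline, and returns the measured operating characteristics: type-I
error of the LRT screens on a null simulation, bias and absolute error of
planted strain effects, call rates for planted RNAi knockdowns, and the
off-gene round trip. Scenario sizes (2,000 genes, 3 replicates per cell) are
the package's standard desk-scale study conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import nbglm
from .containers import ExpressionMatrix
from .count_model import LOG2, filter_low_counts, lrt_screen, size_factors, \
    wald_contrast
from .coverage import classify_coverage, gene_coverage, merge_exons
from .off_genes import call_off_genes, off_gene_summary, pairwise_de_union, \
    zero_expression_strains
from .simulate import SimulationConfig, simulate_annotation, simulate_coverage, \
    simulate_experiment


def _true_alpha(truth, gene_ids):
    idx = {g: i for i, g in enumerate(truth.gene_ids)}
    return np.array([truth.alpha[idx[g]] for g in gene_ids])


def lrt_calibration(seed: int = 0, n_genes: int = 2000) -> dict:
    """Type-I error of the strain and interaction screens on a null simulation.

    Nothing is planted; dispersion is the known simulation value, so the
    measured rejection rate at p < 0.05 isolates the chi-squared calibration
    of the likelihood-ratio statistic itself.
    """
    config = SimulationConfig(n_genes=n_genes, seed=seed, frac_strain_de=0.0,
                              frac_interaction=0.0, frac_off=0.0)
    matrix, design, truth = simulate_experiment(config)
    filtered = filter_low_counts(matrix)
    sf = size_factors(filtered)
    alpha = _true_alpha(truth, filtered.gene_ids)
    ctl = design.control_samples()
    strain = lrt_screen(filtered.subset_samples(ctl), design.subset(ctl),
                        ["strain"], [], alpha=alpha,
                        independent_filtering=False)
    inter = lrt_screen(filtered, design,
                       ["strain", "treatment", "strain:treatment"],
                       ["strain", "treatment"], sf=sf, alpha=alpha,
                       independent_filtering=False)
    n = len(strain)
    mc_se = np.sqrt(0.05 * 0.95 / n)
    return {
        "strain_rejection_rate": float((strain["pvalue"] < 0.05).mean()),
        "interaction_rejection_rate": float((inter["pvalue"] < 0.05).mean()),
        "n_genes": n,
        "monte_carlo_se": float(mc_se),
    }


def strain_effect_recovery(seed: int = 0) -> dict:
    """Bias and MAE of fitted strain coefficients against planted effects.

    500 DE genes among 1,500, baseline mean >= 200 counts, dispersion 0.05,
    3 replicates per strain x treatment cell. The scenario plants no
    treatment or interaction effects, so strain effects are estimated under
    the additive strain + treatment model, pooling all 9 samples per strain;
    fitted log2 coefficients are compared to the planted ones over every
    planted nonzero (gene, strain) effect.
    """
    config = SimulationConfig(
        n_genes=1500, seed=seed, frac_strain_de=1 / 3, frac_interaction=0.0,
        frac_off=0.0, baseline_mean_log2=9.3, baseline_sd_log2=0.3,
        dispersion_alpha=0.05)
    matrix, design, truth = simulate_experiment(config)
    filtered = filter_low_counts(matrix)
    sf = size_factors(filtered)
    alpha = _true_alpha(truth, filtered.gene_ids)
    X, names = design.design_matrix(["strain", "treatment"])
    fit = nbglm.fit_glm(filtered.counts, X, sf, alpha)
    coef = pd.DataFrame(fit.beta / LOG2, index=filtered.gene_ids, columns=names)
    errors = []
    for strain in truth.beta1.columns:
        planted = truth.beta1[strain]
        nz = planted.index[(planted != 0)]
        nz = [g for g in nz if g in coef.index]
        est = coef.loc[nz, f"strain[{strain}]"].to_numpy()
        errors.append(est - planted.loc[nz].to_numpy())
    errors = np.concatenate(errors)
    return {
        "n_effects": int(errors.size),
        "mean_signed_bias": float(errors.mean()),
        "mae": float(np.abs(errors).mean()),
    }


def knockdown_recovery(seed: int = 0) -> dict:
    """Fraction of planted 4-fold RNAi effects called in the right direction.

    300 genes among 2,000 carry a +/-2 log2 interaction effect in one
    (strain, treatment) cell at baseline mean ~1,000; within-strain Wald
    contrasts with shrunken fold changes must call them DE (adjusted
    p < 0.1, shrunken |FC| > 1.5) in the planted direction.
    """
    config = SimulationConfig(
        n_genes=2000, seed=seed, frac_interaction=0.15, frac_strain_de=0.2,
        frac_off=0.0, baseline_mean_log2=np.log2(1000.0),
        baseline_sd_log2=0.3, dispersion_alpha=0.05)
    matrix, design, truth = simulate_experiment(config)
    filtered = filter_low_counts(matrix)
    sf = size_factors(filtered)
    alpha = _true_alpha(truth, filtered.gene_ids)
    tested = set(filtered.gene_ids)
    cache: dict = {}
    correct = total = down_correct = down_total = 0
    for cell in truth.beta3.columns:
        planted = truth.beta3.index[truth.beta3[cell] != 0]
        planted = [g for g in planted if g in tested]
        if not planted:
            continue
        strain, treatment = cell.split(":")
        if cell not in cache:
            cache[cell] = wald_contrast(filtered, design, strain, treatment,
                                        sf=sf, alpha=alpha).set_index("gene_id")
        res = cache[cell]
        for g in planted:
            want = "down" if truth.beta3.loc[g, cell] < 0 else "up"
            hit = res.loc[g, "call"] == want
            total += 1
            correct += hit
            if want == "down":
                down_total += 1
                down_correct += hit
    return {
        "n_planted": total,
        "direction_correct_rate": correct / total,
        "n_planted_down": down_total,
        "down_called_rate": down_correct / down_total if down_total else np.nan,
    }


def off_gene_roundtrip(seed: int = 0) -> dict:
    """Recovery of planted off genes and their coverage categories.

    Zero coverage noise, 8-fold planted effects, expressed-strain means
    floored at 200 counts. Measures (gene, strain)-level sensitivity and
    precision of the off calls, exact category agreement, and conservation
    of the per-strain three-way partition.
    """
    config = SimulationConfig(
        n_genes=2000, seed=seed, effect_size_log2=3.0, off_mean_min=200.0,
        cov_noise_sd=0.0, depth_strain_sd=0.0)
    matrix, design, truth = simulate_experiment(config)
    filtered = filter_low_counts(matrix)
    alpha = _true_alpha(truth, filtered.gene_ids)
    ctl = design.control_samples()
    cm = filtered.subset_samples(ctl)
    cd = design.subset(ctl)
    union = pairwise_de_union(cm, cd, alpha=alpha)
    zeros = zero_expression_strains(filtered, design)
    annotation = simulate_annotation(config)
    depth = simulate_coverage(annotation, truth, config)
    merged = merge_exons(annotation)
    raw = pd.DataFrame({s: gene_coverage(merged, df) for s, df in depth.items()})
    cov = classify_coverage(raw)
    records = call_off_genes(union, zeros, cov, design.strains)

    tested = set(filtered.gene_ids)
    true_pairs = {(g, s) for g, ss in truth.off_strains.items()
                  for s in ss if g in tested}
    called_pairs = {(r.gene_id, s) for r in records for s in r.off_strains}
    tp = true_pairs & called_pairs
    cat_of = {"missing": "missing_genome", "low": "uncertain_low_coverage",
              "adequate": "truly_off"}
    cat_ok = sum(
        1 for r in records for s in r.off_strains
        if (r.gene_id, s) in true_pairs
        and r.categories[s] == cat_of[truth.coverage_class.loc[r.gene_id, s]])
    summary = off_gene_summary(records, design.strains)
    conserved = bool(all(
        row.truly_off + row.missing_genome + row.uncertain_low_coverage
        == row.total_off for row in summary.itertuples(index=False)))
    return {
        "n_true_off_pairs": len(true_pairs),
        "n_called_off_pairs": len(called_pairs),
        "sensitivity": len(tp) / len(true_pairs) if true_pairs else np.nan,
        "precision": len(tp) / len(called_pairs) if called_pairs else np.nan,
        "category_agreement": cat_ok / len(tp) if tp else np.nan,
        "partition_conserved": conserved,
    }
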