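"""End-to-end orchestration: config -> tables -> summary report.

Stage order mirrors the analysis: low-count filter, size factors, dispersion,
strain LRT on control samples, strain x treatment interaction LRT, per-strain
RNAi contrasts, variance-stabilised PCA, merged exons, DNA coverage
classification, off-gene calling and triage, and the overlap/proportion
enrichment summaries. Every stage writes a TSV; the final report recomputes
its percentages from the emitted tables so report and tables cannot disagree.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, count_model, coverage as covmod, off_genes as offmod
from . import enrichment as enrichmod
from . import nbglm
from .containers import ExpressionMatrix, SampleDesign
from .simulate import SimulationConfig, simulate_annotation, simulate_coverage, \
    simulate_experiment, write_bundle

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # file inputs (ignored in synthetic mode)
    counts: str | None = None
    samples: str | None = None
    gtf: str | None = None
    depth: dict = field(default_factory=dict)       # strain -> path
    strain_aliases: dict = field(default_factory=dict)  # expression label -> coverage label
    # synthetic mode
    synthetic: SimulationConfig | None = None
    # labels
    reference_strain: str = "N2"
    control_treatment: str = "control"
    # thresholds
    low_count_threshold: int = 10
    fdr: float = 0.1
    fc_threshold: float = 1.5
    low_coverage_threshold: float = 0.25
    # flags
    independent_filtering: bool = True
    shrinkage: bool = True
    # run
    outdir: str = "strainexpr_out"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.low_count_threshold < 0:
            raise ValueError("low_count_threshold must be nonnegative")
        for name in ("fdr", "fc_threshold", "low_coverage_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.synthetic is None:
            for name in ("counts", "samples"):
                path = getattr(self, name)
                if path is None:
                    raise ValueError(f"non-synthetic mode requires a {name} file")
                if not Path(path).exists():
                    raise ValueError(f"{name} file not found: {path}")
            for strain, path in self.depth.items():
                if not Path(path).exists():
                    raise ValueError(f"depth file for {strain} not found: {path}")
            if self.gtf is not None and not Path(self.gtf).exists():
                raise ValueError(f"gtf file not found: {self.gtf}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if syn is not None:
            cfg.synthetic = SimulationConfig(**{
                k: (tuple(v) if isinstance(v, list) else v) for k, v in syn.items()
            })
        return cfg


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(matrix: ExpressionMatrix, design: SampleDesign,
                    annotation=None, depth: dict | None = None) -> ValidationReport:
    """Check label agreement and basic sanity; errors vs warnings distinguished."""
    rep = ValidationReport()
    ids, counts = np.unique(matrix.gene_ids, return_counts=True)
    for g in ids[counts > 1]:
        rep.errors.append(f"duplicated gene id: {g}")
    if matrix.counts.size and matrix.counts.min() < 0:
        rep.errors.append("counts contain negative entries")
    sheet = set(design.sample_ids)
    cols = set(matrix.sample_ids)
    for s in sorted(cols - sheet):
        rep.errors.append(f"count column {s} missing from sample sheet")
    for s in sorted(sheet - cols):
        rep.errors.append(f"sample sheet row {s} missing from counts")
    cells = design.samples.groupby(["strain", "treatment"], sort=False).size()
    for (s, t), n in cells.items():
        if n < 3:
            rep.warnings.append(f"cell ({s}, {t}) has only {n} replicate(s)")
    if annotation is not None:
        ann_genes = set(annotation.gene_ids)
        missing = [g for g in matrix.gene_ids if g not in ann_genes]
        if missing:
            rep.warnings.append(
                f"{len(missing)} genes in counts absent from annotation "
                f"(first: {missing[0]})")
        if depth:
            ann_chroms = set(annotation.exons["chrom"])
            for strain, df in depth.items():
                extra = set(df["chrom"]) - ann_chroms
                if extra:
                    rep.errors.append(
                        f"depth for {strain} on chromosomes absent from the "
                        f"annotation: {sorted(extra)}")
    return rep


def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        sim = config.synthetic
        matrix, design, truth = simulate_experiment(sim)
        annotation = simulate_annotation(sim)
        depth = simulate_coverage(annotation, truth, sim)
        return matrix, design, annotation, depth, truth
    matrix = ExpressionMatrix.from_tsv(config.counts)
    design = SampleDesign.from_tsv(config.samples, config.reference_strain,
                                   config.control_treatment)
    annotation = covmod.GeneAnnotation.from_gtf(config.gtf) if config.gtf else None
    depth = {}
    for strain, path in config.depth.items():
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "mean_depth"])
        depth[strain] = df
    return matrix, design, annotation, depth, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the summary dict written to report.json."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    matrix, design, annotation, depth, truth = _load_inputs(config)
    if matrix.n_genes == 0 or matrix.n_samples == 0:
        raise ValueError("empty count matrix: nothing to analyse")
    report = validate_inputs(matrix, design, annotation, depth)
    for w in report.warnings:
        logger.warning("%s", w)
    if not report.ok:
        raise ValueError("input validation failed: " + "; ".join(report.errors))

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "strainexpr_version": __version__,
        "seed": config.seed,
        "n_genes_in": int(matrix.n_genes),
        "n_samples": int(matrix.n_samples),
    }
    if config.synthetic is not None:
        write_bundle(outdir / "inputs", matrix, design, truth, annotation, depth)

    # --- expression side -------------------------------------------------
    filtered = count_model.filter_low_counts(matrix, config.low_count_threshold)
    manifest["n_genes_filtered_out"] = int(matrix.n_genes - filtered.n_genes)
    manifest["n_genes_tested"] = int(filtered.n_genes)
    assert manifest["n_genes_filtered_out"] + manifest["n_genes_tested"] \
        == manifest["n_genes_in"]

    sf = count_model.size_factors(filtered)
    pd.DataFrame({"sample": filtered.sample_ids, "size_factor": sf}) \
        .to_csv(outdir / "size_factors.tsv", sep="\t", index=False)

    X_full, _ = design.design_matrix(["strain", "treatment", "strain:treatment"])
    alpha, disp_fallback = nbglm.estimate_dispersion_ml(filtered.counts, X_full, sf)
    pd.DataFrame({"gene_id": filtered.gene_ids, "alpha": alpha,
                  "fallback": disp_fallback}) \
        .to_csv(outdir / "dispersion.tsv", sep="\t", index=False)

    ctl_ids = design.control_samples()
    ctl_matrix = filtered.subset_samples(ctl_ids)
    ctl_design = design.subset(ctl_ids)
    strain_lrt = count_model.lrt_screen(
        ctl_matrix, ctl_design, ["strain"], [],
        independent_filtering=config.independent_filtering, fdr=config.fdr)
    strain_lrt.to_csv(outdir / "strain_lrt.tsv", sep="\t", index=False)

    interaction_lrt = count_model.lrt_screen(
        filtered, design,
        ["strain", "treatment", "strain:treatment"], ["strain", "treatment"],
        sf=sf, alpha=alpha,
        independent_filtering=config.independent_filtering, fdr=config.fdr)
    interaction_lrt.to_csv(outdir / "interaction_lrt.tsv", sep="\t", index=False)

    contrasts = []
    for strain in design.strains:
        for treatment in design.treatments:
            if treatment == design.control_treatment:
                continue
            res = count_model.wald_contrast(
                filtered, design, strain, treatment, sf=sf, alpha=alpha,
                shrink=config.shrinkage, fdr=config.fdr,
                fc_threshold=config.fc_threshold)
            contrasts.append(res)
    contrasts = pd.concat(contrasts, ignore_index=True)
    contrasts.to_csv(outdir / "contrasts.tsv", sep="\t", index=False)

    n_top = min(500, filtered.n_genes)
    pca, varexp = count_model.vst_pca(filtered, sf, n_top=n_top)
    pca.to_csv(outdir / "pca.tsv", sep="\t")
    manifest["pca_variance_explained"] = [float(v) for v in varexp]

    # --- coverage side ---------------------------------------------------
    cov_table = None
    if annotation is not None and depth:
        merged = covmod.merge_exons(annotation)
        merged.to_bed(outdir / "merged_exons.bed")
        raw = {}
        for strain, df in depth.items():
            label = config.strain_aliases.get(strain, strain)
            raw[label] = covmod.gene_coverage(merged, df)
        raw_df = pd.DataFrame(raw)
        cov_table = covmod.classify_coverage(
            raw_df, low_threshold=config.low_coverage_threshold)
        cov_table.to_csv(outdir / "coverage.tsv", sep="\t", index=False)

    # --- off genes -------------------------------------------------------
    off_records = []
    if len(design.strains) >= 2:
        union = offmod.pairwise_de_union(ctl_matrix, ctl_design, fdr=config.fdr)
        zeros = offmod.zero_expression_strains(filtered, design)
        cov_for_off = cov_table if cov_table is not None else \
            pd.DataFrame(columns=["gene_id", "strain", "cov_class"])
        off_records = offmod.call_off_genes(union, zeros, cov_for_off,
                                            design.strains)
        off_records = offmod.rnai_responsive_off(off_records, contrasts)
        offmod.records_to_frame(off_records) \
            .to_csv(outdir / "off_genes.tsv", sep="\t", index=False)
        offmod.off_gene_summary(off_records, design.strains) \
            .to_csv(outdir / "off_summary.tsv", sep="\t", index=False)

    # --- enrichment summaries (recomputed from the emitted tables) -------
    summary = summarize_run(outdir, fdr=config.fdr)
    if truth is not None:
        summary["truth"] = _score_against_truth(
            strain_lrt, interaction_lrt, off_records, truth, config.fdr)
    manifest["config"] = {k: (asdict(v) if isinstance(v, SimulationConfig) else v)
                          for k, v in asdict(config).items()}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    with open(outdir / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return summary


def summarize_run(outdir, fdr: float = 0.1) -> dict:
    """Recompute the bookkeeping summary from a run's emitted TSVs."""
    outdir = Path(outdir)
    summary: dict = {}
    strain_lrt = pd.read_csv(outdir / "strain_lrt.tsv", sep="\t")
    n_adj = int(strain_lrt["padj"].notna().sum())
    de_genes = set(strain_lrt.loc[strain_lrt["padj"] < fdr, "gene_id"])
    summary["n_genes_tested"] = int(len(strain_lrt))
    summary["n_genes_with_padj_strain"] = n_adj
    summary["n_strain_de"] = len(de_genes)
    summary["pct_strain_de"] = round(100.0 * len(de_genes) / n_adj, 1) if n_adj else np.nan

    inter = pd.read_csv(outdir / "interaction_lrt.tsv", sep="\t")
    n_int = int((inter["padj"] < fdr).sum())
    summary["n_interaction_de"] = n_int
    n_adj_int = int(inter["padj"].notna().sum())
    summary["pct_interaction_de"] = round(100.0 * n_int / n_adj_int, 1) if n_adj_int else np.nan

    cov_path = outdir / "coverage.tsv"
    if cov_path.exists():
        cov = pd.read_csv(cov_path, sep="\t")
        flagged = set(cov.loc[cov["cov_class"].isin(["missing", "low"]), "gene_id"])
        universe = set(strain_lrt["gene_id"])
        flagged &= universe
        k = len(flagged & de_genes)
        t = enrichmod.OverlapTable(N=len(universe), K=len(de_genes),
                                   n=len(flagged), k=k)
        enr = enrichmod.hypergeom_enrichment(t)
        summary["coverage_overlap"] = {
            "N": t.N, "K": t.K, "n": t.n, "k": k,
            "hypergeom_p": enr.pvalue,
            "log10_p": enr.log10_pvalue,
            "fold_enrichment": enr.fold_enrichment,
            **enrichmod.summarize_overlap(t),
        }
        per_strain = cov.groupby(["strain", "cov_class"]).size().unstack(fill_value=0)
        summary["coverage_class_counts"] = {
            s: {c: int(v) for c, v in row.items()}
            for s, row in per_strain.iterrows()
        }

    off_path = outdir / "off_summary.tsv"
    if off_path.exists():
        off_sum = pd.read_csv(off_path, sep="\t")
        summary["off_per_strain"] = off_sum.set_index("strain").to_dict("index")
        off = pd.read_csv(outdir / "off_genes.tsv", sep="\t")
        summary["n_off_genes"] = int(len(off))
        if len(off):
            poor = off["categories"].str.contains("missing_genome|uncertain", regex=True)
            resp = off["rnai_responsive"].astype(bool)
            n2, x2 = int(len(off)), int(poor.sum())
            n1, x1 = int(resp.sum()), int((poor & resp).sum())
            summary["n_rnai_responsive_off"] = n1
            if n1 > 0:
                chi2, pval = enrichmod.two_proportion_test(
                    enrichmod.ProportionPair(x1=x1, n1=n1, x2=x2, n2=n2))
                summary["responsive_off_poor_coverage"] = {
                    "x1": x1, "n1": n1, "x2": x2, "n2": n2,
                    "chi2": chi2, "pvalue": pval,
                }
    return summary


def _score_against_truth(strain_lrt, interaction_lrt, off_records, truth, fdr):
    """Recovery of planted signals; only available in synthetic mode."""
    idx = {g: i for i, g in enumerate(truth.gene_ids)}
    de_called = set(strain_lrt.loc[strain_lrt["padj"] < fdr, "gene_id"])
    de_true = set(truth.beta1.index[truth.is_strain_de])
    tested = set(strain_lrt["gene_id"])
    de_true &= tested
    out = {
        "strain_de_sensitivity": round(len(de_called & de_true) / len(de_true), 4)
        if de_true else np.nan,
    }
    true_off_pairs = {(g, s) for g, ss in truth.off_strains.items() for s in ss
                      if g in tested}
    called_off_pairs = {(r.gene_id, s) for r in off_records for s in r.off_strains}
    if true_off_pairs:
        tp = len(true_off_pairs & called_off_pairs)
        out["off_sensitivity"] = round(tp / len(true_off_pairs), 4)
        out["off_precision"] = round(tp / len(called_off_pairs), 4) \
            if called_off_pairs else np.nan
    return out
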