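"""Identification and triage of strain-specific unexpressed ("off") genes.

A gene is "off" in a strain when every sample of that strain — all treatments,
all replicates — has exactly zero estimated counts, while the gene is
significantly differentially expressed between at least one pair of strains in
the control condition (which guarantees real expression somewhere). Each off
(gene, strain) call is then resolved with the DNA-coverage screen:

* ``missing_genome``          — DNA coverage exactly 0: the gene is likely
  absent from that strain's genome;
* ``uncertain_low_coverage``  — low DNA coverage: the zero-expression call may
  be a reference-bias artefact;
* ``truly_off``               — adequate coverage: a confident expression loss
  at the RNA level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nbglm
from .containers import ExpressionMatrix, SampleDesign
from .count_model import FDR_THRESHOLD, bh_adjust, size_factors

logger = logging.getLogger(__name__)

OFF_CATEGORIES = ("truly_off", "missing_genome", "uncertain_low_coverage")

_CLASS_TO_CATEGORY = {
    "missing": "missing_genome",
    "low": "uncertain_low_coverage",
    "adequate": "truly_off",
}


@dataclass
class OffGeneRecord:
    gene_id: str
    off_strains: frozenset
    evidence_strain_pairs: frozenset      # pairs with significant pairwise DE
    categories: dict                      # off strain -> category
    rnai_responsive: bool = False
    responsive_contrasts: list = field(default_factory=list)  # (strain, treatment, direction)


def pairwise_de_union(
    control_matrix: ExpressionMatrix,
    design: SampleDesign,
    sf: np.ndarray | None = None,
    alpha: np.ndarray | float | None = None,
    fdr: float = FDR_THRESHOLD,
) -> dict:
    """Wald test of every strain pair on control samples.

    Returns {gene_id: frozenset of (strainA, strainB) pairs significant at
    adjusted p < fdr}; genes with no significant pair are absent. Strain pairs
    where either strain has fewer than 2 control replicates are skipped with a
    warning.
    """
    strains = design.strains
    if len(strains) < 2:
        raise ValueError("pairwise DE requires at least 2 strains")
    if sf is None:
        sf = size_factors(control_matrix)
    sf = np.asarray(sf, float)
    samp = design.samples
    pos = {s: j for j, s in enumerate(control_matrix.sample_ids)}
    if alpha is None:
        X_full, _ = design.design_matrix(["strain"])
        alpha, _ = nbglm.estimate_dispersion_ml(control_matrix.counts, X_full, sf)
    evidence: dict = {}
    for ai in range(len(strains)):
        for bi in range(ai + 1, len(strains)):
            a, b = strains[ai], strains[bi]
            ids_a = samp.index[samp["strain"] == a].to_numpy()
            ids_b = samp.index[samp["strain"] == b].to_numpy()
            if len(ids_a) < 2 or len(ids_b) < 2:
                logger.warning("skipping strain pair (%s, %s): fewer than 2 "
                               "control replicates", a, b)
                continue
            ids = np.concatenate([ids_a, ids_b])
            idx = [pos[s] for s in ids]
            Y = control_matrix.counts[:, idx]
            X = np.column_stack([
                np.ones(len(ids)),
                np.concatenate([np.zeros(len(ids_a)), np.ones(len(ids_b))]),
            ])
            fit = nbglm.fit_glm(Y, X, sf[idx], alpha)
            from scipy import stats
            with np.errstate(divide="ignore", invalid="ignore"):
                z = fit.beta[:, 1] / fit.se[:, 1]
            pval = 2.0 * stats.norm.sf(np.abs(z))
            pval = np.where(fit.degenerate, np.nan, pval)
            padj = bh_adjust(pval)
            for g in control_matrix.gene_ids[np.nan_to_num(padj, nan=1.0) < fdr]:
                evidence.setdefault(g, set()).add((a, b))
    return {g: frozenset(v) for g, v in evidence.items()}


def zero_expression_strains(full_matrix: ExpressionMatrix,
                            design: SampleDesign) -> dict:
    """Strains in which a gene has exactly zero counts in every sample.

    Uses all treatments and replicates. Returns {gene_id: frozenset}; genes
    expressed everywhere map to an empty set (omitted).
    """
    samp = design.samples
    pos = {s: j for j, s in enumerate(full_matrix.sample_ids)}
    out: dict = {}
    for strain in design.strains:
        ids = samp.index[samp["strain"] == strain].to_numpy()
        idx = [pos[s] for s in ids]
        allzero = np.all(full_matrix.counts[:, idx] == 0, axis=1)
        for g in full_matrix.gene_ids[allzero]:
            out.setdefault(g, set()).add(strain)
    return {g: frozenset(v) for g, v in out.items()}


def call_off_genes(
    pairwise_union: dict,
    zero_sets: dict,
    coverage: pd.DataFrame,
    strains: list,
) -> list[OffGeneRecord]:
    """Combine pairwise DE evidence, zero-expression sets and coverage classes.

    ``coverage`` is the long GeneCoverageTable (gene_id, strain, cov_class).
    A gene is off when it has significant pairwise DE and a nonempty,
    proper-subset zero-expression strain set. Genes absent from the coverage
    table get category ``uncertain_low_coverage`` and are logged.
    """
    cov_lookup = {(r.gene_id, r.strain): r.cov_class
                  for r in coverage.itertuples(index=False)}
    n_strains = len(strains)
    records = []
    for gene in sorted(pairwise_union):
        zs = zero_sets.get(gene, frozenset())
        if not zs or len(zs) >= n_strains:
            continue
        categories = {}
        for s in sorted(zs):
            cls = cov_lookup.get((gene, s))
            if cls is None:
                logger.warning("gene %s strain %s absent from coverage table; "
                               "categorised as uncertain", gene, s)
                categories[s] = "uncertain_low_coverage"
            else:
                categories[s] = _CLASS_TO_CATEGORY[cls]
        records.append(OffGeneRecord(
            gene_id=gene, off_strains=zs,
            evidence_strain_pairs=pairwise_union[gene],
            categories=categories,
        ))
    return records


def off_gene_summary(records: list[OffGeneRecord], strains: list) -> pd.DataFrame:
    """Per-strain counts of off genes split into the three categories."""
    rows = []
    for s in strains:
        counts = {c: 0 for c in OFF_CATEGORIES}
        for rec in records:
            if s in rec.off_strains:
                counts[rec.categories[s]] += 1
        rows.append({"strain": s, **counts,
                     "total_off": sum(counts.values())})
    return pd.DataFrame(rows)


def off_multiplicity(records: list[OffGeneRecord], n_strains: int) -> pd.Series:
    """Number of genes off in exactly 1, 2, ..., n_strains-1 strains."""
    counts = pd.Series(0, index=pd.RangeIndex(1, n_strains, name="n_off_strains"))
    for rec in records:
        counts[len(rec.off_strains)] += 1
    return counts


def rnai_responsive_off(records: list[OffGeneRecord],
                        contrasts: pd.DataFrame) -> list[OffGeneRecord]:
    """Flag off genes that respond to RNAi in a strain where they are expressed.

    ``contrasts`` is the concatenated within-strain Wald contrast table (one
    row per gene x strain x treatment with a ``call`` column). A record is
    responsive iff it has a DE call (up or down) in some strain NOT in its
    off set, for either RNAi treatment. Qualifying (strain, treatment,
    direction) triples are recorded.
    """
    sig = contrasts[contrasts["call"].isin(["up", "down"])]
    by_gene: dict = {}
    for r in sig.itertuples(index=False):
        by_gene.setdefault(r.gene_id, []).append((r.strain, r.treatment, r.call))
    for rec in records:
        hits = [h for h in by_gene.get(rec.gene_id, [])
                if h[0] not in rec.off_strains]
        rec.rnai_responsive = bool(hits)
        rec.responsive_contrasts = sorted(hits)
    return records


def records_to_frame(records: list[OffGeneRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        rows.append({
            "gene_id": rec.gene_id,
            "off_strains": ",".join(sorted(rec.off_strains)),
            "categories": ";".join(f"{s}={rec.categories[s]}"
                                   for s in sorted(rec.off_strains)),
            "evidence_pairs": ";".join(f"{a}|{b}" for a, b in
                                       sorted(rec.evidence_strain_pairs)),
            "rnai_responsive": rec.rnai_responsive,
            "responsive_contrasts": ";".join(
                f"{s}:{t}:{d}" for s, t, d in rec.responsive_contrasts),
        })
    return pd.DataFrame(rows, columns=["gene_id", "off_strains", "categories",
                                       "evidence_pairs", "rnai_responsive",
                                       "responsive_contrasts"])
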