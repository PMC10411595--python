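"""Synthetic multi-strain RNAi experiment generator with known ground truth.

Emulates a study design of 5 strains x 3 treatments (control plus 2 RNAi
treatments) x 3 replicates: NB-distributed counts assembled from planted
log2-scale strain, treatment and strain x treatment effects; structurally
"off" genes (expected count exactly 0 in some strains); a synthetic exon
annotation with multi-transcript overlap; and per-strain DNA-depth tracks
carrying planted missing- and low-coverage genes.

Counts are integer NB draws (so the NB likelihood the tests assume is exact),
off genes are structural zeros rather than small means, and per-sample depth
factors are log-uniform within a configured fold-spread. Every planted signal
is recorded in :class:`GroundTruth` so downstream calls can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SampleDesign
from .coverage import GeneAnnotation, merge_exons

DEFAULT_STRAINS = ("N2", "CB4856", "EG4348", "JU1088", "QX1211")
DEFAULT_TREATMENTS = ("control", "par1_rnai", "pos1_rnai")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    The first strain is the reference, the first treatment the control.
    ``effect_size_log2`` is the magnitude |beta| planted for DE and
    interaction genes. ``library_size_spread`` is the fold-range of the
    per-sample depth factors (log-uniform). ``off_mean_min`` floors the
    expressed-strain mean of off genes so a zero-vs-expressed contrast is
    well powered.
    """

    n_genes: int = 2000
    strains: tuple = DEFAULT_STRAINS
    treatments: tuple = DEFAULT_TREATMENTS
    n_replicates: int = 3
    baseline_mean_log2: float = 6.0
    baseline_sd_log2: float = 1.5
    dispersion_alpha: float = 0.05
    frac_strain_de: float = 0.34
    frac_interaction: float = 0.05
    frac_off: float = 0.026
    frac_missing_cov: float = 0.02
    frac_low_cov: float = 0.02
    effect_size_log2: float = 2.0
    library_size_spread: float = 3.0
    seed: int = 0
    # expressed-strain mean floor for off genes (counts)
    off_mean_min: float = 200.0
    # composition of planted coverage classes among off (gene, strain) calls
    # in nonreference strains; remainder is adequate (truly off)
    off_missing_frac: float = 0.25
    off_low_frac: float = 0.40
    # fraction of off genes also given an RNAi (interaction) effect in one
    # strain where they are expressed
    frac_off_responsive: float = 0.15
    # DNA depth model
    depth_mean: float = 30.0
    depth_strain_sd: float = 0.1
    cov_noise_sd: float = 0.1
    low_cov_target: float = 0.10
    # annotation model
    overlap_fraction: float = 0.5

    def validate(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be nonnegative")
        if len(self.strains) == 0:
            raise ValueError("strains must be a nonempty list")
        if len(self.treatments) == 0:
            raise ValueError("treatments must be a nonempty list")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")
        for name in ("frac_strain_de", "frac_interaction", "frac_off",
                     "frac_missing_cov", "frac_low_cov"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.frac_off > self.frac_strain_de:
            raise ValueError("frac_off must not exceed frac_strain_de "
                             "(off genes are a subset of strain-DE genes)")
        if self.effect_size_log2 <= 0:
            raise ValueError("effect_size_log2 must be positive")
        if self.library_size_spread <= 0:
            raise ValueError("library_size_spread must be positive")
        if np.isscalar(self.dispersion_alpha) and self.dispersion_alpha <= 0:
            raise ValueError("dispersion_alpha must be positive")

    @property
    def reference_strain(self) -> str:
        return self.strains[0]

    @property
    def control_treatment(self) -> str:
        return self.treatments[0]


@dataclass
class GroundTruth:
    """Planted per-gene parameters and labels.

    ``beta1``/``beta2``/``beta3`` are log2-scale effect tables (zero rows for
    genes without the corresponding signal). ``off_strains`` maps gene id to
    the set of strains where the expected count is structurally zero.
    ``coverage_class`` is genes x strains with values missing/low/adequate.
    """

    gene_ids: np.ndarray
    baseline_mean: np.ndarray            # linear-scale mu per gene
    alpha: np.ndarray                    # NB dispersion per gene
    beta1: pd.DataFrame                  # genes x nonreference strains (log2)
    beta2: pd.DataFrame                  # genes x noncontrol treatments (log2)
    beta3: pd.DataFrame                  # genes x "strain:treatment" cells (log2)
    off_strains: dict                    # gene_id -> frozenset of strains
    coverage_class: pd.DataFrame         # genes x strains
    size_factors: pd.Series = field(default=None)  # planted per-sample depth factors

    @property
    def is_strain_de(self) -> pd.Series:
        has_beta = (self.beta1 != 0).any(axis=1)
        has_off = pd.Series([g in self.off_strains for g in self.gene_ids],
                            index=self.beta1.index)
        return has_beta | has_off

    @property
    def is_interaction(self) -> pd.Series:
        return (self.beta3 != 0).any(axis=1)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame({"gene_id": self.gene_ids,
                           "baseline_mean": self.baseline_mean,
                           "alpha": self.alpha})
        df["off_strains"] = [",".join(sorted(self.off_strains.get(g, ()))) or "."
                             for g in self.gene_ids]
        df["strain_de"] = self.is_strain_de.to_numpy()
        df["interaction"] = self.is_interaction.to_numpy()
        for c in self.beta1.columns:
            df[f"beta1_{c}"] = self.beta1[c].to_numpy()
        for c in self.beta2.columns:
            df[f"beta2_{c}"] = self.beta2[c].to_numpy()
        for c in self.beta3.columns:
            df[f"beta3_{c}"] = self.beta3[c].to_numpy()
        for c in self.coverage_class.columns:
            df[f"cov_{c}"] = self.coverage_class[c].to_numpy()
        df.to_csv(path, sep="\t", index=False)


def _gene_alpha(config: SimulationConfig, rng, n: int) -> np.ndarray:
    rule = config.dispersion_alpha
    if callable(rule):
        return np.asarray(rule(rng, n), dtype=float)
    return np.full(n, float(rule))


def simulate_experiment(config: SimulationConfig
                        ) -> tuple[ExpressionMatrix, SampleDesign, GroundTruth]:
    """Draw a full synthetic experiment: counts, sample sheet, ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    strains = list(config.strains)
    treatments = list(config.treatments)
    nonref = strains[1:]
    nonctl = treatments[1:]
    gene_ids = np.array([f"gene{i:05d}" for i in range(n)], dtype=object)

    # sample sheet
    rows, sample_ids = [], []
    for s in strains:
        for t in treatments:
            for r in range(1, config.n_replicates + 1):
                sample_ids.append(f"{s}_{t}_r{r}")
                rows.append({"strain": s, "treatment": t, "replicate": r})
    samples = pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample"))
    design = SampleDesign(samples, config.reference_strain, config.control_treatment)

    # per-gene baseline and dispersion
    base_log2 = rng.normal(config.baseline_mean_log2, config.baseline_sd_log2, size=n)
    alpha = _gene_alpha(config, rng, n)

    # planted effect tables (log2)
    beta1 = pd.DataFrame(0.0, index=gene_ids, columns=nonref)
    beta2 = pd.DataFrame(0.0, index=gene_ids, columns=nonctl)
    int_cols = [f"{s}:{t}" for s in nonref for t in nonctl]
    beta3 = pd.DataFrame(0.0, index=gene_ids, columns=int_cols)

    n_de = int(round(config.frac_strain_de * n))
    n_off = int(round(config.frac_off * n))
    n_int = int(round(config.frac_interaction * n))
    de_idx = rng.choice(n, size=n_de, replace=False) if n_de else np.array([], int)
    off_idx = de_idx[:n_off]
    de_only_idx = de_idx[n_off:]

    eff = config.effect_size_log2
    for i in de_only_idx:
        if not nonref:
            break
        k = 1 + rng.binomial(len(nonref) - 1, 0.3) if len(nonref) > 1 else 1
        which = rng.choice(len(nonref), size=k, replace=False)
        signs = rng.choice([-1.0, 1.0], size=k)
        for w, sg in zip(which, signs):
            beta1.iloc[i, w] = sg * eff

    # off genes: structural zeros in a nonempty proper subset of strains,
    # expressed strains share a mean floored at off_mean_min
    off_strains: dict = {}
    if len(strains) > 1:
        max_off = len(strains) - 1
        m_probs = np.array([0.6, 0.25, 0.1, 0.05][:max_off], dtype=float)
        m_probs /= m_probs.sum()
        for i in off_idx:
            m = rng.choice(np.arange(1, max_off + 1), p=m_probs)
            chosen = rng.choice(len(strains), size=m, replace=False)
            off = frozenset(strains[c] for c in chosen)
            off_strains[gene_ids[i]] = off
            base_log2[i] = max(base_log2[i], np.log2(config.off_mean_min))
            expressed_nonref = [s for s in nonref if s not in off]
            if expressed_nonref and nonctl \
                    and rng.random() < config.frac_off_responsive:
                s = expressed_nonref[int(rng.integers(len(expressed_nonref)))]
                t = nonctl[int(rng.integers(len(nonctl)))]
                beta3.loc[gene_ids[i], f"{s}:{t}"] = \
                    float(rng.choice([-1.0, 1.0])) * eff

    int_pool = np.setdiff1d(np.arange(n), off_idx)
    int_idx = rng.choice(int_pool, size=min(n_int, len(int_pool)), replace=False) \
        if n_int else np.array([], int)
    for i in int_idx:
        if not nonref or not nonctl:
            break
        s = nonref[rng.integers(len(nonref))]
        t = nonctl[rng.integers(len(nonctl))]
        beta3.loc[gene_ids[i], f"{s}:{t}"] = rng.choice([-1.0, 1.0]) * eff

    # per-sample depth factors, log-uniform within the configured fold-spread
    half = 0.5 * np.log(config.library_size_spread)
    sfac = np.exp(rng.uniform(-half, half, size=len(sample_ids)))
    sfac = pd.Series(sfac, index=sample_ids, name="size_factor")

    # expected counts and NB draws
    strain_of = samples["strain"].to_numpy()
    treat_of = samples["treatment"].to_numpy()
    log2q = np.tile(base_log2[:, None], (1, len(sample_ids)))
    for j in range(len(sample_ids)):
        s, t = strain_of[j], treat_of[j]
        if s != config.reference_strain:
            log2q[:, j] += beta1[s].to_numpy()
        if t != config.control_treatment:
            log2q[:, j] += beta2[t].to_numpy()
            if s != config.reference_strain:
                log2q[:, j] += beta3[f"{s}:{t}"].to_numpy()
    mu = sfac.to_numpy()[None, :] * np.exp2(log2q)
    for g, off in off_strains.items():
        i = int(np.flatnonzero(gene_ids == g)[0])
        mu[i, np.isin(strain_of, list(off))] = 0.0

    counts = np.zeros_like(mu)
    pos = mu > 0
    a = np.tile(alpha[:, None], (1, mu.shape[1]))
    poisson_like = a < 1e-7
    draw_nb = pos & ~poisson_like
    draw_po = pos & poisson_like
    if np.any(draw_nb):
        r = 1.0 / a[draw_nb]
        p = r / (r + mu[draw_nb])
        counts[draw_nb] = rng.negative_binomial(r, p)
    if np.any(draw_po):
        counts[draw_po] = rng.poisson(mu[draw_po])

    # planted DNA-coverage classes per (gene, strain)
    cov = pd.DataFrame("adequate", index=gene_ids, columns=strains)
    noff_strains = strains[1:] if len(strains) > 1 else strains
    for g, off in off_strains.items():
        for s in off:
            if s == config.reference_strain:
                continue  # reference mapped to itself: coverage always adequate
            u = rng.random()
            if u < config.off_missing_frac:
                cov.loc[g, s] = "missing"
            elif u < config.off_missing_frac + config.off_low_frac:
                cov.loc[g, s] = "low"
    # background missing/low genes independent of expression
    free = [g for g in gene_ids if g not in off_strains]
    n_miss = int(round(config.frac_missing_cov * n))
    n_low = int(round(config.frac_low_cov * n))
    if noff_strains and free:
        pick = rng.choice(len(free), size=min(n_miss + n_low, len(free)), replace=False)
        for rank, gi in enumerate(pick):
            s = noff_strains[rng.integers(len(noff_strains))]
            cov.loc[free[gi], s] = "missing" if rank < n_miss else "low"

    truth = GroundTruth(
        gene_ids=gene_ids, baseline_mean=np.exp2(base_log2), alpha=alpha,
        beta1=beta1, beta2=beta2, beta3=beta3, off_strains=off_strains,
        coverage_class=cov, size_factors=sfac,
    )
    matrix = ExpressionMatrix(gene_ids, np.array(sample_ids, dtype=object),
                              counts.astype(np.int64))
    return matrix, design, truth


def simulate_annotation(config: SimulationConfig) -> GeneAnnotation:
    """Lay genes with 1-5 exons along a synthetic chromosome.

    A fraction ``overlap_fraction`` of genes gets a second transcript whose
    records duplicate and partially overlap the first transcript's exons, to
    exercise merging. Coordinates are 1-based inclusive (GTF convention).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 17])
    rows = []
    pos = 1000
    chrom = "chrS"
    for i in range(config.n_genes):
        gene = f"gene{i:05d}"
        n_exons = int(rng.integers(1, 6))
        exons = []
        start = pos
        for _ in range(n_exons):
            length = int(rng.integers(50, 301))
            exons.append((start, start + length - 1))
            start = start + length + int(rng.integers(20, 201))
        strand = "+" if rng.random() < 0.5 else "-"
        for (s, e) in exons:
            rows.append({"gene_id": gene, "transcript_id": f"{gene}.t1",
                         "chrom": chrom, "strand": strand, "start": s, "end": e})
        if rng.random() < config.overlap_fraction:
            s0, e0 = exons[0]
            rows.append({"gene_id": gene, "transcript_id": f"{gene}.t2",
                         "chrom": chrom, "strand": strand, "start": s0, "end": e0})
            shift = int(rng.integers(0, (e0 - s0) + 1))
            rows.append({"gene_id": gene, "transcript_id": f"{gene}.t2",
                         "chrom": chrom, "strand": strand,
                         "start": s0 + shift, "end": e0 + shift})
        pos = exons[-1][1] + int(rng.integers(300, 1001))
    length = pos + 1000
    df = pd.DataFrame(rows, columns=["gene_id", "transcript_id", "chrom",
                                     "strand", "start", "end"])
    return GeneAnnotation(df, chrom_lengths={chrom: length})


def simulate_coverage(annotation: GeneAnnotation, truth: GroundTruth,
                      config: SimulationConfig) -> dict:
    """Per-strain BED-style depth tables over the annotation's merged exons.

    Genes planted ``missing`` get depth exactly 0 on every interval; genes
    planted ``low`` are scaled so their median-normalised coverage sits near
    ``low_cov_target`` (inside (0, 0.25)); all others fluctuate around the
    strain depth. Returns {strain: DataFrame(chrom, start, end, mean_depth)}
    with 0-based half-open intervals.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 29])
    merged = merge_exons(annotation)
    annotated = set(merged.gene_ids)
    for g in truth.gene_ids:
        if g not in annotated:
            raise ValueError(f"gene {g} in ground truth is absent from the annotation")
    out = {}
    for strain in truth.coverage_class.columns:
        strain_depth = config.depth_mean * float(
            np.exp(rng.normal(0.0, config.depth_strain_sd)))
        rows = []
        for g in truth.gene_ids:
            cls = truth.coverage_class.loc[g, strain]
            ivs = merged.intervals[g]
            if cls == "missing":
                depths = np.zeros(len(ivs))
            else:
                noise = (np.exp(rng.normal(0.0, config.cov_noise_sd, size=len(ivs)))
                         if config.cov_noise_sd > 0 else np.ones(len(ivs)))
                depths = strain_depth * noise
                if cls == "low":
                    depths = depths * config.low_cov_target
            for (s, e), d in zip(ivs, depths):
                rows.append((merged.chrom[g], int(s), int(e), float(d)))
        out[strain] = pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_depth"])
    return out


def write_bundle(outdir, matrix: ExpressionMatrix, design: SampleDesign,
                 truth: GroundTruth, annotation: GeneAnnotation | None = None,
                 depth: dict | None = None) -> None:
    """Write the synthetic experiment as plain-text files under ``outdir``."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix.to_tsv(outdir / "counts.tsv")
    design.to_tsv(outdir / "samples.tsv")
    truth.to_tsv(outdir / "truth.tsv")
    if annotation is not None:
        annotation.to_gtf(outdir / "annotation.gtf")
    if depth is not None:
        for strain, df in depth.items():
            df.to_csv(outdir / f"depth_{strain}.tsv", sep="\t",
                      index=False, header=False)
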