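"""DNA-coverage reference-bias screen.

Low or absent DNA sequencing coverage of a gene in a nonreference strain is a
warning sign that apparent expression differences may reflect read-mapping
failure (reference bias) rather than biology. This module builds per-gene
merged exons from an annotation, computes the length-weighted mean depth over
those exons,

    coverage = sum(depth_per_merged_exon * merged_exon_length)
               / sum(merged_exon_length),

median-normalises within each strain, and classifies every (gene, strain) as

* ``missing``  — raw coverage exactly 0,
* ``low``      — raw > 0 but median-normalised coverage < 0.25,
* ``adequate`` — everything else (normalised 0.25 counts as adequate; the
  threshold is strict).

Coordinates: GTF exons are 1-based inclusive; merged exons and depth records
are 0-based half-open. Depth files are expected to already exclude unmapped,
duplicate and QC-fail reads upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COVERAGE_CLASSES = ("missing", "low", "adequate")
LOW_COVERAGE_THRESHOLD = 0.25


@dataclass
class GeneAnnotation:
    """Exon records per gene, 1-based inclusive as read from GTF."""

    exons: pd.DataFrame  # columns: gene_id, transcript_id, chrom, strand, start, end
    chrom_lengths: dict = field(default_factory=dict)

    def __post_init__(self):
        required = {"gene_id", "transcript_id", "chrom", "strand", "start", "end"}
        missing = required - set(self.exons.columns)
        if missing:
            raise ValueError(f"annotation lacks columns: {sorted(missing)}")

    @property
    def gene_ids(self) -> np.ndarray:
        return pd.unique(self.exons["gene_id"])

    @classmethod
    def from_gtf(cls, path) -> "GeneAnnotation":
        import gffutils

        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True, disable_infer_transcripts=True,
        )
        rows = []
        for feat in db.features_of_type("exon", order_by=("seqid", "start")):
            rows.append({
                "gene_id": feat.attributes["gene_id"][0],
                "transcript_id": feat.attributes.get("transcript_id", [""])[0],
                "chrom": feat.seqid,
                "strand": feat.strand,
                "start": feat.start,
                "end": feat.end,
            })
        return cls(pd.DataFrame(rows))

    def to_gtf(self, path, source: str = "strainexpr") -> None:
        with open(path, "w") as fh:
            for row in self.exons.itertuples(index=False):
                attrs = f'gene_id "{row.gene_id}"; transcript_id "{row.transcript_id}";'
                fh.write(
                    f"{row.chrom}\t{source}\texon\t{row.start}\t{row.end}\t.\t"
                    f"{row.strand}\t.\t{attrs}\n"
                )


@dataclass
class MergedExonSet:
    """Per-gene sorted, disjoint exon intervals (0-based half-open)."""

    intervals: dict       # gene_id -> (k, 2) int array of [start, end)
    chrom: dict           # gene_id -> chromosome
    total_length: dict    # gene_id -> int

    @property
    def gene_ids(self) -> list:
        return list(self.intervals)

    def to_bed(self, path) -> None:
        rows = []
        for gene, ivs in self.intervals.items():
            for s, e in ivs:
                rows.append((self.chrom[gene], s, e, gene))
        pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"]) \
            .to_csv(path, sep="\t", index=False, header=False)


def merge_exons(annotation: GeneAnnotation) -> MergedExonSet:
    """Union of each gene's exon intervals across transcripts.

    Duplicated records collapse; overlapping or book-ended intervals coalesce.
    Input coordinates are 1-based inclusive; output is 0-based half-open
    (start-1, end).
    """
    bad = annotation.exons["start"] > annotation.exons["end"]
    if bad.any():
        row = annotation.exons[bad].iloc[0]
        raise ValueError(
            f"inverted exon interval ({row.start}, {row.end}) in gene {row.gene_id}"
        )
    intervals, chroms, lengths = {}, {}, {}
    for gene, grp in annotation.exons.groupby("gene_id", sort=False):
        iv = np.column_stack([grp["start"].to_numpy() - 1, grp["end"].to_numpy()])
        iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
        merged = []
        cur_s, cur_e = iv[0]
        for s, e in iv[1:]:
            if s <= cur_e:  # overlap or adjacency
                cur_e = max(cur_e, e)
            else:
                merged.append((cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((cur_s, cur_e))
        arr = np.array(merged, dtype=int)
        intervals[gene] = arr
        chroms[gene] = grp["chrom"].iloc[0]
        lengths[gene] = int(np.sum(arr[:, 1] - arr[:, 0]))
    return MergedExonSet(intervals, chroms, lengths)


def _depth_arrays(depth: pd.DataFrame) -> dict:
    """Index depth records by chromosome as sorted (starts, ends, depths)."""
    if {"chrom", "start", "end", "mean_depth"} <= set(depth.columns):
        df = depth
    elif {"chrom", "pos", "depth"} <= set(depth.columns):
        df = pd.DataFrame({
            "chrom": depth["chrom"],
            "start": depth["pos"],
            "end": depth["pos"] + 1,
            "mean_depth": depth["depth"],
        })
    else:
        raise ValueError(
            "depth table needs columns (chrom, start, end, mean_depth) or "
            "(chrom, pos, depth)"
        )
    out = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        g = grp.sort_values("start")
        out[chrom] = (
            g["start"].to_numpy(dtype=int),
            g["end"].to_numpy(dtype=int),
            g["mean_depth"].to_numpy(dtype=float),
        )
    return out


def gene_coverage(merged: MergedExonSet, depth: pd.DataFrame) -> pd.Series:
    """Length-weighted mean depth over each gene's merged exons.

    ``depth`` is a BED-style table (chrom, start, end, mean_depth; 0-based
    half-open, records non-overlapping within a chromosome) or a per-base
    table (chrom, pos, depth). Depth records partially overlapping a merged
    exon are intersected; any merged base with no depth record raises, listing
    the gap, rather than being silently zero-filled.
    """
    by_chrom = _depth_arrays(depth)
    result = {}
    for gene, ivs in merged.intervals.items():
        chrom = merged.chrom[gene]
        if chrom not in by_chrom:
            raise ValueError(f"no depth records on {chrom} (gene {gene})")
        starts, ends, depths = by_chrom[chrom]
        weighted = 0.0
        total = 0
        for s, e in ivs:
            lo = np.searchsorted(ends, s, side="right")
            hi = np.searchsorted(starts, e, side="left")
            covered = 0
            for i in range(lo, hi):
                os_, oe = max(starts[i], s), min(ends[i], e)
                if oe > os_:
                    weighted += depths[i] * (oe - os_)
                    covered += oe - os_
            if covered < e - s:
                raise ValueError(
                    f"gene {gene}: merged exon {chrom}:{s}-{e} has "
                    f"{e - s - covered} bases with no depth record"
                )
            total += e - s
        result[gene] = weighted / total
    return pd.Series(result, name="raw_cov").rename_axis("gene_id")


def classify_coverage(raw_by_strain: pd.DataFrame,
                      low_threshold: float = LOW_COVERAGE_THRESHOLD) -> pd.DataFrame:
    """Median-normalise within strain and classify each (gene, strain).

    ``raw_by_strain``: genes x strains raw coverage. The within-strain median
    is taken over all genes, zeros included. Returns a long DataFrame with
    columns gene_id, strain, raw_cov, norm_cov, cov_class.
    """
    rows = []
    for strain in raw_by_strain.columns:
        raw = raw_by_strain[strain].to_numpy(dtype=float)
        med = np.median(raw)
        if med <= 0:
            raise ValueError(
                f"strain {strain}: median coverage is 0, normalisation undefined"
            )
        norm = raw / med
        cls = np.where(raw == 0, "missing",
                       np.where(norm < low_threshold, "low", "adequate"))
        rows.append(pd.DataFrame({
            "gene_id": raw_by_strain.index,
            "strain": strain,
            "raw_cov": raw,
            "norm_cov": norm,
            "cov_class": cls,
        }))
    return pd.concat(rows, ignore_index=True)
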