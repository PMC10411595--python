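"""Core data containers: the count matrix and the sample design.

Both are thin wrappers over pandas/numpy with the invariants the analysis
relies on (unique ids, nonnegative counts, declared reference levels) checked
at construction, plus TSV round-trip I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """Gene x sample estimated-count table.

    counts[i, j] is the estimated read count for gene ``gene_ids[i]`` in
    sample ``sample_ids[j]``. Counts may be fractional (pseudoalignment
    estimates) but never negative.
    """

    gene_ids: np.ndarray
    sample_ids: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.counts = np.asarray(self.counts)
        if self.counts.dtype == object or not np.issubdtype(self.counts.dtype, np.number):
            self.counts = self.counts.astype(float)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids are not unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids are not unique")
        if self.counts.size and np.min(self.counts) < 0:
            raise ValueError("counts contain negative entries")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_genes(self, mask_or_ids) -> "ExpressionMatrix":
        mask = np.asarray(mask_or_ids)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            pos = {g: i for i, g in enumerate(self.gene_ids)}
            idx = np.array([pos[g] for g in mask_or_ids], dtype=int)
        return ExpressionMatrix(self.gene_ids[idx], self.sample_ids, self.counts[idx])

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in sample_ids], dtype=int)
        return ExpressionMatrix(self.gene_ids, self.sample_ids[idx], self.counts[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.gene_ids, name="gene_id"),
                            columns=list(self.sample_ids))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, gene_column: str = "gene_id") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t")
        if gene_column not in df.columns:
            raise ValueError(f"counts file lacks a '{gene_column}' column")
        df = df.set_index(gene_column)
        return cls(df.index.to_numpy(), df.columns.to_numpy(), df.to_numpy())


@dataclass
class SampleDesign:
    """Per-sample strain / treatment / replicate labels with reference levels."""

    samples: pd.DataFrame  # index: sample id; columns strain, treatment, replicate
    reference_strain: str
    control_treatment: str

    def __post_init__(self):
        required = {"strain", "treatment", "replicate"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValueError(f"sample sheet lacks columns: {sorted(missing)}")
        if self.samples.index.duplicated().any():
            raise ValueError("duplicate sample ids in sample sheet")
        if self.reference_strain not in set(self.samples["strain"]):
            raise ValueError(f"reference strain {self.reference_strain!r} has no samples")
        if self.control_treatment not in set(self.samples["treatment"]):
            raise ValueError(f"control treatment {self.control_treatment!r} has no samples")

    @property
    def sample_ids(self) -> np.ndarray:
        return self.samples.index.to_numpy()

    @property
    def strains(self) -> list:
        """Strain labels, reference first, then the rest in sheet order."""
        rest = [s for s in pd.unique(self.samples["strain"]) if s != self.reference_strain]
        return [self.reference_strain] + rest

    @property
    def treatments(self) -> list:
        rest = [t for t in pd.unique(self.samples["treatment"]) if t != self.control_treatment]
        return [self.control_treatment] + rest

    def subset(self, sample_ids) -> "SampleDesign":
        sub = self.samples.loc[list(sample_ids)]
        ref = self.reference_strain if self.reference_strain in set(sub["strain"]) \
            else pd.unique(sub["strain"])[0]
        ctl = self.control_treatment if self.control_treatment in set(sub["treatment"]) \
            else pd.unique(sub["treatment"])[0]
        return SampleDesign(sub, ref, ctl)

    def control_samples(self) -> np.ndarray:
        mask = self.samples["treatment"] == self.control_treatment
        return self.samples.index[mask].to_numpy()

    def design_matrix(self, terms: list[str]) -> tuple[np.ndarray, list[str]]:
        """Build a reference-coded design matrix for the given terms.

        Allowed terms: ``"strain"``, ``"treatment"``, ``"strain:treatment"``.
        An intercept column is always included. Returns (X, column_names).
        """
        n = len(self.samples)
        cols = [np.ones(n)]
        names = ["intercept"]
        strain = self.samples["strain"].to_numpy()
        treat = self.samples["treatment"].to_numpy()
        nonref_strains = [s for s in self.strains if s != self.reference_strain]
        nonctl_treats = [t for t in self.treatments if t != self.control_treatment]
        for term in terms:
            if term == "strain":
                for s in nonref_strains:
                    cols.append((strain == s).astype(float))
                    names.append(f"strain[{s}]")
            elif term == "treatment":
                for t in nonctl_treats:
                    cols.append((treat == t).astype(float))
                    names.append(f"treatment[{t}]")
            elif term == "strain:treatment":
                for s in nonref_strains:
                    for t in nonctl_treats:
                        cols.append(((strain == s) & (treat == t)).astype(float))
                        names.append(f"strain[{s}]:treatment[{t}]")
            else:
                raise ValueError(f"unknown design term: {term!r}")
        return np.column_stack(cols), names

    def to_tsv(self, path) -> None:
        out = self.samples.copy()
        out.index.name = "sample"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, reference_strain: str, control_treatment: str,
                 sample_column: str = "sample") -> "SampleDesign":
        df = pd.read_csv(path, sep="\t")
        if sample_column not in df.columns:
            raise ValueError(f"sample sheet lacks a '{sample_column}' column")
        df = df.set_index(sample_column)
        return cls(df, reference_strain, control_treatment)
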