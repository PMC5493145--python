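"""Core in-memory containers for the multi-omics pipeline.

All feature matrices are thin, validated wrappers around a pandas DataFrame
with features on the rows and samples on the columns.  Expression values are
log2-scale, methylation values are beta fractions in [0, 1], and copy-number
values are log-ratios relative to a diploid baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ExpressionMatrix",
    "MethylationMatrix",
    "CopyNumberMatrix",
    "MutationTable",
    "ClusterAssignment",
    "DiscriminantGeneSet",
    "MUTATION_COLUMNS",
    "EFFECT_CLASSES",
    "CONTEXT_PATTERN",
]


class ValidationError(ValueError):
    """Raised when an on-disk artifact or in-memory container is malformed."""


def _check_unique(index: pd.Index, what: str, where: str) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"{where}: duplicate {what}: {dupes}")


def _check_finite(values: pd.DataFrame, where: str) -> None:
    arr = values.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValidationError(f"{where}: non-numeric values present")
    if not np.isfinite(arr).all():
        bad = np.argwhere(~np.isfinite(arr))[0]
        raise ValidationError(
            f"{where}: non-finite value at feature "
            f"{values.index[bad[0]]!r}, sample {values.columns[bad[1]]!r}"
        )


@dataclass
class ExpressionMatrix:
    """Gene x sample log2-scale expression matrix."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene symbols", "expression matrix")
        _check_unique(self.values.columns, "sample IDs", "expression matrix")
        _check_finite(self.values, "expression matrix")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset_genes(self, genes) -> "ExpressionMatrix":
        keep = self.values.index.intersection(pd.Index(genes))
        return ExpressionMatrix(self.values.loc[keep])


#: required columns of the probe annotation table
PROBE_ANNOTATION_COLUMNS = ("gene", "promoter", "chrom", "pos")


@dataclass
class MethylationMatrix:
    """Probe x sample beta-value matrix with per-probe promoter annotation.

    ``probe_annotation`` maps every probe to a gene symbol, a promoter flag,
    and a 0-based genomic coordinate.
    """

    betas: pd.DataFrame
    probe_annotation: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.betas.index, "probe IDs", "methylation matrix")
        _check_unique(self.betas.columns, "sample IDs", "methylation matrix")
        _check_finite(self.betas, "methylation matrix")
        arr = self.betas.to_numpy()
        if (arr < 0).any() or (arr > 1).any():
            bad = np.argwhere((arr < 0) | (arr > 1))[0]
            raise ValidationError(
                f"methylation matrix: beta out of [0, 1] at probe "
                f"{self.betas.index[bad[0]]!r}, sample {self.betas.columns[bad[1]]!r}"
            )
        missing = [c for c in PROBE_ANNOTATION_COLUMNS if c not in self.probe_annotation.columns]
        if missing:
            raise ValidationError(f"probe annotation: missing columns {missing}")
        unannotated = self.betas.index.difference(self.probe_annotation.index)
        if len(unannotated):
            raise ValidationError(
                f"probe annotation: probes without annotation: {unannotated.tolist()[:5]}"
            )

    @property
    def probes(self) -> pd.Index:
        return self.betas.index

    @property
    def samples(self) -> pd.Index:
        return self.betas.columns

    def promoter_probes(self, gene: str) -> list[str]:
        ann = self.probe_annotation
        mask = (ann["gene"] == gene) & ann["promoter"].astype(bool)
        return ann.index[mask].intersection(self.betas.index).tolist()


#: SEG source-table columns (internal convention: 0-based half-open intervals)
SEGMENT_COLUMNS = ("sample", "chrom", "start", "end", "n_probes", "log_ratio")


@dataclass
class CopyNumberMatrix:
    """Locus x sample copy-number log-ratio matrix.

    Loci may be genes, cytobands, or chromosome arms; an optional segment
    table retains the SEG-style source records.
    """

    values: pd.DataFrame
    segments: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "locus labels", "copy-number matrix")
        _check_unique(self.values.columns, "sample IDs", "copy-number matrix")
        _check_finite(self.values, "copy-number matrix")
        if self.segments is not None:
            missing = [c for c in SEGMENT_COLUMNS if c not in self.segments.columns]
            if missing:
                raise ValidationError(f"segment table: missing columns {missing}")
            bad = self.segments[self.segments["start"] >= self.segments["end"]]
            if len(bad):
                raise ValidationError(
                    f"segment table: start >= end in {len(bad)} rows "
                    f"(first: {bad.iloc[0].to_dict()})"
                )

    @property
    def loci(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


MUTATION_COLUMNS = ("sample", "gene", "protein_change", "effect_class", "context")
EFFECT_CLASSES = frozenset({"silent", "non-silent"})
CONTEXT_PATTERN = r"^[ACGT]\[[ACGT]>[ACGT]\][ACGT]$"


@dataclass
class MutationTable:
    """MAF-like somatic mutation records.

    One row per mutation with sample, gene, protein change, effect class
    (silent / non-silent) and the trinucleotide context in ``A[C>T]G`` form.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MUTATION_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValidationError(f"mutation table: missing columns {missing}")
        if len(self.records):
            bad_class = set(self.records["effect_class"]) - EFFECT_CLASSES
            if bad_class:
                raise ValidationError(
                    f"mutation table: unknown effect classes {sorted(bad_class)}"
                )
            ok = self.records["context"].astype(str).str.match(CONTEXT_PATTERN)
            if not ok.all():
                first = self.records.loc[~ok, "context"].iloc[0]
                raise ValidationError(
                    f"mutation table: malformed trinucleotide context {first!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def samples(self) -> pd.Index:
        return pd.Index(self.records["sample"].unique())

    def per_sample_counts(self, samples=None) -> pd.Series:
        counts = self.records.groupby("sample").size()
        if samples is not None:
            counts = counts.reindex(samples, fill_value=0)
        return counts

    def context_counts(self, contexts=None) -> pd.Series:
        counts = self.records.groupby("context").size()
        if contexts is not None:
            counts = counts.reindex(contexts, fill_value=0)
        return counts

    def mutated_samples(self, gene: str, non_silent_only: bool = True) -> set[str]:
        rec = self.records[self.records["gene"] == gene]
        if non_silent_only:
            rec = rec[rec["effect_class"] == "non-silent"]
        return set(rec["sample"])


@dataclass
class ClusterAssignment:
    """A per-platform sample partition with robustness scores.

    Labels are integers in ``1..k``; robustness is a per-sample score in
    [0, 1] (rescaled silhouette width) expressing strength of cluster
    membership.
    """

    platform: str
    labels: pd.Series
    robustness: pd.Series
    k: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(int)
        if len(self.labels) == 0:
            raise ValidationError("cluster assignment: no samples")
        lab = set(self.labels)
        if not lab <= set(range(1, self.k + 1)):
            raise ValidationError(
                f"cluster assignment: labels {sorted(lab)} outside 1..{self.k}"
            )
        if not self.robustness.index.equals(self.labels.index):
            self.robustness = self.robustness.reindex(self.labels.index)
        rob = self.robustness.to_numpy(dtype=float)
        if np.isfinite(rob).all() and ((rob < -1e-9) | (rob > 1 + 1e-9)).any():
            raise ValidationError("cluster assignment: robustness outside [0, 1]")

    @property
    def samples(self) -> pd.Index:
        return self.labels.index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.labels.index,
                "platform": self.platform,
                "cluster": self.labels.to_numpy(),
                "robustness": self.robustness.to_numpy(),
            }
        )


@dataclass
class DiscriminantGeneSet:
    """Genes ranked by how strongly they separate expression clusters.

    ``weights`` is ordered by decreasing |weight|; ``origin`` records, per
    gene, the cluster contrast contributing its maximal loading.
    """

    weights: pd.Series
    origin: pd.Series

    def __post_init__(self) -> None:
        order = self.weights.abs().sort_values(ascending=False, kind="stable").index
        self.weights = self.weights.loc[order]
        self.origin = self.origin.reindex(order)

    @property
    def genes(self) -> pd.Index:
        return self.weights.index

    def top(self, n: int) -> "DiscriminantGeneSet":
        return DiscriminantGeneSet(self.weights.iloc[:n].copy(), self.origin.iloc[:n].copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.weights.index, "weight": self.weights.to_numpy(),
             "origin": self.origin.to_numpy()}
        )
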