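"""Tissue-specific gene derivation and stromal-signature filtering.

Bulk tumor expression from organs with a highly specialized parenchyma is
confounded by admixed normal tissue: a handful of genes expressed orders of
magnitude higher in the normal organ than in tumor cells inherit the
sample-to-sample variation of the contamination fraction and crowd out tumor
biology from any most-variable-gene selection.  The remedy implemented here
is to derive the organ-specific gene list from a normal-tissue expression
compendium and remove those genes outright before clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrices import ExpressionMatrix, ValidationError

__all__ = ["TissueGeneList", "derive_tissue_specific_genes", "filter_genes"]


@dataclass
class TissueGeneList:
    """Genes specific to one tissue, with their linear specificity folds."""

    tissue: str
    folds: pd.Series  # gene -> linear fold over max of other tissues, descending

    def __post_init__(self) -> None:
        self.folds = self.folds.sort_values(ascending=False, kind="stable")

    @property
    def genes(self) -> pd.Index:
        return self.folds.index

    def __len__(self) -> int:
        return len(self.folds)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.folds.index, "fold": self.folds.to_numpy()})


def derive_tissue_specific_genes(
    compendium: pd.DataFrame,
    tissue: str,
    min_fold: float = 50.0,
    min_level: float = 1.0,
) -> TissueGeneList:
    """Select genes specific to ``tissue`` from a log2 median-expression
    compendium (genes x tissues).

    A gene qualifies when its linear expression in the target tissue is at
    least ``min_fold`` times the maximum across all other tissues (inclusive
    boundary) and its linear target-tissue level is at least ``min_level``.
    """
    if tissue not in compendium.columns:
        raise ValidationError(
            f"tissue {tissue!r} not in compendium (have {list(compendium.columns)})"
        )
    if compendium.shape[1] < 2:
        raise ValidationError("compendium needs at least 2 tissues")
    if not np.isfinite(compendium.to_numpy()).all():
        raise ValidationError("compendium contains non-finite values")
    target = np.power(2.0, compendium[tissue])
    others = np.power(2.0, compendium.drop(columns=[tissue])).max(axis=1)
    fold = target / others
    keep = (fold >= min_fold) & (target >= min_level)
    return TissueGeneList(tissue, fold[keep])


def filter_genes(expr: ExpressionMatrix, gene_list: TissueGeneList) -> ExpressionMatrix:
    """Drop every gene on the tissue list from the expression matrix.

    The sample set is unchanged; a list disjoint from the matrix is a no-op.
    """
    keep = expr.genes.difference(gene_list.genes, sort=False)
    return ExpressionMatrix(expr.values.loc[keep])
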