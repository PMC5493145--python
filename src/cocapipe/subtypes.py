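"""Expression-based subtype discovery.

Variance filtering, hierarchical and PCA-space clustering with per-sample
robustness (rescaled silhouette widths), OPLS-DA discriminant gene ranking,
and transfer of a cluster solution onto an external dataset through the
shared discriminant genes.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import silhouette_samples

from .matrices import (
    ClusterAssignment,
    DiscriminantGeneSet,
    ExpressionMatrix,
    ValidationError,
)

__all__ = [
    "select_top_variable",
    "sample_distance",
    "hierarchical_cluster",
    "pca_cluster",
    "discriminant_genes",
    "transfer_clusters",
]


def select_top_variable(expr: ExpressionMatrix, fraction: float) -> ExpressionMatrix:
    """Keep the ``ceil(fraction * n_genes)`` genes of highest variance.

    Variance is computed on the log2 values across samples; ties are broken
    by gene-symbol lexicographic order so the selection is deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    n_keep = math.ceil(fraction * len(expr.genes))
    var = expr.values.var(axis=1, ddof=1)
    order = pd.DataFrame({"var": var, "gene": var.index}).sort_values(
        ["var", "gene"], ascending=[False, True], kind="stable"
    )
    keep = order.index[:n_keep]
    return ExpressionMatrix(expr.values.loc[keep])


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, ExpressionMatrix):
        return matrix.values
    if isinstance(matrix, pd.DataFrame):
        return matrix
    raise TypeError(f"expected feature x sample frame, got {type(matrix).__name__}")


def sample_distance(frame: pd.DataFrame, metric: str = "pearson") -> pd.DataFrame:
    """Pairwise sample distance: ``1 - Pearson`` correlation or Euclidean."""
    if metric == "pearson":
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(frame.to_numpy().T)
        corr = np.nan_to_num(corr, nan=0.0)
        dist = 1.0 - corr
    elif metric == "euclidean":
        dist = ssd.squareform(ssd.pdist(frame.to_numpy().T, metric="euclidean"))
    else:
        raise ValidationError(f"unknown distance metric {metric!r}")
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(dist, 0.0)
    return pd.DataFrame(dist, index=frame.columns, columns=frame.columns)


def _relabel_first_occurrence(raw: np.ndarray) -> np.ndarray:
    """Map arbitrary cluster codes to 1..k in order of first appearance."""
    mapping: dict = {}
    out = np.empty_like(raw)
    for i, c in enumerate(raw):
        if c not in mapping:
            mapping[c] = len(mapping) + 1
        out[i] = mapping[c]
    return out


def _silhouette_robustness(dist: pd.DataFrame, labels: np.ndarray) -> np.ndarray:
    """Per-sample silhouette on a precomputed distance, rescaled to [0, 1]."""
    n = len(labels)
    k = len(set(labels))
    if k < 2 or k >= n:
        return np.ones(n)
    sil = silhouette_samples(dist.to_numpy(), labels, metric="precomputed")
    return (sil + 1.0) / 2.0


def hierarchical_cluster(
    matrix,
    k: int,
    linkage: str = "ward",
    distance: str = "pearson",
    platform: str = "expression",
) -> ClusterAssignment:
    """Agglomerative clustering of samples into ``k`` groups.

    Deterministic for a fixed input; robustness is the per-sample silhouette
    width on the same distance, rescaled from [-1, 1] to [0, 1].
    """
    frame = _as_frame(matrix)
    n = frame.shape[1]
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    if k > n:
        raise ValidationError(f"k={k} exceeds {n} samples")
    dist = sample_distance(frame, distance)
    condensed = ssd.squareform(dist.to_numpy(), checks=False)
    tree = sch.linkage(condensed, method=linkage)
    raw = sch.fcluster(tree, t=k, criterion="maxclust")
    labels = _relabel_first_occurrence(raw)
    robustness = _silhouette_robustness(dist, labels)
    return ClusterAssignment(
        platform=platform,
        labels=pd.Series(labels, index=frame.columns),
        robustness=pd.Series(robustness, index=frame.columns),
        k=int(labels.max()),
        meta={"linkage": linkage, "distance": distance},
    )


def pca_cluster(
    expr: ExpressionMatrix,
    n_components: int,
    k: int,
    linkage: str = "ward",
    platform: str = "expression",
) -> tuple[pd.DataFrame, ClusterAssignment]:
    """PCA of the gene-centered matrix, then clustering in embedding space.

    Component signs follow the largest-loading-positive convention so the
    embedding is reproducible.  Clustering uses Euclidean distance between
    sample scores.
    """
    X = expr.values.to_numpy().T  # samples x genes
    n, g = X.shape
    if n_components > min(n, g):
        raise ValidationError(f"n_components={n_components} exceeds min(n, genes)={min(n, g)}")
    Xc = X - X.mean(axis=0, keepdims=True)
    if not np.any(Xc):
        raise ValidationError("degenerate matrix: zero variance everywhere")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, S, Vt = U[:, :n_components], S[:n_components], Vt[:n_components]
    for i in range(n_components):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    scores = U * S
    embedding = pd.DataFrame(
        scores,
        index=expr.samples,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    assignment = hierarchical_cluster(
        embedding.T, k=k, linkage=linkage, distance="euclidean", platform=platform
    )
    assignment.meta["explained_variance"] = (S**2 / max(n - 1, 1)).tolist()
    return embedding, assignment


def _opls_contrast(X: np.ndarray, y: np.ndarray, n_orthogonal: int) -> np.ndarray:
    """Predictive loading vector of a single OPLS-DA contrast.

    Removes ``n_orthogonal`` label-orthogonal components from X before
    extracting the predictive latent variable; returns the per-gene loading
    of that predictive component.
    """
    Xd = X.copy()
    eps = 1e-12
    w = Xd.T @ y
    nw = np.linalg.norm(w)
    if nw < eps:
        return np.zeros(Xd.shape[1])
    w /= nw
    for _ in range(n_orthogonal):
        t = Xd @ w
        p = Xd.T @ t / max(t @ t, eps)
        w_orth = p - (w @ p) * w
        n_orth = np.linalg.norm(w_orth)
        if n_orth < eps:
            break
        w_orth /= n_orth
        t_orth = Xd @ w_orth
        p_orth = Xd.T @ t_orth / max(t_orth @ t_orth, eps)
        Xd = Xd - np.outer(t_orth, p_orth)
        w = Xd.T @ y
        nw = np.linalg.norm(w)
        if nw < eps:
            return np.zeros(Xd.shape[1])
        w /= nw
    t = Xd @ w
    return Xd.T @ t / max(t @ t, eps)


def discriminant_genes(
    expr: ExpressionMatrix,
    labels: pd.Series,
    n_orthogonal: int = 1,
    selection_rule: tuple = ("top", 200),
) -> DiscriminantGeneSet:
    """Rank genes by OPLS-DA predictive loading over one-vs-rest contrasts.

    Each cluster label defines a contrast; a gene's weight is its largest-
    magnitude predictive loading across contrasts, and ``origin`` records
    the contributing contrast.  ``selection_rule`` is ``("top", N)`` or
    ``("threshold", min_abs_loading)``.
    """
    labels = labels.reindex(expr.samples)
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValidationError("need at least 2 cluster labels")
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValidationError(f"labels with a single sample: {small}")
    X = expr.values.to_numpy().T.astype(float)
    X = X - X.mean(axis=0, keepdims=True)
    sd = X.std(axis=0, ddof=1)
    X = X / np.where(sd < 1e-12, 1.0, sd)
    loadings = {}
    for lab in sorted(counts.index.astype(str)):
        y = (labels.astype(str) == lab).to_numpy(dtype=float)
        y = y - y.mean()
        loadings[lab] = _opls_contrast(X, y, n_orthogonal)
    mat = pd.DataFrame(loadings, index=expr.genes)
    best = mat.abs().idxmax(axis=1)
    weight = pd.Series(
        [mat.at[g, c] for g, c in best.items()], index=mat.index, dtype=float
    )
    result = DiscriminantGeneSet(weight, best)
    rule, value = selection_rule
    if rule == "top":
        result = result.top(int(value))
    elif rule == "threshold":
        keep = result.weights.abs() >= float(value)
        result = DiscriminantGeneSet(result.weights[keep], result.origin[keep])
    else:
        raise ValidationError(f"unknown selection rule {rule!r}")
    return result


def _centroids(frame: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    return frame.T.groupby(labels).mean()


def transfer_clusters(
    external_expr: ExpressionMatrix,
    genes: DiscriminantGeneSet,
    k: int,
    reference: tuple[ExpressionMatrix, ClusterAssignment] | None = None,
    linkage: str = "ward",
    distance: str = "pearson",
    min_shared: int = 10,
) -> ClusterAssignment:
    """Project a cluster solution onto an external cohort.

    The external matrix is restricted to the discriminant genes it shares
    with the reference, median-centered per gene, and hierarchically
    clustered into ``k`` groups.  When a reference cohort and assignment are
    supplied, external cluster labels are matched to reference clusters by
    centroid cosine similarity with a Hungarian one-to-one assignment.
    """
    shared = external_expr.genes.intersection(genes.genes)
    if len(shared) < min_shared:
        raise ValidationError(
            f"only {len(shared)} shared discriminant genes (< {min_shared})"
        )
    sub = external_expr.values.loc[shared]
    centered = sub.sub(sub.median(axis=1), axis=0)
    assignment = hierarchical_cluster(
        centered, k=k, linkage=linkage, distance=distance, platform="transfer"
    )
    assignment.meta["n_shared_genes"] = int(len(shared))
    if reference is not None:
        ref_expr, ref_assign = reference
        ref_shared = ref_expr.genes.intersection(shared)
        ref_sub = ref_expr.values.loc[ref_shared]
        ref_centered = ref_sub.sub(ref_sub.median(axis=1), axis=0)
        ref_cent = _centroids(ref_centered, ref_assign.labels)
        ext_cent = _centroids(centered.loc[ref_shared], assignment.labels)
        sim = np.zeros((len(ext_cent), len(ref_cent)))
        for i, (_, a) in enumerate(ext_cent.iterrows()):
            for j, (_, b) in enumerate(ref_cent.iterrows()):
                na, nb = np.linalg.norm(a), np.linalg.norm(b)
                sim[i, j] = (a @ b) / (na * nb) if na > 0 and nb > 0 else 0.0
        rows, cols = linear_sum_assignment(-sim)
        mapping = {
            int(ext_cent.index[i]): int(ref_cent.index[j]) for i, j in zip(rows, cols)
        }
        unmatched = [c for c in ext_cent.index if int(c) not in mapping]
        spare = [c for c in range(1, max(len(ext_cent), len(ref_cent)) + 1)
                 if c not in mapping.values()]
        for c, s in zip(unmatched, spare):
            mapping[int(c)] = s
        assignment.labels = assignment.labels.map(mapping)
        assignment.k = max(assignment.k, max(mapping.values()))
        assignment.meta["label_mapping"] = mapping
    return assignment
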