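"""Per-platform feature selection, consensus clustering, and COCA.

Copy-number clustering uses only recurrently altered loci (clustering on
every locus overfits to noise); the recurrence statistic is a simplified
frequency x amplitude score with a within-sample permutation null standing
in for a full segmented-marker algorithm.  Methylation clustering uses only
CpGs that are unmethylated in normal tissue and recurrently hypermethylated
in tumors.  Consensus clustering resamples the cohort and reports, per
sample pair, the co-clustering frequency; cluster-of-clusters analysis
(COCA) then clusters samples on the binary matrix of their per-platform
cluster memberships to define integrated subtypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from statsmodels.stats.multitest import multipletests

from .matrices import ClusterAssignment, CopyNumberMatrix, MethylationMatrix, ValidationError
from .subtypes import _relabel_first_occurrence, _silhouette_robustness, sample_distance

__all__ = [
    "RecurrentLociSet",
    "CancerCpGSet",
    "select_recurrent_scna",
    "select_cancer_cpgs",
    "build_membership_indicator",
    "consensus_cluster",
    "coca",
]


@dataclass
class RecurrentLociSet:
    """Loci recurrently gained or lost, with scores and permutation q-values."""

    table: pd.DataFrame  # locus, direction, frequency, score, p_value, q_value

    @property
    def loci(self) -> list[str]:
        return self.table["locus"].unique().tolist()

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class CancerCpGSet:
    """Probes unmethylated in normals but recurrently hypermethylated in tumors."""

    table: pd.DataFrame  # probe, normal_mean, hyper_frequency

    @property
    def probes(self) -> list[str]:
        return self.table["probe"].tolist()

    def __len__(self) -> int:
        return len(self.table)


def _direction_scores(values: np.ndarray, thresh: float, direction: str):
    mask = values >= thresh if direction == "gain" else values <= thresh
    count = mask.sum(axis=1)
    freq = count / values.shape[1]
    amp = np.where(count > 0, (np.abs(values) * mask).sum(axis=1) / np.maximum(count, 1), 0.0)
    return freq, freq * amp


def select_recurrent_scna(
    cn: CopyNumberMatrix,
    amp_thresh: float = 0.3,
    del_thresh: float = -0.3,
    n_perm: int = 200,
    q_max: float = 0.25,
    seed: int = 0,
) -> RecurrentLociSet:
    """Select loci whose gain/loss recurrence exceeds a permutation null.

    Per locus and direction the score is (fraction of samples beyond the
    threshold) x (mean |log-ratio| among those samples).  The null permutes
    locus labels within each sample, preserving every sample's log-ratio
    distribution; p-values pool null scores over loci, and BH q-values are
    thresholded at ``q_max``.
    """
    if not (amp_thresh > 0 > del_thresh):
        raise ValidationError("need amp_thresh > 0 > del_thresh")
    values = cn.values.to_numpy()
    n_loci, n_samples = values.shape
    empty = pd.DataFrame(
        columns=["locus", "direction", "frequency", "score", "p_value", "q_value"]
    )
    if n_samples < 2:
        warnings.warn("recurrence undefined with a single sample; returning empty set")
        return RecurrentLociSet(empty)
    rng = np.random.default_rng(seed)
    rows = []
    for direction, thresh in [("gain", amp_thresh), ("loss", del_thresh)]:
        freq, score = _direction_scores(values, thresh, direction)
        null = np.empty((n_perm, n_loci))
        for b in range(n_perm):
            perm = rng.permuted(values, axis=0)
            _, null[b] = _direction_scores(perm, thresh, direction)
        flat = np.sort(null.ravel())
        # one-sided pooled-null p: fraction of null scores >= observed
        idx = np.searchsorted(flat, score, side="left")
        p = (flat.size - idx + 1) / (flat.size + 1)
        for i in range(n_loci):
            if freq[i] > 0:
                rows.append(
                    {
                        "locus": cn.loci[i],
                        "direction": direction,
                        "frequency": float(freq[i]),
                        "score": float(score[i]),
                        "p_value": float(p[i]),
                    }
                )
    if not rows:
        return RecurrentLociSet(empty)
    table = pd.DataFrame(rows)
    table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
    table = table[table["q_value"] <= q_max].reset_index(drop=True)
    return RecurrentLociSet(table.sort_values(["q_value", "locus"]).reset_index(drop=True))


def select_cancer_cpgs(
    meth_tumor: MethylationMatrix,
    meth_normal: MethylationMatrix,
    normal_max_beta: float = 0.3,
    delta_min: float = 0.2,
    min_frequency: float = 0.1,
) -> CancerCpGSet:
    """Select probes with cancer-specific methylation gain.

    A probe qualifies when its mean beta in normals is below
    ``normal_max_beta`` and at least ``min_frequency`` of tumors gain
    ``delta_min`` beta over the normal mean.
    """
    shared = meth_tumor.probes.intersection(meth_normal.probes)
    if len(shared) == 0:
        raise ValidationError("no shared probes between tumor and normal matrices")
    tumor = meth_tumor.betas.loc[shared]
    normal_mean = meth_normal.betas.loc[shared].mean(axis=1)
    gain_freq = tumor.sub(normal_mean, axis=0).ge(delta_min).mean(axis=1)
    keep = (normal_mean < normal_max_beta) & (gain_freq >= min_frequency)
    table = pd.DataFrame(
        {
            "probe": shared[keep],
            "normal_mean": normal_mean[keep].to_numpy(),
            "hyper_frequency": gain_freq[keep].to_numpy(),
        }
    ).reset_index(drop=True)
    return CancerCpGSet(table)


def _consensus_from_distance(
    dist: pd.DataFrame,
    k_range,
    n_reps: int,
    subsample_fraction: float,
    seed: int,
    linkage: str = "average",
    platform: str = "consensus",
):
    """Consensus clustering over resampled runs on a precomputed distance.

    Subsampling samples and clustering the corresponding distance submatrix
    is equivalent to reclustering the subsampled data.  Per candidate k the
    consensus matrix C holds co-clustering frequencies among runs containing
    both samples; k is chosen by maximal mean silhouette on 1 - C.
    """
    samples = dist.index
    n = len(samples)
    k_range = [int(k) for k in k_range]
    if max(k_range) > n:
        raise ValidationError(f"k_range max {max(k_range)} exceeds {n} samples")
    if not 0 < subsample_fraction <= 1:
        raise ValidationError("subsample_fraction must be in (0, 1]")
    if n_reps < 2:
        raise ValidationError("need at least 2 resampling runs")
    rng = np.random.default_rng(seed)
    m = max(max(k_range), int(round(subsample_fraction * n)))
    co = {k: np.zeros((n, n)) for k in k_range}
    both = np.zeros((n, n))
    D = dist.to_numpy()
    for _ in range(n_reps):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        both[np.ix_(idx, idx)] += 1
        sub = D[np.ix_(idx, idx)]
        tree = sch.linkage(ssd.squareform(sub, checks=False), method=linkage)
        for k in k_range:
            labels = sch.fcluster(tree, t=k, criterion="maxclust")
            for lab in np.unique(labels):
                members = idx[labels == lab]
                co[k][np.ix_(members, members)] += 1
    results = {}
    for k in k_range:
        C = np.where(both > 0, co[k] / np.maximum(both, 1), 0.0)
        np.fill_diagonal(C, 1.0)
        C = (C + C.T) / 2
        consensus = pd.DataFrame(C, index=samples, columns=samples)
        cdist = pd.DataFrame(1.0 - C, index=samples, columns=samples)
        np.fill_diagonal(cdist.values, 0.0)
        tree = sch.linkage(ssd.squareform(cdist.to_numpy(), checks=False), method=linkage)
        labels = _relabel_first_occurrence(sch.fcluster(tree, t=k, criterion="maxclust"))
        sil = _silhouette_robustness(cdist, labels)
        # a cut that collapses to a single cluster is never a valid solution
        quality = float(np.mean(sil)) if len(set(labels)) >= 2 else -np.inf
        results[k] = (labels, sil, consensus, quality)
    best_k = max(results, key=lambda k: (results[k][3], -k))
    labels, sil, consensus, _ = results[best_k]
    assignment = ClusterAssignment(
        platform=platform,
        labels=pd.Series(labels, index=samples),
        robustness=pd.Series(sil, index=samples),
        k=int(labels.max()),
        meta={"k_range": k_range, "chosen_k": int(best_k), "n_reps": n_reps},
    )
    return assignment, consensus


def consensus_cluster(
    matrix,
    k_range=(2, 3, 4, 5, 6),
    n_reps: int = 100,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    distance: str = "euclidean",
    linkage: str = "average",
    platform: str = "consensus",
) -> tuple[ClusterAssignment, pd.DataFrame]:
    """Consensus clustering of a feature x sample matrix.

    Returns the assignment at the silhouette-optimal k together with the
    consensus co-clustering matrix; robustness is the per-sample silhouette
    on 1 - consensus, rescaled to [0, 1].
    """
    if isinstance(matrix, (MethylationMatrix,)):
        frame = matrix.betas
    elif isinstance(matrix, CopyNumberMatrix):
        frame = matrix.values
    elif hasattr(matrix, "values") and isinstance(matrix.values, pd.DataFrame):
        frame = matrix.values
    else:
        frame = matrix
    dist = sample_distance(frame, distance)
    return _consensus_from_distance(
        dist, k_range, n_reps, subsample_fraction, seed, linkage, platform
    )


def build_membership_indicator(assignments: list[ClusterAssignment]) -> pd.DataFrame:
    """Binary sample x (platform, cluster) membership matrix.

    Per platform each sample has exactly one 1; samples a platform lacks get
    NaN across that platform's columns.
    """
    if len(assignments) == 0:
        raise ValidationError("no assignments given")
    all_samples = pd.Index([])
    for a in assignments:
        all_samples = all_samples.union(a.samples, sort=False)
    cols = {}
    for a in assignments:
        for c in range(1, a.k + 1):
            col = pd.Series(np.nan, index=all_samples)
            col.loc[a.samples] = (a.labels == c).astype(float)
            cols[(a.platform, c)] = col
    ind = pd.DataFrame(cols)
    ind.columns = pd.MultiIndex.from_tuples(ind.columns, names=["platform", "cluster"])
    return ind


def _jaccard_distance_with_missing(ind: pd.DataFrame) -> pd.DataFrame:
    """1 - Jaccard over indicator columns observed for both samples."""
    X = ind.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    Xz = np.nan_to_num(X, nan=0.0)
    inter = Xz @ Xz.T
    ones = (Xz > 0).astype(float)
    obs_f = obs.astype(float)
    # union over mutually observed columns: |a| + |b| - |a & b|, each
    # restricted to columns observed in both samples
    a_in_obs = ones @ obs_f.T
    b_in_obs = obs_f @ ones.T
    union = a_in_obs + b_in_obs - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, inter / union, 0.0)
    dist = 1.0 - jac
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=ind.index, columns=ind.index)


def coca(
    assignments: list[ClusterAssignment],
    k_range=(2, 3, 4, 5, 6),
    n_reps: int = 100,
    subsample_fraction: float = 0.8,
    seed: int = 0,
) -> ClusterAssignment:
    """Cluster-of-clusters integration of per-platform partitions.

    Samples are consensus-clustered on their binary membership-indicator
    rows with a 1 - Jaccard distance; samples missing from a platform are
    compared over mutually observed columns only.
    """
    if len(assignments) == 1:
        a = assignments[0]
        return ClusterAssignment(
            platform="coca",
            labels=a.labels.copy(),
            robustness=pd.Series(1.0, index=a.samples),
            k=a.k,
            meta={"platforms": [a.platform], "chosen_k": a.k},
        )
    if len(assignments) < 1:
        raise ValidationError("COCA needs at least one platform assignment")
    shared = assignments[0].samples
    for a in assignments[1:]:
        shared = shared.intersection(a.samples)
    if len(shared) < 2:
        raise ValidationError("fewer than 2 samples shared across platforms")
    ind = build_membership_indicator(assignments)
    dist = _jaccard_distance_with_missing(ind)
    assignment, consensus = _consensus_from_distance(
        dist, k_range, n_reps, subsample_fraction, seed, linkage="average",
        platform="coca",
    )
    assignment.meta["platforms"] = [a.platform for a in assignments]
    assignment.meta["consensus"] = consensus
    return assignment
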