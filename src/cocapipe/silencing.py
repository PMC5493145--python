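"""Epigenetic-silencing statistics and mutational-signature exposures.

A gene is called epigenetically silenced in a sample when its promoter
methylation rises well above the cohort-low reference while its expression
drops below the cohort — and the call is annotated for conflicts with
mutation or deep deletion of the same gene, since genetic and epigenetic
inactivation of the same driver tend to be mutually exclusive.  The
group-level analysis intersects group-specific promoter hypermethylation
with group-specific downregulation and per-gene methylation-expression
anticorrelation.  Exposure fitting decomposes the cohort's trinucleotide
spectrum onto a fixed signature matrix by non-negative least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls
from statsmodels.stats.multitest import multipletests

from .matrices import (
    CopyNumberMatrix,
    ExpressionMatrix,
    MethylationMatrix,
    MutationTable,
    ValidationError,
)

__all__ = [
    "SilencingCall",
    "GroupSilencingResult",
    "ExposureEstimate",
    "call_silencing_per_sample",
    "intersect_hyper_down",
    "fisher_exact",
    "overlap_test",
    "signature_correlated_features",
    "CorrelatedFeatureResult",
    "fit_signature_exposures",
]


@dataclass
class SilencingCall:
    sample: str
    gene: str
    promoter_beta: float
    beta_gain: float
    expression_z: float
    silenced: bool
    exclusivity: str  # "", "conflict_mutation", "conflict_deletion"


def call_silencing_per_sample(
    meth: MethylationMatrix,
    expr: ExpressionMatrix,
    mutations: MutationTable | None,
    cn: CopyNumberMatrix | None,
    gene: str,
    beta_gain_min: float = 0.3,
    expr_z_max: float = -1.0,
    deep_deletion_thresh: float = -1.0,
) -> list[SilencingCall]:
    """Call per-sample epigenetic silencing of one gene.

    The promoter beta reference is the mean over the lowest-beta tertile of
    the cohort (a cohort-low stand-in when adjacent normals are not
    available).  A sample is silenced iff its beta gain over that reference
    is >= ``beta_gain_min`` and its expression z-score is <= ``expr_z_max``.
    Silenced calls co-occurring with a non-silent mutation or a deep
    deletion of the same gene are annotated as conflicts, never converted.
    """
    probes = meth.promoter_probes(gene)
    if not probes:
        raise ValidationError(f"gene {gene!r} has no annotated promoter probes")
    if gene not in expr.genes:
        raise ValidationError(f"gene {gene!r} missing from expression matrix")
    shared = meth.samples.intersection(expr.samples)
    beta = meth.betas.loc[probes, shared].mean(axis=0)
    n_low = max(1, len(shared) // 3)
    reference = float(beta.sort_values().iloc[:n_low].mean())
    e = expr.values.loc[gene, shared]
    sd = e.std(ddof=1)
    z = (e - e.mean()) / (sd if sd > 1e-12 else 1.0)
    mutated = mutations.mutated_samples(gene) if mutations is not None else set()
    deleted: set[str] = set()
    if cn is not None and gene in cn.loci:
        row = cn.values.loc[gene, shared]
        deleted = set(row.index[row <= deep_deletion_thresh])
    calls = []
    for s in shared:
        gain = float(beta[s] - reference)
        silenced = gain >= beta_gain_min and float(z[s]) <= expr_z_max
        exclusivity = ""
        if silenced and s in mutated:
            exclusivity = "conflict_mutation"
        elif silenced and s in deleted:
            exclusivity = "conflict_deletion"
        calls.append(
            SilencingCall(
                sample=s,
                gene=gene,
                promoter_beta=float(beta[s]),
                beta_gain=gain,
                expression_z=float(z[s]),
                silenced=bool(silenced),
                exclusivity=exclusivity,
            )
        )
    return calls


@dataclass
class GroupSilencingResult:
    """Genes passing hypermethylation x downregulation x anticorrelation."""

    table: pd.DataFrame  # gene-indexed: delta_beta, expr_log2_fold, rho, q_meth, q_expr
    probes: dict[str, list[str]]  # gene -> contributing probes

    @property
    def genes(self) -> list[str]:
        return self.table.index.tolist()

    @property
    def n_probes(self) -> int:
        return sum(len(v) for v in self.probes.values())


def _ranksum_rows(values: pd.DataFrame, mask: np.ndarray) -> np.ndarray:
    """Two-sided rank-sum p per row for in-group vs rest."""
    inside = values.to_numpy()[:, mask]
    outside = values.to_numpy()[:, ~mask]
    res = stats.mannwhitneyu(inside, outside, alternative="two-sided", axis=1)
    return np.atleast_1d(res.pvalue)


def intersect_hyper_down(
    meth: MethylationMatrix,
    expr: ExpressionMatrix,
    group_mask: pd.Series,
    purity: pd.Series | None = None,
    purity_cutoff: float = 0.65,
    delta_beta_min: float = 0.2,
    q_max: float = 0.05,
    rho_max: float = -0.3,
    promoter_only: bool = True,
) -> GroupSilencingResult:
    """Three-stage group-specific silencing screen.

    Stage 1 keeps probes whose in-group beta exceeds the rest by
    ``delta_beta_min`` at rank-sum BH q <= ``q_max``; stage 2 keeps their
    target genes whose in-group expression decreases at BH q <= ``q_max``;
    stage 3 keeps genes whose promoter beta and expression are Spearman-
    anticorrelated at rho <= ``rho_max`` across the retained samples.
    Low-purity samples are excluded before testing.
    """
    shared = meth.samples.intersection(expr.samples)
    mask_series = group_mask.reindex(shared).astype(bool)
    if purity is not None:
        keep = purity.reindex(shared) >= purity_cutoff
        shared = shared[keep.to_numpy()]
        mask_series = mask_series.loc[shared]
    mask = mask_series.to_numpy()
    if mask.sum() < 3 or (~mask).sum() < 3:
        raise ValidationError(
            f"need >= 3 samples per group after purity filtering, have "
            f"{int(mask.sum())} vs {int((~mask).sum())}"
        )
    betas = meth.betas[shared]
    ann = meth.probe_annotation
    if promoter_only:
        betas = betas.loc[ann.loc[betas.index, "promoter"].astype(bool)]
    empty = GroupSilencingResult(
        pd.DataFrame(
            columns=["delta_beta", "expr_log2_fold", "rho", "q_meth", "q_expr"]
        ),
        {},
    )
    if betas.empty:
        return empty
    # stage 1: group-specific hypermethylation per probe
    delta = betas.to_numpy()[:, mask].mean(axis=1) - betas.to_numpy()[:, ~mask].mean(axis=1)
    p_meth = _ranksum_rows(betas, mask)
    q_meth = multipletests(p_meth, method="fdr_bh")[1]
    probe_pass = (delta >= delta_beta_min) & (q_meth <= q_max)
    if not probe_pass.any():
        return empty
    hyper_probes = betas.index[probe_pass]
    probe_stats = pd.DataFrame(
        {"delta": delta[probe_pass], "q": q_meth[probe_pass]}, index=hyper_probes
    )
    gene_probes: dict[str, list[str]] = {}
    for probe in hyper_probes:
        g = ann.at[probe, "gene"]
        if g in expr.genes:
            gene_probes.setdefault(g, []).append(probe)
    if not gene_probes:
        return empty
    # stage 2: group-specific downregulation of the mapped genes
    cand = sorted(gene_probes)
    evals = expr.values.loc[cand, shared]
    lfc = evals.to_numpy()[:, mask].mean(axis=1) - evals.to_numpy()[:, ~mask].mean(axis=1)
    p_expr = _ranksum_rows(evals, mask)
    q_expr = multipletests(p_expr, method="fdr_bh")[1]
    gene_pass = (lfc < 0) & (q_expr <= q_max)
    # stage 3: per-gene methylation-expression anticorrelation
    rows = []
    probes_out: dict[str, list[str]] = {}
    for i, g in enumerate(cand):
        if not gene_pass[i]:
            continue
        prom = betas.loc[gene_probes[g]].mean(axis=0)
        rho = stats.spearmanr(prom, evals.loc[g]).statistic
        if np.isnan(rho) or rho > rho_max:
            continue
        rows.append(
            {
                "gene": g,
                "delta_beta": float(probe_stats.loc[gene_probes[g], "delta"].mean()),
                "expr_log2_fold": float(lfc[i]),
                "rho": float(rho),
                "q_meth": float(probe_stats.loc[gene_probes[g], "q"].min()),
                "q_expr": float(q_expr[i]),
            }
        )
        probes_out[g] = list(gene_probes[g])
    if not rows:
        return empty
    table = pd.DataFrame(rows).set_index("gene").sort_index()
    return GroupSilencingResult(table, probes_out)


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table.

    The p-value sums hypergeometric probabilities of all tables (with the
    observed margins) no more probable than the observed one.  The odds
    ratio applies the Haldane 0.5 correction when a zero cell is present.
    Returns ``(p_value, odds_ratio)``.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("fisher_exact needs a 2x2 table of non-negative counts")
    a, b = t[0]
    c, d = t[1]
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if n == 0 or row1 == 0 or row1 == n or col1 == 0 or col1 == n:
        p = 1.0
    else:
        support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
        pmf = stats.hypergeom.pmf(support, n, row1, col1)
        p_obs = stats.hypergeom.pmf(a, n, row1, col1)
        p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
        p = min(p, 1.0)
    if min(a, b, c, d) == 0:
        a2, b2, c2, d2 = (x + 0.5 for x in (a, b, c, d))
    else:
        a2, b2, c2, d2 = a, b, c, d
    odds = (a2 * d2) / (b2 * c2)
    return p, float(odds)


def overlap_test(set_a, set_b, universe_size: int) -> tuple[int, float]:
    """Upper-tail hypergeometric test of the overlap between two gene sets."""
    set_a, set_b = set(set_a), set(set_b)
    if len(set_a | set_b) > universe_size:
        raise ValidationError("sets exceed the stated universe")
    k = len(set_a & set_b)
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(set_a), len(set_b)))
    return k, min(p, 1.0)


@dataclass
class CorrelatedFeatureResult:
    """Features tracking a signature score across datasets, with a chance null."""

    features: list[str]          # flagged in >= min_datasets datasets
    counts: pd.Series            # feature -> number of datasets flagged
    observed: int
    expected_by_chance: float
    fisher_p: float
    null_counts: np.ndarray | None = None  # per-permutation flagged counts


def _spearman_features_vs_score(frame: pd.DataFrame, score: pd.Series) -> np.ndarray:
    ranks = frame.rank(axis=1).to_numpy()
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((ranks**2).sum(axis=1))
    r = stats.rankdata(score.to_numpy())
    r = r - r.mean()
    rn = np.sqrt((r**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ranks @ r) / (norm * rn)
    return np.nan_to_num(rho, nan=0.0)


def signature_correlated_features(
    feature_matrices: list[pd.DataFrame],
    scores: list[pd.Series],
    rho_min: float = 0.5,
    sign: str = "positive",
    min_datasets: int = 2,
    n_perm: int = 200,
    seed: int = 0,
) -> CorrelatedFeatureResult:
    """Find features that track a signature score across several datasets.

    A feature is flagged in a dataset when its Spearman correlation with
    that dataset's score passes ``rho_min`` with the stated ``sign``
    (positive / negative / any); it is reported when flagged in at least
    ``min_datasets`` datasets.  The chance expectation recomputes the count
    over ``n_perm`` sample-permuted scores, and enrichment of observed over
    expected is a Fisher exact test.
    """
    if min_datasets > len(feature_matrices):
        raise ValidationError(
            f"min_datasets={min_datasets} exceeds {len(feature_matrices)} datasets"
        )
    if len(feature_matrices) != len(scores):
        raise ValidationError("need one score vector per dataset")
    features = feature_matrices[0].index
    for fm in feature_matrices[1:]:
        features = features.intersection(fm.index)
    if len(features) == 0:
        raise ValidationError("no shared features across datasets")
    aligned = []
    for fm, sc in zip(feature_matrices, scores):
        cols = fm.columns.intersection(sc.index)
        aligned.append((fm.loc[features, cols], sc.loc[cols]))

    def _flag(rho: np.ndarray) -> np.ndarray:
        if sign == "positive":
            return rho >= rho_min
        if sign == "negative":
            return rho <= -rho_min
        if sign == "any":
            return np.abs(rho) >= rho_min
        raise ValidationError(f"unknown sign {sign!r}")

    counts = np.zeros(len(features), dtype=int)
    for fm, sc in aligned:
        counts += _flag(_spearman_features_vs_score(fm, sc)).astype(int)
    observed_mask = counts >= min_datasets
    observed = int(observed_mask.sum())
    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_perm)
    for b in range(n_perm):
        cnt = np.zeros(len(features), dtype=int)
        for fm, sc in aligned:
            perm = pd.Series(rng.permutation(sc.to_numpy()), index=sc.index)
            cnt += _flag(_spearman_features_vs_score(fm, perm)).astype(int)
        null_counts[b] = (cnt >= min_datasets).sum()
    expected = float(null_counts.mean())
    exp_int = int(round(expected))
    nf = len(features)
    p, _ = fisher_exact([[observed, nf - observed], [exp_int, nf - exp_int]])
    return CorrelatedFeatureResult(
        features=list(features[observed_mask]),
        counts=pd.Series(counts, index=features),
        observed=observed,
        expected_by_chance=expected,
        fisher_p=p,
        null_counts=null_counts,
    )


@dataclass
class ExposureEstimate:
    """Per-signature exposure fractions from an NNLS spectrum refit."""

    exposures: pd.Series
    reconstruction_error: float
    enriched: pd.Series

    def __post_init__(self) -> None:
        total = self.exposures.sum()
        if (self.exposures < -1e-12).any() or abs(total - 1.0) > 1e-6:
            raise ValidationError("exposures must be non-negative and sum to 1")


def fit_signature_exposures(
    mutations: MutationTable,
    signature_matrix: pd.DataFrame,
    enrichment_threshold: float = 0.05,
) -> ExposureEstimate:
    """Fit cohort signature exposures by non-negative least squares.

    The cohort's trinucleotide context frequencies are regressed onto the
    column-stochastic signature matrix; exposures are normalized to sum to
    one, and a signature is flagged enriched when its exposure reaches
    ``enrichment_threshold``.
    """
    if len(mutations) == 0:
        raise ValidationError("cannot fit exposures on an empty mutation table")
    observed = mutations.context_counts()
    unknown = observed.index.difference(signature_matrix.index)
    if len(unknown):
        raise ValidationError(
            f"contexts absent from the signature matrix: {list(unknown)[:5]}"
        )
    counts = observed.reindex(signature_matrix.index, fill_value=0).to_numpy(dtype=float)
    freq = counts / counts.sum()
    S = signature_matrix.to_numpy(dtype=float)
    x, _ = nnls(S, freq)
    if x.sum() <= 0:
        raise ValidationError("degenerate fit: all exposures zero")
    exposures = pd.Series(x / x.sum(), index=signature_matrix.columns)
    error = float(np.linalg.norm(freq - S @ x))
    enriched = exposures >= enrichment_threshold
    return ExposureEstimate(exposures, error, enriched)
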