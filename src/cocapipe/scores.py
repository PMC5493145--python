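"""Geneset scoring, permutation GSEA, and association statistics.

The per-sample signature score condenses a geneset into one number (the
mean of member-gene z-scores, or the per-sample median of raw member
expression).  GSEA follows the classic weighted running-sum statistic with
a gene-label permutation null.  Group associations use two-sided rank-sum
tests with Benjamini-Hochberg correction, optionally after excluding
low-purity samples whose expression largely reflects admixed stroma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrices import ExpressionMatrix, ValidationError

__all__ = [
    "GseaResult",
    "score_signature",
    "score_signatures",
    "enrichment_score",
    "gsea",
    "rank_by_group",
    "associate_score_with_groups",
    "anticorrelation_block",
]


def score_signature(
    expr: ExpressionMatrix, geneset: list[str], method: str = "mean_z"
) -> pd.Series:
    """Condense a geneset into a per-sample score.

    ``mean_z``: z-score each member gene across samples, then average over
    members.  ``median_raw``: per-sample median of raw member expression.
    Zero-variance genes are dropped with a warning.
    """
    members = [g for g in dict.fromkeys(geneset) if g in expr.genes]
    if not members:
        raise ValidationError("no geneset members present in the expression matrix")
    sub = expr.values.loc[members]
    if method == "median_raw":
        return sub.median(axis=0)
    if method != "mean_z":
        raise ValidationError(f"unknown scoring method {method!r}")
    sd = sub.std(axis=1, ddof=1)
    flat = sd[sd < 1e-12].index
    if len(flat):
        warnings.warn(f"dropping {len(flat)} zero-variance genes from signature score")
        sub = sub.drop(index=flat)
        sd = sd.drop(index=flat)
        if sub.empty:
            raise ValidationError("all geneset members have zero variance")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    return z.mean(axis=0)


def score_signatures(
    expr: ExpressionMatrix, genesets: dict[str, list[str]], method: str = "mean_z"
) -> pd.DataFrame:
    """Sample x signature score table for a GMT-style collection."""
    return pd.DataFrame(
        {name: score_signature(expr, members, method) for name, members in genesets.items()}
    )


def enrichment_score(
    ranked: pd.Series, geneset: set[str], weight_exponent: float = 1.0
) -> float:
    """Maximum-deviation running-sum enrichment score on a ranked gene list.

    Hits increment by |ranking weight|^exponent (normalized to sum 1 over
    members); misses decrement by 1/(N - |S|).  The score is the running
    sum's extremum, signed.
    """
    genes = ranked.index
    hit = np.asarray(genes.isin(geneset))
    n, ns = len(genes), int(hit.sum())
    if ns == 0 or ns == n:
        raise ValidationError("geneset must be a non-empty proper subset of the universe")
    w = np.abs(ranked.to_numpy()) ** weight_exponent
    w = np.where(hit, w, 0.0)
    total = w.sum()
    if total < 1e-300:  # all-hit weights zero (e.g. exponent 0 handled above)
        w = hit.astype(float)
        total = float(ns)
    running = np.cumsum(w / total - (~hit) / (n - ns))
    return float(running[np.argmax(np.abs(running))])


@dataclass
class GseaResult:
    name: str
    es: float
    nes: float
    p_value: float
    size: int


def _sorted_ranking(ranked: pd.Series) -> pd.Series:
    order = pd.DataFrame({"w": ranked, "gene": ranked.index}).sort_values(
        ["w", "gene"], ascending=[False, True], kind="stable"
    )
    return ranked.loc[order.index]


def gsea(
    ranked: pd.Series,
    geneset: list[str] | set[str],
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    name: str = "geneset",
) -> GseaResult:
    """Permutation GSEA of one geneset against a ranked, weighted gene list.

    The null permutes gene labels (which positions are members), suitable at
    small sample counts where phenotype permutation is infeasible.  NES is
    the observed ES divided by the mean |permuted ES| of the same sign; the
    p-value is the two-sided permutation tail with the +1 correction.
    """
    ranked = _sorted_ranking(ranked.astype(float))
    members = set(geneset) & set(ranked.index)
    es = enrichment_score(ranked, members, weight_exponent)
    ns = len(members)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    gene_array = ranked.index.to_numpy()
    for i in range(n_perm):
        perm = set(rng.choice(gene_array, size=ns, replace=False))
        null[i] = enrichment_score(ranked, perm, weight_exponent)
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    denom = np.mean(np.abs(same_sign)) if len(same_sign) else np.mean(np.abs(null))
    nes = es / denom if denom > 0 else 0.0
    p = (np.sum(np.abs(null) >= abs(es)) + 1) / (n_perm + 1)
    return GseaResult(name=name, es=es, nes=float(nes), p_value=float(p), size=ns)


def rank_by_group(
    expr: ExpressionMatrix,
    labels: pd.Series,
    statistic: str = "signal_to_noise",
    positive_group: str | None = None,
) -> pd.Series:
    """Rank genes by a two-group differential statistic.

    ``signal_to_noise`` is (mu1 - mu2) / (sd1 + sd2); ``t`` is Welch's t.
    Positive values mean higher expression in ``positive_group`` (default:
    lexicographically first label).  Ties break lexicographically.
    """
    labels = labels.reindex(expr.samples)
    groups = sorted(labels.unique().astype(str))
    if len(groups) != 2:
        raise ValidationError(f"need exactly 2 groups, got {groups}")
    if positive_group is None:
        positive_group = groups[0]
    in_a = (labels.astype(str) == positive_group).to_numpy()
    if in_a.sum() < 3 or (~in_a).sum() < 3:
        raise ValidationError("each group needs at least 3 samples")
    A = expr.values.to_numpy()[:, in_a]
    B = expr.values.to_numpy()[:, ~in_a]
    if statistic == "signal_to_noise":
        denom = A.std(axis=1, ddof=1) + B.std(axis=1, ddof=1)
        vals = (A.mean(axis=1) - B.mean(axis=1)) / np.maximum(denom, 1e-12)
    elif statistic == "t":
        vals = stats.ttest_ind(A, B, axis=1, equal_var=False).statistic
        vals = np.nan_to_num(vals, nan=0.0)
    else:
        raise ValidationError(f"unknown statistic {statistic!r}")
    return _sorted_ranking(pd.Series(vals, index=expr.genes))


def associate_score_with_groups(
    scores: pd.Series,
    group_labels: pd.Series,
    purity: pd.Series | None = None,
    purity_cutoff: float = 0.65,
) -> pd.DataFrame:
    """Rank-sum association of a per-sample score with each labeled group.

    Samples with purity below the cutoff are excluded first (admixed stroma
    confounds expression-derived scores).  Each group is tested against all
    remaining samples with a two-sided rank-sum test; q-values are BH over
    groups.
    """
    scores = scores.dropna()
    keep = scores.index.intersection(group_labels.index)
    if purity is not None:
        pure = purity.reindex(keep)
        keep = keep[(pure >= purity_cutoff).to_numpy()]
    if len(keep) == 0:
        raise ValidationError("all samples removed by the purity filter")
    sc = scores.loc[keep]
    lab = group_labels.loc[keep].astype(str)
    rows = []
    for group in sorted(lab.unique()):
        mask = (lab == group).to_numpy()
        if mask.sum() < 2 or (~mask).sum() < 2:
            raise ValidationError(f"group {group!r} has < 2 samples after filtering")
        inside, outside = sc[mask], sc[~mask]
        stat, p = stats.mannwhitneyu(inside, outside, alternative="two-sided")
        rows.append(
            {
                "group": group,
                "n_group": int(mask.sum()),
                "n_rest": int((~mask).sum()),
                "median_group": float(inside.median()),
                "median_rest": float(outside.median()),
                "statistic": float(stat),
                "p_value": float(p),
            }
        )
    out = pd.DataFrame(rows).set_index("group")
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def anticorrelation_block(
    expr_list: list[ExpressionMatrix],
    geneset_a: list[str],
    geneset_b: list[str],
    method: str = "spearman",
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Cross-geneset correlation blocks, one per dataset, in a shared order.

    For every dataset the Spearman correlation of each A-gene with each
    B-gene is computed; gene order on both axes is identical across
    datasets so the blocks are directly comparable.  Genes absent or
    constant in any dataset are dropped (with a warning for constants).
    The summary reports each dataset's mean cross-set correlation and the
    fraction of negative pairs.
    """
    if method != "spearman":
        raise ValidationError(f"unsupported correlation method {method!r}")
    a_order = list(dict.fromkeys(geneset_a))
    b_order = list(dict.fromkeys(geneset_b))
    for expr in expr_list:
        if expr.values.shape[1] < 3:
            raise ValidationError("each dataset needs at least 3 samples")
        present = set(expr.genes)
        const = set(expr.values.index[expr.values.std(axis=1, ddof=1) < 1e-12])
        if const & (set(a_order) | set(b_order)):
            warnings.warn(
                f"dropping constant genes from correlation block: "
                f"{sorted(const & (set(a_order) | set(b_order)))[:5]}"
            )
        a_order = [g for g in a_order if g in present and g not in const]
        b_order = [g for g in b_order if g in present and g not in const]
    if len(a_order) < 2 or len(b_order) < 2:
        raise ValidationError("fewer than 2 usable genes in a geneset")
    blocks, rows = [], []
    for i, expr in enumerate(expr_list):
        sub = expr.values.loc[a_order + [g for g in b_order if g not in a_order]]
        ranks = sub.rank(axis=1)
        rn = ranks.sub(ranks.mean(axis=1), axis=0)
        rn = rn.div(np.sqrt((rn**2).sum(axis=1)), axis=0)
        corr = rn.to_numpy() @ rn.to_numpy().T
        corr_df = pd.DataFrame(corr, index=sub.index, columns=sub.index)
        block = corr_df.loc[a_order, b_order]
        blocks.append(block)
        cross = block.to_numpy()
        rows.append(
            {
                "dataset": i,
                "mean_correlation": float(cross.mean()),
                "fraction_negative": float((cross < 0).mean()),
            }
        )
    return blocks, pd.DataFrame(rows).set_index("dataset")
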