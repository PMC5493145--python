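"""Silencing calls, overlap statistics, and exposure fitting."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cocapipe import (
    CohortConfig,
    CopyNumberMatrix,
    MethylationMatrix,
    MutationTable,
    ValidationError,
    call_silencing_per_sample,
    fisher_exact,
    fit_signature_exposures,
    intersect_hyper_down,
    overlap_test,
    signature_correlated_features,
)
from cocapipe.synthetic import SubtypeSpec, generate_cohort, generate_mutations

from conftest import make_expr


def _meth_single_gene(betas, gene="CDKN2A", samples=None):
    arr = np.atleast_2d(np.asarray(betas, dtype=float))
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    probes = [f"cg{i}" for i in range(arr.shape[0])]
    ann = pd.DataFrame(
        {"gene": gene, "promoter": True, "chrom": "chr9", "pos": range(arr.shape[0])},
        index=pd.Index(probes, name="probe"),
    )
    return MethylationMatrix(pd.DataFrame(arr, index=probes, columns=samples), ann)


# --------------------------------------------------------- per-sample calls

def test_planted_silencing_called():
    betas = [0.1] * 8 + [0.55, 0.6]
    expr_vals = np.array([[5.0] * 8 + [1.0, 0.8]])
    meth = _meth_single_gene(betas)
    expr = make_expr(expr_vals, genes=["CDKN2A"])
    calls = call_silencing_per_sample(meth, expr, None, None, "CDKN2A",
                                      beta_gain_min=0.3, expr_z_max=-1.0)
    by_sample = {c.sample: c for c in calls}
    assert by_sample["s8"].silenced and by_sample["s9"].silenced
    assert sum(c.silenced for c in calls) == 2


def test_deletion_with_low_expression_is_not_silencing():
    """Deep deletion lowers expression without methylation; never called."""
    betas = [0.1] * 10
    expr_vals = np.array([[5.0] * 9 + [0.5]])
    meth = _meth_single_gene(betas)
    expr = make_expr(expr_vals, genes=["CDKN2A"])
    cn = CopyNumberMatrix(pd.DataFrame(
        [[0.0] * 9 + [-2.0]], index=["CDKN2A"], columns=expr.samples))
    calls = call_silencing_per_sample(meth, expr, None, cn, "CDKN2A")
    assert not any(c.silenced for c in calls)


def test_conflict_annotation_marks_mutated_silenced_sample():
    betas = [0.1] * 8 + [0.6, 0.6]
    expr_vals = np.array([[5.0] * 8 + [0.5, 0.4]])
    meth = _meth_single_gene(betas)
    expr = make_expr(expr_vals, genes=["CDKN2A"])
    muts = MutationTable(pd.DataFrame(
        {"sample": ["s8"], "gene": ["CDKN2A"], "protein_change": ["p.R80*"],
         "effect_class": ["non-silent"], "context": ["A[C>T]G"]}))
    calls = call_silencing_per_sample(meth, expr, muts, None, "CDKN2A")
    by_sample = {c.sample: c for c in calls}
    assert by_sample["s8"].silenced and by_sample["s8"].exclusivity == "conflict_mutation"
    assert by_sample["s9"].silenced and by_sample["s9"].exclusivity == ""


def test_unmethylated_expressed_cohort_has_zero_calls(small_cohort):
    planted = {g for block in small_cohort.truth["silenced_genes"].values() for g in block}
    ann = small_cohort.methylation.probe_annotation.query("promoter")
    gene = next(g for g in ann["gene"] if g not in planted)
    calls = call_silencing_per_sample(
        small_cohort.methylation, small_cohort.expression, small_cohort.mutations,
        None, gene,
    )
    assert sum(c.silenced for c in calls) == 0


def test_gene_without_promoter_probes_errors(small_cohort):
    with pytest.raises(ValidationError, match="promoter"):
        call_silencing_per_sample(
            small_cohort.methylation, small_cohort.expression, None, None,
            "NO_SUCH_GENE",
        )


def test_calls_invariant_to_sample_order():
    betas = [0.1, 0.6, 0.1, 0.55]
    expr_vals = np.array([[5.0, 0.5, 5.2, 0.6]])
    meth = _meth_single_gene(betas)
    expr = make_expr(expr_vals, genes=["CDKN2A"])
    calls = call_silencing_per_sample(meth, expr, None, None, "CDKN2A")
    order = [c.sample for c in calls]
    perm = ["s2", "s0", "s3", "s1"]
    meth2 = MethylationMatrix(meth.betas[perm], meth.probe_annotation)
    expr2 = make_expr(expr.values[perm].to_numpy(), genes=["CDKN2A"], samples=perm)
    calls2 = {c.sample: c for c in call_silencing_per_sample(meth2, expr2, None, None, "CDKN2A")}
    for c in calls:
        assert calls2[c.sample].silenced == c.silenced
        assert calls2[c.sample].beta_gain == pytest.approx(c.beta_gain)


# ------------------------------------------------------- group intersection

def test_intersection_recovers_planted_genes(two_group_cohort):
    cohort = two_group_cohort
    mask = cohort.samples["subtype"] == "idh"
    result = intersect_hyper_down(
        cohort.methylation, cohort.expression, mask, purity=cohort.samples["purity"]
    )
    assert set(result.genes) == set(cohort.truth["silenced_genes"]["idh"])
    assert (result.table["rho"] <= -0.3).all()
    assert (result.table["delta_beta"] >= 0.2).all()


def test_no_group_difference_gives_empty_result(small_cohort):
    # arbitrary half-split of a cohort with no planted silencing
    mask = pd.Series(
        [i % 2 == 0 for i in range(len(small_cohort.samples))],
        index=small_cohort.samples.index,
    )
    result = intersect_hyper_down(
        small_cohort.methylation, small_cohort.expression, mask,
    )
    assert len(result.genes) == 0


def test_uncoupled_hyper_and_down_excluded_by_anticorrelation():
    """Hypermethylation and downregulation in different group members fail
    the per-gene anticorrelation stage."""
    rng = np.random.default_rng(0)
    n = 40
    samples = [f"s{j}" for j in range(n)]
    group = np.zeros(n, dtype=bool)
    group[:16] = True
    betas = np.clip(rng.normal(0.1, 0.02, size=(1, n)), 0, 1)
    betas[0, :8] += 0.5          # first half of the group: hypermethylated
    expr_vals = rng.normal(8.0, 0.2, size=(1, n))
    expr_vals[0, 8:16] -= 4.0    # second half: downregulated
    meth = _meth_single_gene(betas, gene="GENE1", samples=samples)
    expr = make_expr(expr_vals, genes=["GENE1"], samples=samples)
    result = intersect_hyper_down(
        meth, expr, pd.Series(group, index=samples),
        delta_beta_min=0.2, q_max=0.05, rho_max=-0.3,
    )
    assert result.genes == []


# ----------------------------------------------------------------- Fisher

def enumeration_fisher(table):
    """Exhaustive two-sided Fisher p over all tables with fixed margins."""
    (a, b), (c, d) = table
    n, r1, c1 = a + b + c + d, a + b, a + c
    denom = math.comb(n, c1)

    def prob(x):
        return math.comb(r1, x) * math.comb(n - r1, c1 - x) / denom

    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-7))


def test_balanced_table_gives_p_one():
    p, odds = fisher_exact([[5, 5], [5, 5]])
    assert p == pytest.approx(1.0)
    assert odds == pytest.approx(1.0)


def test_fisher_matches_full_enumeration_example():
    p, _ = fisher_exact([[8, 2], [1, 9]])
    assert p == pytest.approx(enumeration_fisher([[8, 2], [1, 9]]))
    # and the library reference agrees
    assert p == pytest.approx(stats.fisher_exact([[8, 2], [1, 9]]).pvalue)


def test_zero_margin_gives_p_one():
    p, _ = fisher_exact([[0, 0], [3, 7]])
    assert p == 1.0


def test_haldane_correction_on_zero_cell():
    _, odds = fisher_exact([[5, 0], [2, 8]])
    assert odds == pytest.approx((5.5 * 8.5) / (0.5 * 2.5))


@settings(max_examples=60, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_fisher_agrees_with_enumeration_on_small_tables(seed):
    rng = np.random.default_rng(seed)
    total = int(rng.integers(1, 31))
    cuts = np.sort(rng.integers(0, total + 1, size=3))
    a, b, c = cuts[0], cuts[1] - cuts[0], cuts[2] - cuts[1]
    d = total - a - b - c
    p, _ = fisher_exact([[a, b], [c, d]])
    assert p == pytest.approx(enumeration_fisher([[a, b], [c, d]]))


def test_negative_counts_rejected():
    with pytest.raises(ValidationError):
        fisher_exact([[1, -2], [3, 4]])


# ----------------------------------------------------------------- overlap

def test_disjoint_sets_near_p_one():
    k, p = overlap_test({"a", "b"}, {"c", "d"}, 1000)
    assert k == 0 and p > 0.99


def test_identical_sets_give_max_overlap_min_p():
    s = {f"g{i}" for i in range(10)}
    k, p = overlap_test(s, s, 100)
    assert k == 10
    assert p == pytest.approx(1 / math.comb(100, 10))


def test_overlap_p_matches_direct_summation():
    k, p = overlap_test({f"g{i}" for i in range(10)},
                        {f"g{i}" for i in range(2, 22)}, 100)
    assert k == 8
    direct = sum(
        math.comb(20, x) * math.comb(80, 10 - x) / math.comb(100, 10)
        for x in range(8, 11)
    )
    assert p == pytest.approx(direct)


def test_sets_exceeding_universe_rejected():
    with pytest.raises(ValidationError):
        overlap_test({"a", "b"}, {"c"}, 2)


# -------------------------------------------- signature-correlated features

def _score_datasets(n_datasets=8, n_samples=30, n_features=21, seed=0):
    rng = np.random.default_rng(seed)
    mats, scores = [], []
    for d in range(n_datasets):
        samples = [f"d{d}s{j}" for j in range(n_samples)]
        score = pd.Series(rng.normal(size=n_samples), index=samples)
        feats = rng.normal(size=(n_features, n_samples))
        mats.append(pd.DataFrame(feats, index=[f"f{i}" for i in range(n_features)],
                                 columns=samples))
        scores.append(score)
    return mats, scores


def test_monotone_features_flagged_across_datasets():
    mats, scores = _score_datasets(seed=1)
    for d in range(7):  # f0 tracks the score in 7 of 8 datasets
        mats[d].loc["f0"] = (2 * scores[d] + 0.1 * np.random.default_rng(d).normal(
            size=len(scores[d]))).to_numpy()
    result = signature_correlated_features(
        mats, scores, rho_min=0.5, sign="positive", min_datasets=6, n_perm=50, seed=2
    )
    assert "f0" in result.features
    assert result.counts["f0"] >= 7


def test_noise_features_within_null_central_interval():
    mats, scores = _score_datasets(seed=5)
    result = signature_correlated_features(
        mats, scores, rho_min=0.5, sign="positive", min_datasets=2, n_perm=200, seed=3
    )
    lo, hi = np.percentile(result.null_counts, [2.5, 97.5])
    assert lo <= result.observed <= hi


def test_min_datasets_exceeding_datasets_errors():
    mats, scores = _score_datasets(n_datasets=3)
    with pytest.raises(ValidationError, match="min_datasets"):
        signature_correlated_features(mats, scores, min_datasets=5)


# --------------------------------------------------------------- exposures

def _orthogonal_signatures():
    from cocapipe.synthetic import trinucleotide_contexts

    contexts = trinucleotide_contexts()
    sig = pd.DataFrame(0.0, index=contexts, columns=["s1", "s2"])
    sig.iloc[:48, 0] = 1 / 48
    sig.iloc[48:, 1] = 1 / 48
    return sig


def test_single_signature_dominates_fit():
    sig = _orthogonal_signatures()
    cfg = CohortConfig(n_samples=30, mean_mutations=50,
                       signature_matrix=sig, exposures=[1.0, 0.0], seed=4)
    est = fit_signature_exposures(generate_mutations(cfg), sig)
    assert est.exposures["s1"] >= 0.95
    assert bool(est.enriched["s1"])


def test_mixture_recovery_within_tolerance():
    sig = _orthogonal_signatures()
    cfg = CohortConfig(n_samples=100, mean_mutations=100,
                       signature_matrix=sig, exposures=[0.7, 0.3], seed=8)
    table = generate_mutations(cfg)
    assert len(table) > 9000
    est = fit_signature_exposures(table, sig)
    assert abs(est.exposures["s1"] - 0.7) <= 0.03
    assert abs(est.exposures["s2"] - 0.3) <= 0.03


def test_l1_recovery_at_one_thousand_mutations():
    sig = _orthogonal_signatures()
    cfg = CohortConfig(n_samples=20, mean_mutations=50,
                       signature_matrix=sig, exposures=[0.6, 0.4], seed=12)
    est = fit_signature_exposures(generate_mutations(cfg), sig)
    l1 = abs(est.exposures["s1"] - 0.6) + abs(est.exposures["s2"] - 0.4)
    assert l1 <= 0.1


def test_empty_mutation_table_errors():
    sig = _orthogonal_signatures()
    cfg = CohortConfig(n_samples=5, mean_mutations=0.0, seed=0)
    empty = generate_mutations(cfg)
    with pytest.raises(ValidationError, match="empty"):
        fit_signature_exposures(empty, sig)
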