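"""Cohort summary statistics for reports.

Prevalences are reported as count / denominator pairs with the percentage
rounded half-away-from-zero to the nearest integer, the convention used in
clinical cohort tables.  The mutation burden per megabase is reported only
when the caller supplies the callable exome territory.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = ["CohortSummary", "percentage", "summarize_cohort"]


def percentage(count: int, denominator: int) -> int:
    """Integer percentage with half-away-from-zero rounding."""
    if denominator == 0:
        raise ZeroDivisionError("percentage undefined for a zero denominator")
    x = 100.0 * count / denominator
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass
class CohortSummary:
    prevalences: pd.DataFrame  # feature-indexed: count, denominator, percent
    median_mutation_count: float
    median_mutations_per_mb: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return self.prevalences


def summarize_cohort(
    cohort,
    features_of_interest: list[str] | None = None,
    extra_counts: list[tuple[str, int, int]] | None = None,
    callable_mb: float | None = None,
) -> CohortSummary:
    """Summarize prevalences and mutation burden for a cohort.

    ``features_of_interest`` names boolean columns of the sample annotation
    (e.g. driver-mutation status); ``extra_counts`` supplies ready
    (name, count, denominator) rows.  Zero-denominator rows are omitted with
    a warning rather than reported as undefined percentages.
    """
    n = len(cohort.samples)
    rows: list[dict] = []

    def add(name: str, count: int, denom: int) -> None:
        if denom == 0:
            warnings.warn(f"omitting {name!r}: zero denominator")
            return
        rows.append(
            {"feature": name, "count": int(count), "denominator": int(denom),
             "percent": percentage(count, denom)}
        )

    total_mut = len(cohort.mutations)
    nonsilent = int((cohort.mutations.records["effect_class"] == "non-silent").sum())
    add("non_silent_mutations", nonsilent, total_mut)
    for col in features_of_interest or []:
        if col not in cohort.samples.columns:
            warnings.warn(f"omitting unknown annotation column {col!r}")
            continue
        add(col, int(cohort.samples[col].astype(bool).sum()), n)
    if "subtype" in cohort.samples.columns:
        for name, cnt in cohort.samples["subtype"].value_counts().items():
            add(f"subtype_{name}", int(cnt), n)
    for name, count, denom in extra_counts or []:
        add(name, count, denom)
    prev = pd.DataFrame(rows).set_index("feature") if rows else pd.DataFrame(
        columns=["count", "denominator", "percent"]
    )
    per_sample = cohort.mutations.per_sample_counts(cohort.samples.index)
    median_count = float(per_sample.median())
    per_mb = float((per_sample / callable_mb).median()) if callable_mb else None
    return CohortSummary(prev, median_count, per_mb)
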