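import numpy as np
import pandas as pd
import pytest

from cocapipe import CohortConfig, ExpressionMatrix, generate_cohort
from cocapipe.synthetic import SubtypeSpec


def make_expr(values, genes=None, samples=None) -> ExpressionMatrix:
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples))


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort reused by read-only tests."""
    cfg = CohortConfig(
        n_samples=40, n_genes=800, n_probes=300, n_loci=100,
        n_stromal_genes=60, seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def two_group_cohort():
    """One subtype with planted silencing vs a background group."""
    subs = [
        SubtypeSpec("idh", 0.3, n_silenced_genes=8, beta_shift=0.3,
                    expr_log2_effect=1.5, driver_genes={"IDH1": 0.9}),
        SubtypeSpec("rest", 0.7),
    ]
    cfg = CohortConfig(n_samples=60, n_genes=900, n_probes=400, subtypes=subs, seed=11)
    return generate_cohort(cfg)
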