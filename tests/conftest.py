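import warnings

import numpy as np
import pandas as pd
import pytest

from imodkit import ExpressionMatrix, log_center, simulate_compendium

# FastICA at dims above the true dimensionality legitimately hits the
# iteration cap on noise directions; keep test output readable.
warnings.filterwarnings(
    "ignore", message="FastICA did not converge", category=UserWarning
)


def expr(values, genes=None, samples=None, space="log_centered"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j + 1}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), space=space
    )


@pytest.fixture(scope="session")
def benchmark_sim():
    """Planted 10-module starvation compendium (300 genes, 60 samples)."""
    return simulate_compendium(
        n_genes=300,
        k_modules=10,
        genes_per_module=15,
        timepoints=[3, 4, 6, 8, 12],
        background_samples=30,
        seed=1,
    )


@pytest.fixture(scope="session")
def benchmark_x(benchmark_sim):
    meta = benchmark_sim["metadata"]
    ref = list(meta.loc[meta["is_reference"], "sample_id"])
    return log_center(benchmark_sim["tpm"], ref)
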