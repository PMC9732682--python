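import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from nuegrn import (
    ExpressionMatrix,
    GoldStandard,
    InferenceConfig,
    SimulationConfig,
    infer_grn,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def four_module_dataset():
    """200-gene dataset with 4 planted 50-gene modules at noise_sd 0.1."""
    cfg = SimulationConfig(
        n_genes=200,
        n_modules=4,
        module_sizes=[50] * 4,
        noise_sd=0.1,
        n_tfs=0,
        tf_out_degree=0,
        seed=1,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def grn_dataset():
    """Small dataset with planted TF->target edges for inference tests."""
    cfg = SimulationConfig(
        n_genes=100,
        n_modules=4,
        module_sizes=[25] * 4,
        n_tfs=10,
        tf_out_degree=5,
        noise_sd=0.1,
        seed=3,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def grn_edges(grn_dataset):
    """Ranked edges inferred once from the small planted-edge dataset."""
    return infer_grn(
        grn_dataset.expression,
        grn_dataset.tf_list,
        grn_dataset.expression.gene_ids,
        InferenceConfig(n_trees=100, seed=3),
    )


@pytest.fixture(scope="session")
def grn_gold(grn_dataset):
    return GoldStandard(
        validated_edges=set(grn_dataset.true_edges),
        assayed_tfs=set(grn_dataset.tf_list),
    )


def make_expression(values: np.ndarray, prefix: str = "G") -> ExpressionMatrix:
    """Wrap a raw genes x samples array in an ExpressionMatrix (no metadata)."""
    n_genes, n_samples = values.shape
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"{prefix}{i + 1:03d}" for i in range(n_genes)],
            columns=[f"S{j + 1:03d}" for j in range(n_samples)],
        )
    )
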