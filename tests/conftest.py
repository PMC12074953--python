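import numpy as np
import pandas as pd
import pytest

from enhmeth.blocks import block_beta
from enhmeth.core_io import BetaMatrix
from enhmeth.synthetic_data import SimulationConfig, simulate_methylation_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort shared by read-only tests."""
    config = SimulationConfig(
        seed=7,
        n_blocks=400,
        n_hyper=40,
        n_hypo=40,
        n_marker=40,
        type2_bias=0.0,
    )
    matrix, annotation, metadata, truth, blocks = simulate_methylation_cohort(config)
    return {
        "config": config,
        "matrix": matrix,
        "annotation": annotation,
        "metadata": metadata,
        "truth": truth,
        "blocks": blocks,
        "block_matrix": block_beta(matrix, blocks),
    }


def random_beta_matrix(rng, n_rows=20, n_cols=5, prefix="f"):
    values = rng.uniform(0.01, 0.99, size=(n_rows, n_cols))
    return BetaMatrix(
        pd.DataFrame(
            values,
            index=[f"{prefix}{i:04d}" for i in range(n_rows)],
            columns=[f"S{j:02d}" for j in range(n_cols)],
        )
    )
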