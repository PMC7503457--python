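from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from lncperturb.layers import ExpressionLayer
from lncperturb.synthetic import GeneratorConfig, generate_cohort

TOY_DIR = Path(__file__).parent / "data" / "toy"


@pytest.fixture(scope="session")
def toy_dir() -> Path:
    return TOY_DIR


@pytest.fixture(scope="session")
def small_cohort():
    """Small planted cohort reused by read-only tests."""
    config = GeneratorConfig(
        n_samples=60, n_planted=3, n_decoy_lnc=5, n_decoy_mir=5, n_decoy_mrna=5,
        seed=7,
    )
    return generate_cohort(config)


def make_layer(values, layer_class="mRNA", genes=None, samples=None, is_log2=True):
    """Build an ExpressionLayer from a 2-D array with generated identifiers."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"S{i + 1:03d}" for i in range(values.shape[1])]
    return ExpressionLayer(
        layer_class=layer_class,
        data=pd.DataFrame(values, index=genes, columns=samples),
        is_log2=is_log2,
    )
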