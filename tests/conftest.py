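import numpy as np
import pandas as pd
import pytest

from paspipe.pasquant import PASCountMatrix
from paspipe.simulate import SimulationConfig, generate_annotation


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=7, n_genes=12, frac_genes_with_ipa=0.5,
                            frac_genes_with_prompt=0.5, base_mean=25.0)


@pytest.fixture(scope="session")
def small_annotation(small_config):
    return generate_annotation(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_matrix(counts: np.ndarray, conditions, compartments=None) -> PASCountMatrix:
    """Wrap a plain array as a PASCountMatrix with generated metadata."""
    counts = np.asarray(counts)
    samples = [f"s{i}" for i in range(counts.shape[1])]
    meta = pd.DataFrame(
        {
            "condition": conditions,
            "compartment": compartments or ["nucleus"] * len(samples),
            "replicate": list(range(1, len(samples) + 1)),
        },
        index=pd.Index(samples, name="sample"),
    )
    df = pd.DataFrame(counts, columns=samples,
                      index=[f"site{i}" for i in range(counts.shape[0])])
    return PASCountMatrix(df, meta)
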