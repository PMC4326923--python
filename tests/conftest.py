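import numpy as np
import pandas as pd
import pytest

from agetraj.io import CountMatrix, NormalizedMatrix, SampleSheet
from agetraj.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def default_sim():
    """One default-config synthetic study shared across tests."""
    return simulate(SimConfig(seed=42))


@pytest.fixture(scope="session")
def small_sim():
    """A light study (60 genes per archetype) for wiring-level tests."""
    cfg = SimConfig(
        genes_per_archetype={a: 60 for a in ("flat", "linear_up", "linear_down",
                                             "rapid_decay", "u_shape", "bell_shape")},
        seed=7,
    )
    return simulate(cfg)


@pytest.fixture()
def tiny_counts():
    counts = pd.DataFrame(
        [[10, 0], [5, 5], [0, 1]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2"],
    )
    lengths = pd.Series([1000.0, 2000.0, 500.0], index=counts.index)
    return CountMatrix(counts=counts, gene_lengths=lengths)


@pytest.fixture()
def two_group_sheet():
    return SampleSheet(
        table=pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(1, 11)],
                "age_weeks": [5.0] * 5 + [39.0] * 5,
                "replicate": list(range(1, 6)) * 2,
            }
        )
    )


def norm_from_array(arr, genes=None, samples=None, log_scale=True) -> NormalizedMatrix:
    arr = np.asarray(arr, float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    return NormalizedMatrix(
        values=pd.DataFrame(arr, index=genes, columns=samples), log_scale=log_scale
    )
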