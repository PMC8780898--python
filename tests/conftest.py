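import numpy as np
import pandas as pd
import pytest

from phaseclear import CountMatrix, SimConfig, compute_fpkm, generate_counts, generate_truth


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_genes=400, seed=7)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return generate_truth(small_config)


@pytest.fixture(scope="session")
def small_counts(small_config, small_truth):
    return generate_counts(small_truth, small_config)


@pytest.fixture(scope="session")
def small_expr(small_counts):
    return compute_fpkm(small_counts)


def make_count_matrix(values, sample_meta=None, lengths=None):
    """Hand-built CountMatrix from a dict {sample_id: counts list}."""
    counts = pd.DataFrame(values)
    n = counts.shape[0]
    counts.index = pd.Index([f"g{i}" for i in range(n)], name="gene_id")
    if sample_meta is None:
        sample_meta = {
            sid: ("control", "DSG", i + 1, "rna") for i, sid in enumerate(counts.columns)
        }
    samples = pd.DataFrame(
        [(sid,) + tuple(meta) for sid, meta in sample_meta.items()],
        columns=["sample_id", "genotype", "stage", "replicate", "assay"],
    ).set_index("sample_id")
    genes = pd.DataFrame(
        {"length_nt": lengths if lengths is not None else np.full(n, 1000)},
        index=counts.index,
    )
    return CountMatrix(counts.astype(np.int64), samples, genes)


@pytest.fixture
def tiny_cm():
    return make_count_matrix({"s1": [1, 3], "s2": [2, 4]})
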