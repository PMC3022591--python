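import numpy as np
import pandas as pd
import pytest

from peptisig import GeneratorConfig, ReplicateMatrix, generate_dataset
from peptisig.containers import SampleMatrix

SMALL_CONFIG = GeneratorConfig(
    seed=11,
    n_features=80,
    sources=(("A", 10, 10), ("B", 10, 10), ("C", 6, 0)),
)


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced two-source dataset (80 features, 10/10 per source) for unit tests."""
    return generate_dataset(SMALL_CONFIG)


@pytest.fixture(scope="session")
def default_dataset():
    """Full-scale default-design dataset (637 features, A/B/C sources)."""
    return generate_dataset(GeneratorConfig(seed=101))


def toy_replicate_matrix(values, classes, sources=None, replicate_ids=None, features=None):
    """Hand-built ReplicateMatrix: ``values`` is (n_rows, n_features);
    classes/sources are per *sample*; rows sharing a sample_id are replicates."""
    values = np.asarray(values, dtype=float)
    n_samples = len(classes)
    n_rows = values.shape[0]
    reps = n_rows // n_samples
    assert reps * n_samples == n_rows
    sources = sources or ["A"] * n_samples
    features = features or [str(1000 + 10 * j) for j in range(values.shape[1])]
    sids = [f"s{i:02d}" for i in range(n_samples)]
    index = pd.MultiIndex.from_tuples(
        [(sids[i], f"r{r+1}") for i in range(n_samples) for r in range(reps)],
        names=["sample_id", "replicate_id"],
    )
    data = pd.DataFrame(values, index=index, columns=features)
    samples = pd.DataFrame(
        {"source": sources, "class": classes}, index=pd.Index(sids, name="sample_id")
    )
    return ReplicateMatrix(data, samples)


def toy_sample_matrix(values, classes, sources=None, features=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    sources = sources or ["A"] * n
    features = features or [str(1000 + 10 * j) for j in range(values.shape[1])]
    sids = [f"s{i:02d}" for i in range(n)]
    data = pd.DataFrame(values, index=pd.Index(sids, name="sample_id"), columns=features)
    samples = pd.DataFrame(
        {"source": sources, "class": classes}, index=pd.Index(sids, name="sample_id")
    )
    return SampleMatrix(data, samples)
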