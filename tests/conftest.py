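"""Shared fixtures: toy matrices and the (expensive) default synthetic dataset.

The default-design dataset and its score matrices are session-scoped so the
planted-truth recovery tests share one computation.
"""

import numpy as np
import pandas as pd
import pytest

from coexnet import (
    clr_z_matrix,
    correlation_matrix,
    mutual_information_matrix,
)
from coexnet.synthetic import (
    default_design,
    generate_annotation_map,
    generate_complex_benchmark,
    generate_dataset,
)

SEED = 1


@pytest.fixture(scope="session")
def default_dataset():
    """(matrix, truth) drawn from the default 600-gene design."""
    return generate_dataset(default_design(seed=SEED))


@pytest.fixture(scope="session")
def default_benchmark(default_dataset):
    _, truth = default_dataset
    return generate_complex_benchmark(truth)


@pytest.fixture(scope="session")
def default_annotations(default_dataset):
    _, truth = default_dataset
    return generate_annotation_map(truth, terms_per_module=2, background_term_rate=0.0)


@pytest.fixture(scope="session")
def default_pcc(default_dataset):
    m, _ = default_dataset
    return correlation_matrix(m, "pcc")


@pytest.fixture(scope="session")
def default_clr(default_dataset):
    m, _ = default_dataset
    z, _ = clr_z_matrix(mutual_information_matrix(m))
    return z


@pytest.fixture
def toy_matrix():
    """4 genes × 3 samples; the worked low-information-filter example."""
    return pd.DataFrame(
        [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [5.0, 5.0, 5.0], [0.0, 4.0, 8.0]],
        index=pd.Index(["A", "B", "C", "D"], name="gene"),
        columns=["s1", "s2", "s3"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)
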