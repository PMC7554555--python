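import numpy as np
import pytest
from threadpoolctl import threadpool_limits

# single-threaded BLAS: multi-threaded reductions reorder floating-point
# sums and break bitwise reproducibility of SVM fits across runs
_BLAS_LIMIT = threadpool_limits(limits=1)

from kinemid import (ClassificationTask, GeneratorParams, GridSearchSpec, ProtocolSpec,
                     generate_dataset, preprocess_dataset)

# Small protocol shared across test modules: 3 subjects, 3 sets x 3 blocks x
# 4 kicks per leg plus 2 maximal-intensity time points x 2 kicks.
TINY_PROTOCOL = ProtocolSpec(
    n_subjects=3, n_sets=3, blocks_per_set=3, kicks_per_block=4,
    k100_timepoints=2, k100_kicks_per_timepoint=2,
)


@pytest.fixture(scope="session")
def tiny_dataset():
    return generate_dataset(TINY_PROTOCOL, GeneratorParams(seed=11))


@pytest.fixture(scope="session")
def tiny_features(tiny_dataset):
    return preprocess_dataset(tiny_dataset)


@pytest.fixture(scope="session")
def fast_grid():
    """Coarse 3-point cost grid for tests that exercise the full task loop."""
    return GridSearchSpec(exponent_range=(-3.0, 5.0), exponent_step=4.0, inner_folds=2)


@pytest.fixture(scope="session")
def single_cost_grid():
    """Degenerate 1-point grid for tests where cost selection is irrelevant."""
    return GridSearchSpec(exponent_range=(0.0, 0.0), exponent_step=1.0, inner_folds=2)


def binomial_chance_band(n_classes: int, n_test: int, n_sd: float = 3.0) -> float:
    """Monte-Carlo tolerance (percent) around chance for permuted labels."""
    p = 1.0 / n_classes
    return 100.0 * n_sd * np.sqrt(p * (1 - p) / n_test)
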