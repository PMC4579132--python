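import numpy as np
import pytest

from semipnmf import ExpressionMatrix, PartialLabelSet, generate_toy
from semipnmf.data import UNLABELED
from semipnmf.factorization import FactorizationState


@pytest.fixture(scope="session")
def toy():
    """Default toy dataset: 30 samples, 3 dims, 3 classes, 9 labeled."""
    return generate_toy()


def random_instance(seed, n=6, m=4, r=2, n_labeled_per_class=1):
    """A random non-negative problem instance with a valid partial labeling."""
    rng = np.random.default_rng(seed)
    values = rng.uniform(0.1, 2.0, size=(n, m))
    assignment = np.full(n, UNLABELED, dtype=int)
    for j in range(r):
        for t in range(n_labeled_per_class):
            assignment[(j * n_labeled_per_class + t) % max(n - 1, 1)] = j
    data = ExpressionMatrix(
        values=values,
        sample_ids=[f"s{i}" for i in range(n)],
        gene_ids=[f"g{j}" for j in range(m)],
    )
    labels = PartialLabelSet(
        classes=[f"c{j}" for j in range(r)], assignment=assignment
    )
    return data, labels


def random_state(seed, n_u, m, r):
    rng = np.random.default_rng(seed)
    return FactorizationState(
        W=rng.uniform(0.05, 1.0, size=(r, m)),
        H_U=rng.uniform(0.05, 1.0, size=(n_u, r)),
    )
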