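import numpy as np
import pytest

from groupfa.em import MFAParams
from groupfa.preprocess import FeatureMatrix, GroupLabels
from groupfa.simulate import SyntheticSpec, generate


def random_params(rng, m=2, d=6, k=2, names=None):
    """Random well-conditioned model parameters for small instances."""
    loadings = rng.normal(scale=0.7, size=(m, d, k))
    means = rng.normal(scale=0.5, size=(m, d))
    psi = rng.uniform(0.2, 0.8, size=d)
    props = rng.dirichlet(np.full(m, 5.0))
    return MFAParams(loadings, means, psi, props, group_names=names)


def small_cohort(seed=0, n=200, m=2, d=6, k=2):
    """A generated cohort with its ground truth, for fit-level tests."""
    rng = np.random.default_rng(seed)
    params = random_params(rng, m=m, d=d, k=k)
    spec = SyntheticSpec(n, params, seed)
    X, labels, scores = generate(spec)
    return spec, X, labels, scores


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cohort():
    return small_cohort()


@pytest.fixture
def toy_matrix():
    values = np.array([[1.0, 2.0], [3.0, 5.0], [2.0, 4.0], [4.0, 7.0]])
    return FeatureMatrix(values, ["a", "b"], ["s1", "s2", "s3", "s4"])


@pytest.fixture
def toy_labels():
    return GroupLabels([1, 1, 2, 2], ["ctrl", "case"])
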