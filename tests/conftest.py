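import numpy as np
import pytest

import poserank as pr

#: Published worked-example values carried by the packaged fixtures.
PUBLISHED_WEIGHTS = (0.633, 0.228, 0.044, 0.095)
PUBLISHED_EXPERT_CRS = (0.09, 0.09, 0.08, 0.08)
PUBLISHED_GROUP_CR = 0.083


@pytest.fixture(scope="session")
def expert_pcms():
    return pr.load_expert_pcms()


@pytest.fixture(scope="session")
def group_pcm_printed():
    return pr.load_group_pcm()


@pytest.fixture(scope="session")
def obidoxime_poses():
    return pr.load_fixture_poses("obidoxime")


@pytest.fixture(scope="session")
def isatin_poses():
    return pr.load_fixture_poses("isatin-O")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_reciprocal_pcm(rng, n):
    """Random positive reciprocal matrix (not necessarily consistent)."""
    a = np.ones((n, n))
    iu = np.triu_indices(n, k=1)
    vals = np.exp(rng.normal(0.0, 0.8, size=len(iu[0])))
    a[iu] = vals
    a[(iu[1], iu[0])] = 1.0 / vals
    return pr.PairwiseComparisonMatrix(tuple(f"c{i}" for i in range(n)), a)


def consistent_pcm(w):
    w = np.asarray(w, dtype=float)
    a = np.outer(w, 1.0 / w)
    np.fill_diagonal(a, 1.0)
    return pr.PairwiseComparisonMatrix(
        tuple(f"c{i}" for i in range(len(w))), a)
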