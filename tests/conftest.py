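import numpy as np
import pytest

from cmflv import (
    LVParams,
    PhantomSpec,
    PriorTrainingSet,
    make_phantom,
    sample_parameter_grid,
    train_prior,
)
from cmflv.shape_prior import descriptor_from_params


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_default():
    """Noiseless default phantom: (volume, truth mask, defect fraction)."""
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def phantom_hard():
    """Two-level (no soft edge) phantom for exact self-consistency checks."""
    return make_phantom(PhantomSpec(soft_edge=0.0))


@pytest.fixture(scope="session")
def prior_bank():
    """Candidate LV shapes plus a kernel prior trained on their descriptors."""
    cands = sample_parameter_grid(counts={"a": 3, "b": 2, "c": 3, "d": 2})
    Z = np.array([descriptor_from_params(p) for p in cands])
    std = np.where(Z.std(axis=0) > 0, Z.std(axis=0), 1.0)
    Zs = (Z - Z.mean(axis=0)) / std
    model = train_prior(PriorTrainingSet(Zs))
    return cands, model, Zs
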