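import numpy as np
import pytest

from gliocascade.phantom import PhantomSpec, generate_case
from gliocascade.preprocess import PreprocessConfig, preprocess_case


@pytest.fixture(scope="session")
def hgg_case():
    """One deterministic high-grade phantom at full (64^3) resolution."""
    return generate_case(PhantomSpec.for_grade("HGG", shape=(64, 64, 64)), seed=123)


@pytest.fixture(scope="session")
def lgg_case():
    return generate_case(PhantomSpec.for_grade("LGG", shape=(64, 64, 64)), seed=321)


@pytest.fixture(scope="session")
def hgg_preprocessed(hgg_case):
    """(tensor (4,32,32,32), labels (32,32,32)) of the HGG phantom."""
    tensor, labels = preprocess_case(hgg_case.scan, hgg_case.truth, PreprocessConfig())
    return tensor, labels


@pytest.fixture(scope="session")
def tiny_preprocessed(hgg_case):
    """Small 16^3 version for fast network tests."""
    cfg = PreprocessConfig(target_shape=(16, 16, 16))
    tensor, labels = preprocess_case(hgg_case.scan, hgg_case.truth, cfg)
    return tensor, labels


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
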