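import numpy as np
import pytest

from gremnet.synthetic import SimParams, generate_truth
from gremnet.types import ExpressionMatrix


@pytest.fixture
def tiny_counts():
    """2 samples x 3 genes counts matrix."""
    return ExpressionMatrix(
        np.array([[1.0, 1.0, 2.0], [0.0, 3.0, 5.0]]),
        ["s1", "s2"],
        ["g1", "g2", "g3"],
        layer="counts",
    )


@pytest.fixture(scope="session")
def small_bundle():
    """Small signed ground-truth system shared across read-only tests."""
    params = SimParams(
        n_tf=6, n_gene=60, n_sample_wt=80, n_sample_ko=80, noise_sd=0.2
    )
    return generate_truth(params, seed=11)


@pytest.fixture(scope="session")
def exact_bundle():
    """Noiseless unit-weight system: the exact-model identifiability case."""
    params = SimParams(
        n_tf=6,
        n_gene=60,
        n_sample_wt=40,
        n_sample_ko=40,
        noise_sd=0.0,
        weight_mode="unit",
        prior_fpr=0.0,
        prior_fnr=0.0,
    )
    return generate_truth(params, seed=5)
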