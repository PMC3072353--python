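import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rbratio.io import ExpressionMatrix, PhenotypeLabels

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_matrix():
    """3 genes x 4 samples with distinct, hand-chosen values."""
    return ExpressionMatrix(
        gene_ids=("CCND1", "CDKN2A", "GAPDH"),
        sample_ids=("s1", "s2", "s3", "s4"),
        values=np.array(
            [
                [0.5, 0.6, -0.4, -0.5],
                [-0.3, -0.2, 0.4, 0.3],
                [0.01, 0.02, 0.0, -0.01],
            ]
        ),
    )


@pytest.fixture
def tiny_labels():
    return PhenotypeLabels({"s1": 1, "s2": 1, "s3": 0, "s4": 0})
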