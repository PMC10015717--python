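import hypothesis
import numpy as np
import pandas as pd
import pytest

from devstab import ExpressionMatrix, GeneratorConfig, SampleMetadata, generate

hypothesis.settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=30
)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """One small synthetic dataset shared across tests (defaults, 800 genes)."""
    cfg = GeneratorConfig(seed=11, n_genes=800)
    return generate(cfg)


@pytest.fixture
def toy_matrix():
    """3 genes x 4 samples log-scale matrix with hand-checkable values."""
    data = pd.DataFrame(
        {
            "s1": [0.0, 1.0, 2.0],
            "s2": [0.0, 3.0, 2.5],
            "s3": [1.0, 2.0, 0.5],
            "s4": [1.0, 0.0, 1.5],
        },
        index=pd.Index(["gA", "gB", "gC"], name="gene_id"),
    )
    return ExpressionMatrix(data, units="log10")


def make_metadata(rows):
    """Build SampleMetadata from (sample_id, stage, group, sex, sibling, rep_of)."""
    cols = ["sample_id", "stage", "group", "sex", "sibling_group", "replicate_of"]
    return SampleMetadata(pd.DataFrame(rows, columns=cols))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
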