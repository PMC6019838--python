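import numpy as np
import pytest

from caprilinc.pipeline import default_hexamer_table
from caprilinc.simulate import SimConfig, generate_annotation, generate_expression


@pytest.fixture(scope="session")
def noise_free_sim():
    """One noise-free synthetic dataset shared across the suite."""
    config = SimConfig(seed=3, noise_sd=0.0)
    reference, candidates, truth, sequences = generate_annotation(config)
    features = list(candidates.transcripts) + sorted(reference.gene_index)
    matrix, metadata = generate_expression(config, features, truth)
    return {
        "config": config,
        "reference": reference,
        "candidates": candidates,
        "truth": truth,
        "sequences": sequences,
        "features": features,
        "matrix": matrix,
        "metadata": metadata,
    }


@pytest.fixture(scope="session")
def hexamer_table():
    return default_hexamer_table(seed=12345, n=100, length=500)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
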