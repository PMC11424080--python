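import numpy as np
import pandas as pd
import pytest

from stagediv.core_io import ExpressionMatrix, SampleMetadata
from stagediv.synthetic_data import SimulationConfig, generate_dataset

STAGES = ["third_instar", "fifth_instar", "early_pupa", "late_pupa", "adult"]


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_matrix():
    """3 genes x 10 samples (5 stages x 1 host x 2 replicates), raw TPM."""
    samples = [
        SampleMetadata(f"{stage}_r{rep}", stage, "incarnata", rep)
        for stage in STAGES for rep in (1, 2)
    ]
    gen = np.random.default_rng(7)
    values = pd.DataFrame(
        gen.uniform(0.0, 50.0, (3, len(samples))),
        index=["gA", "gB", "gC"],
        columns=[s.sample_id for s in samples])
    return ExpressionMatrix(values, samples, STAGES, transformed=False)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small but fully structured synthetic dataset (session-wide)."""
    cfg = SimulationConfig(seed=11, n_groups=15, n_singletons=40)
    return generate_dataset(cfg, tmp_path_factory.mktemp("bundle"))
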