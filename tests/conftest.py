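import numpy as np
import pytest
from hypothesis import settings

from nprescribe.experiments import RunConfig, run_pipeline
from nprescribe.models import ModelConfig
from nprescribe.synthetic import GeneratorConfig, generate_field_table

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_table():
    """A small generated field table with its true response."""
    cfg = GeneratorConfig(n_samples=400, seed=11)
    return generate_field_table(cfg)


@pytest.fixture(scope="session")
def clean_table():
    """No missingness, no duplicates — for tests needing complete data."""
    cfg = GeneratorConfig(
        n_samples=400, seed=12, missing_rate_per_feature=0.0, duplicate_rate=0.0
    )
    return generate_field_table(cfg)


@pytest.fixture(scope="session")
def pipeline_result():
    """One end-to-end pipeline run on a small dataset (tree model only,
    reduced forest for speed)."""
    cfg = RunConfig(
        generator=GeneratorConfig(n_samples=1200, seed=5),
        model_candidates=(ModelConfig(family="tree_ensemble", n_trees=60, seed=0),),
    )
    return run_pipeline(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
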