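import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_dataset():
    """A modest synthetic dataset exercising every pipeline stage."""
    from cardiorisk import SyntheticConfig, generate
    from cardiorisk.io import Concern

    cfg = SyntheticConfig(
        n_per_concern={
            Concern.MOST: 60,
            Concern.LESS: 80,
            Concern.AMBIGUOUS: 20,
            Concern.NO: 60,
        },
        seed=7,
    )
    return generate(cfg)


@pytest.fixture
def classified(small_dataset, tmp_path):
    from cardiorisk import parse_dictrank_table, run_pipeline
    from cardiorisk.pipeline import annotations_from_frame

    path = tmp_path / "dictrank.csv"
    small_dataset.dictrank.to_csv(path, index=False)
    records, _ = parse_dictrank_table(path)
    annotations = annotations_from_frame(small_dataset.annotations)
    return run_pipeline(records, annotations)
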