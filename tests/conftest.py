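import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cellsift import SyntheticConfig, generate_dataset
from cellsift.pipeline import RunConfig, run_pipeline

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_dataset():
    """The generator's default study conditions (5 genes per enriched class,
    10 negatives, two sections, noise-free)."""
    return generate_dataset(SyntheticConfig())


@pytest.fixture(scope="session")
def tiny_dataset():
    return generate_dataset(SyntheticConfig(
        genes_per_class=(2, 2, 2, 3), image_size=64, seed=3,
    ))


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline run at the default study conditions, shared by the
    end-to-end classification and ranking-traceback tests."""
    out = tmp_path_factory.mktemp("pipeline")
    config = RunConfig(
        out_dir=str(out),
        words_single=64,
        words_combined=32,
        tasks=[["N-vs-Neg", 1.5], ["N-vs-O", 1.5]],
        sections=["coronal", "combined"],
        n_reps=30,
        ranking={"task": "N-vs-O", "threshold": 1.5, "section": "coronal",
                 "subsamples": 100, "top": 10},
        seed=0,
    )
    report = run_pipeline(config)
    return config, report


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
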