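import numpy as np
import pytest

from swiddenscape.pipeline import PipelineParams, run_pipeline
from swiddenscape.synthetic import GeneratorConfig, generate_landscape


def small_config(seed: int = 7, **over) -> GeneratorConfig:
    """A fast, fully valid landscape: 12 small fields over an 18-yr record."""
    kw = dict(n_fields=12, n_communities=5, pixels_per_field=(2, 4),
              time_span=(1992.5, 2010.6), census_year=2009.6, seed=seed)
    kw.update(over)
    return GeneratorConfig(**kw)


@pytest.fixture(scope="session")
def small_truth():
    return generate_landscape(small_config())


@pytest.fixture(scope="session")
def small_report():
    return run_pipeline(small_config(), PipelineParams(n_sample_points=1500))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
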