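import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_table():
    from mitochar.datasets import load_reference_annotation

    return load_reference_annotation()


@pytest.fixture(scope="session")
def synthetic_bundle():
    """Default synthetic genome (seed 1): (genome, annotation, manifest)."""
    from mitochar.synthetic_data import default_spec, generate_genome

    return generate_genome(default_spec(seed=1))
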