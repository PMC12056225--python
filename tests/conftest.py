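import pytest
from hypothesis import HealthCheck, settings

from vpptbench import AnnotatedVariant, Consequence, VariantKey, get_registry, load_reference_metrics

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def registry():
    return get_registry()


@pytest.fixture(scope="session")
def reference_metrics():
    return load_reference_metrics()


def make_variant(
    pos: int,
    cohort: str = "T",
    ref: str = "A",
    alt: str = "G",
    consequence: Consequence = Consequence.missense,
    **kwargs,
) -> AnnotatedVariant:
    """Terse AnnotatedVariant builder for tests."""
    return AnnotatedVariant(
        key=VariantKey("1", pos, ref, alt),
        cohort=cohort,
        consequence=consequence,
        **kwargs,
    )
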