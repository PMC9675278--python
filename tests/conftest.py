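import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def validation_cohort():
    """The deterministic 169-sample validation cohort with fixture calls."""
    from methmark.samples import validation_cohort as _vc

    return _vc()


@pytest.fixture(scope="session")
def planted_dataset():
    """One simulated paired-array dataset with 9 planted genes."""
    from methmark.simulate import ArraySimConfig, generate_array_dataset

    return generate_array_dataset(ArraySimConfig(seed=1))
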