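import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from combsec import FixtureSpec, StateReplicates, TreatmentCode, generate_plate

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def table_layout_plate():
    """Default design: 3 drugs x 3 stimulations x 23 proteins = 87 wells."""
    return generate_plate(FixtureSpec(seed=11))


@pytest.fixture
def small_spec():
    """One stimulation, 6 proteins, 3 replicates everywhere; T1 fully restores."""
    return FixtureSpec(
        n_stimulations=1,
        d=6,
        replicates=StateReplicates.uniform(3),
        treatment_effects={TreatmentCode([1]): 1.0},
        seed=5,
    )


@pytest.fixture
def small_plate(small_spec):
    return generate_plate(small_spec)


@pytest.fixture
def noise_free_spec():
    return FixtureSpec(
        n_stimulations=1,
        d=5,
        replicates=StateReplicates.uniform(3),
        treatment_effects={
            TreatmentCode([1]): 1.0,
            TreatmentCode([1, 2]): 0.5,
        },
        noise_sd=0.0,
        blank_noise=0.0,
        seed=3,
    )
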