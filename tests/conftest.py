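import numpy as np
import pytest

from ovuconfirm.simulate import (
    CycleParams,
    PlatformErrorModel,
    default_platform_models,
    simulate_cohort,
)


@pytest.fixture
def noise_free_params() -> CycleParams:
    """Deterministic cycle template: no day-to-day or between-cycle noise."""
    return CycleParams(day_cv=0.0, follicular_gcv=0.0, creatinine_cv=0.0)


@pytest.fixture
def identity_platforms() -> dict[str, PlatformErrorModel]:
    """Platforms that read the true concentrations back unchanged."""
    return {
        "pdg": PlatformErrorModel(analyte="pdg"),
        "p4_platform_a": PlatformErrorModel(analyte="p4"),
    }


@pytest.fixture
def noisy_cohort():
    """A small daily cohort with the default platform error models."""
    return simulate_cohort(
        8, 0, CycleParams(), default_platform_models(), 0.0, master_seed=11
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
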