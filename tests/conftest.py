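import numpy as np
import pytest

from stringentflow import (
    GaussianComponent,
    LognormalComponent,
    MixtureModel,
    SyntheticScenario,
    generate_flow_timecourse,
)

# fitted invariant components for the mprA reporter, reused across suites
MPRA_GAUSS = GaussianComponent(center=97.3366, width=103.0731)
MPRA_LOGN = LognormalComponent(log_mean=5.95526, log_sd=0.17618)


@pytest.fixture
def mpra_model() -> MixtureModel:
    return MixtureModel(
        gaussian=MPRA_GAUSS,
        lognormal=MPRA_LOGN,
        weights={"18h": (0.6, 0.4)},
    )


@pytest.fixture
def small_timecourse():
    """Three-time-point synthetic course, 5,000 events each (fast suites)."""
    scenario = SyntheticScenario(
        schedule={"12h": 0.1, "20h": 0.5, "28h": 0.9},
        events_per_timepoint=5_000,
        seed=11,
    )
    dataset, truth = generate_flow_timecourse(scenario)
    return dataset, truth
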