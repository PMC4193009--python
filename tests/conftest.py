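import numpy as np
import pytest

import dynconn as dc


@pytest.fixture(scope="session")
def small_subject():
    """One fast synthetic subject: 2 runs, 6 events, no drift/AR."""
    spec = dc.SimulationSpec(
        n_regions=6,
        n_runs=2,
        n_events=6,
        min_gap=72,
        ar_coefficient=0.0,
        drift_amplitude=0.0,
        base_covariance=dc.equicorrelation(6, 0.3),
        condition_effects={
            "before": dc.equicorrelation(6, 0.5) - dc.equicorrelation(6, 0.3)
        },
        seed=11,
        subject_id="sub-small",
    )
    series, events = dc.simulate_subject(spec)
    return spec, series, events


@pytest.fixture(scope="session")
def study_subject():
    """One subject under the full study conditions (14 regions)."""
    spec = dc.study_cohort_specs(1, seed=41)[0]
    series, events = dc.simulate_subject(spec)
    return spec, series, events


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
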