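import pytest

from reachadapt import (
    LearnerParams,
    SimConfig,
    build_schedule,
    minjerk_profile,
    run_subject,
)


@pytest.fixture(scope="session")
def default_schedule():
    return build_schedule(seed=1)


@pytest.fixture(scope="session")
def default_profile():
    cfg = SimConfig()
    return minjerk_profile(cfg.distance, cfg.duration, cfg.dt)


@pytest.fixture(scope="session")
def noiseless_averager(default_schedule):
    return run_subject(
        default_schedule,
        learner="averager",
        params=LearnerParams(noise_sd=0.0),
        seed=3,
    )


@pytest.fixture(scope="session")
def noiseless_extrapolator(default_schedule):
    return run_subject(
        default_schedule,
        learner="extrapolator",
        params=LearnerParams(noise_sd=0.0),
        seed=3,
    )
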