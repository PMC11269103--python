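"""Shared fixtures: desk-scale closed-loop runs reused across tests."""

import pytest

from pvloop import (
    ControllerConfig,
    HeartParams,
    RampProtocol,
    analyze_ramp,
    concat_traces,
    run_protocol,
)

#: Desk-scale dwell (s) used for test ramps; the assessment protocol records
#: 60 s per level, which only adds identical steady-state beats.
TEST_DWELL = 5.0


@pytest.fixture(scope="session")
def default_cfg():
    return ControllerConfig()


@pytest.fixture(scope="session")
def ramp_protocol():
    return RampProtocol(dwell=TEST_DWELL)


@pytest.fixture(scope="session")
def heart_27():
    return HeartParams(Ees_true=2.7)


@pytest.fixture(scope="session")
def ramp_traces_27(default_cfg, ramp_protocol, heart_27):
    """Noise-free default ramp (10->25 mmHg) at Ees_true = 2.7 mmHg/mL."""
    return run_protocol(default_cfg, ramp_protocol, heart_27)


@pytest.fixture(scope="session")
def ramp_trace_27(ramp_traces_27):
    return concat_traces(ramp_traces_27)


@pytest.fixture(scope="session")
def ramp_result_27(ramp_trace_27):
    return analyze_ramp(ramp_trace_27)
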