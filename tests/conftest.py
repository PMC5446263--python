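import numpy as np
import pytest

from gnrhsim.gates import GateSpec, simulate_reporter
from gnrhsim.network import NetworkParams, simulate_network
from gnrhsim.pulses import PulseProtocol
from gnrhsim.scan import DEFAULT_PERIOD_GRID, frequency_scan

#: solver tolerances used by the slower, shared fixtures
RTOL, ATOL = 1e-8, 1e-10

LADDER = (0.03125, 0.0625, 0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0)
GATE_INT_MULTS = (0.001, 0.5, 1.0)
DOSES = (1e-11, 1e-10, 1e-9, 1e-8, 1e-7, 1e-6)


@pytest.fixture(scope="session")
def default_network():
    return NetworkParams()


@pytest.fixture(scope="session")
def ladder_scans(default_network):
    """Ca/PLC frequency scans over the internalization doubling ladder.

    Shared by the period-optimum and bell-threshold acceptance tests;
    this is the expensive fixture of the suite (77 pulse-train runs).
    """
    scans = {}
    for mult in LADDER:
        params = default_network.with_multipliers(int_mult=mult)
        scans[mult] = frequency_scan(
            params, periods=DEFAULT_PERIOD_GRID, width=5.0, amplitude=1e-7,
            horizon=960.0, channels=("Ca", "PLC"), rtol=RTOL, atol=ATOL)
    return scans


@pytest.fixture(scope="session")
def gate_timecourses(default_network):
    """Network time courses feeding the transcription-gate shape tests."""
    freq, dose = {}, {}
    for mult in GATE_INT_MULTS:
        params = default_network.with_multipliers(int_mult=mult)
        for period in DEFAULT_PERIOD_GRID:
            proto = (PulseProtocol(1e-7, 5.0, period, 960.0) if period > 5
                     else PulseProtocol(1e-7, 960.0, 960.0, 960.0))
            freq[(mult, period)] = simulate_network(
                params, proto, rtol=RTOL, atol=ATOL)
        for conc in DOSES:
            proto = PulseProtocol(conc, 960.0, 960.0, 960.0)
            dose[(mult, conc)] = simulate_network(
                params, proto, rtol=RTOL, atol=ATOL)
    return {"freq": freq, "dose": dose}


@pytest.fixture(scope="session")
def reporter_aucs(gate_timecourses):
    """960-min reporter AUCs for every gate mode, condition and axis."""
    out = {"freq": {}, "dose": {}}
    for mode in ("ERK_DT", "NFAT_DT", "AND", "OR", "COOP"):
        gate = GateSpec(mode=mode)
        for mult in GATE_INT_MULTS:
            out["freq"][(mode, mult)] = np.array([
                simulate_reporter(gate_timecourses["freq"][(mult, T)], gate)[1]
                for T in DEFAULT_PERIOD_GRID])
            out["dose"][(mode, mult)] = np.array([
                simulate_reporter(gate_timecourses["dose"][(mult, c)], gate)[1]
                for c in DOSES])
    return out
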