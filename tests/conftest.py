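import numpy as np
import pytest

from phasekit import (
    SimConfig,
    VdPParams,
    adjoint_sensitivity,
    make_fixture_three_oscillators,
    run_circuit_benchmark,
    simulate_circuit,
)


@pytest.fixture(scope="session")
def three_osc():
    """Simulated three-oscillator benchmark network (moderate length)."""
    cfg = SimConfig(dt=0.01, n_steps=60_000, seed=11, burn_in=0)
    phases, truth = make_fixture_three_oscillators(cfg)
    return phases, truth


@pytest.fixture(scope="session")
def adjoint_osc1():
    """Adjoint phase sensitivity of the first (autonomous) circuit unit."""
    return adjoint_sensitivity(
        VdPParams.same_frequency().uncoupled(), oscillator=1, n_grid=128
    )


@pytest.fixture(scope="session")
def vdp_traj():
    """Short noiseless trajectory of the coupled same-frequency circuit."""
    return simulate_circuit(VdPParams.same_frequency(), 3.0, 1.0 / 15000.0)


@pytest.fixture(scope="session")
def circuit_report():
    """Full cross-frequency circuit benchmark at reduced duration."""
    return run_circuit_benchmark(
        preset="cross-freq", duration=10.0, fs=15000.0, noise_sd=0.0, seed=0
    )
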