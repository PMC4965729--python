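import pytest

from delayloop import SimulationConfig, run_closed_loop


@pytest.fixture(scope="session")
def compensated_run():
    """Full 5 s compensated closed-loop run with the 10 ms constant delay.

    Shared across estimator-convergence, slip and delay-recovery tests to
    avoid repeating the simulation.
    """
    return run_closed_loop(SimulationConfig(scenario="compensated_constant_delay"))


@pytest.fixture(scope="session")
def uncompensated_run():
    """Matching run with estimator and predictor disabled (raw delayed error)."""
    return run_closed_loop(SimulationConfig(scenario="uncompensated_delay"))
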