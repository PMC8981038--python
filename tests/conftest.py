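"""Shared (session-scoped) simulation fixtures.

The microcircuit experiments are the expensive part of the suite, so each
configuration is simulated once and shared by every test that inspects it.
Seed counts are scaled down from the reference protocol (40 realizations)
to keep the suite fast; the asserted properties are sign- and
ordering-level and stable at these sizes.
"""

import pytest

import boldsim.experiments as ex


@pytest.fixture(scope="session")
def hyp_pulse():
    """All six coupling monitors, 100 ms x5 Poisson pulse, 2 seeds."""
    return ex.run_hypothesis_comparison("ABCDEF", "pulse", n_seeds=2, seed=7)


@pytest.fixture(scope="session")
def hyp_sustained():
    """Two-input monitors under a 20 s x1.2 stimulus, 3 seeds."""
    return ex.run_hypothesis_comparison("DEF", "sustained", n_seeds=3,
                                        seed=7, total_ms=32_000.0)


@pytest.fixture(scope="session")
def pulse_rest():
    """Resting-state runs (no stimulus), normalized + raw monitors, 3 seeds."""
    return ex.run_pulse_experiment(n_seeds=3, with_stimulus=False, seed=7)


@pytest.fixture(scope="session")
def pulse_stim():
    """Stimulated runs (100 ms x5 pulse), normalized + raw monitors, 2 seeds."""
    return ex.run_pulse_experiment(n_seeds=2, with_stimulus=True, seed=7)
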