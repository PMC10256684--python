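import numpy as np
import pytest

from surroundkit import SimulatorConfig, build_rate_table, simulate_session


@pytest.fixture(scope="session")
def default_config():
    return SimulatorConfig()


@pytest.fixture(scope="session")
def session_recording(default_config):
    """One full simulated session (all three protocols, baseline + drug)."""
    return simulate_session(default_config, seed=11, site_id="fix_site")


@pytest.fixture(scope="session")
def session_rate_table(session_recording):
    return build_rate_table(session_recording)


def poisson_rate_samples(rng, expected_rate, n_reps, count_window_s=0.15,
                         baseline_window_s=0.2, spont_rate=10.0):
    """Baseline-subtracted rate samples with the simulator's noise structure.

    Lightweight stand-in for full session simulation in tests that only
    need per-repetition rates: Poisson counts in the count and baseline
    windows, converted and subtracted exactly as the rates module does.
    """
    evoked = rng.poisson((expected_rate + spont_rate) * count_window_s, n_reps)
    base = rng.poisson(spont_rate * baseline_window_s, n_reps)
    return evoked / count_window_s - base / baseline_window_s
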