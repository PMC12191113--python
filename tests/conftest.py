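"""Shared fixtures: small synthetic sessions generated once per run."""

import pytest

from gpekit import synth


@pytest.fixture(scope="session")
def small_session():
    """30 trials, 6 neurons (2 per cluster), with eye trace and waveforms."""
    cfg = synth.default_choice(seed=2, n_neurons_per_cluster=(2, 2, 2),
                               n_trials=30, include_eye=True)
    return synth.generate_session(cfg)


@pytest.fixture(scope="session")
def behavioral_session():
    """150 trials, no neurons, with eye trace — behavior-only testing."""
    cfg = synth.default_choice(seed=3, n_neurons_per_cluster=(0, 0, 0),
                               n_trials=150, include_eye=True)
    return synth.generate_session(cfg)


@pytest.fixture(scope="session")
def medium_session():
    """240 trials, 24 neurons (8 per cluster) — population analyses."""
    cfg = synth.default_choice(seed=7, n_neurons_per_cluster=(8, 8, 8),
                               n_trials=240, include_waveforms=False)
    return synth.generate_session(cfg)
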