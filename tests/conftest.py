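"""Shared fixtures: small synthetic sessions generated at test time."""

import numpy as np
import pytest

from ecogest import io, preprocess, synth


def small_config(**overrides) -> synth.SynthConfig:
    """A desk-scale session: 8 channels at 1 kHz, 30 trials, planted
    high-gamma/high-band modulation on channels 2 and 5."""
    defaults = dict(
        n_channels=8,
        fs=1000.0,
        n_trials=30,
        informative_channels=(2, 5),
        effect_size=3.0,
        seed=11,
    )
    defaults.update(overrides)
    return synth.SynthConfig(**defaults)


@pytest.fixture(scope="session")
def small_session():
    cfg = small_config()
    rec, glove, truth = synth.generate_session(cfg)
    return cfg, rec, glove, truth


@pytest.fixture(scope="session")
def small_features(small_session):
    cfg, rec, glove, truth = small_session
    onsets = io.detect_trial_onsets(rec.events, glove, cfg.glove_threshold)
    ds = preprocess.session_features(rec, onsets)
    return ds, truth


@pytest.fixture(scope="session")
def null_features():
    """Features from a session with no planted modulation (effect_size 1)."""
    cfg = small_config(effect_size=1.0, seed=5)
    rec, glove, truth = synth.generate_session(cfg)
    onsets = io.detect_trial_onsets(rec.events, glove, cfg.glove_threshold)
    ds = preprocess.session_features(rec, onsets)
    return ds, truth


def planted_columns(ds, truth) -> list[int]:
    return sorted(
        ds.feature_names.index(f"ch{c}_band{b}") for c, b in truth.planted_features
    )
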