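"""Shared fixtures: small seeded sessions and epochs built at run time."""

from __future__ import annotations

import numpy as np
import pytest

from erdswitch.io_epochs import EpochSet
from erdswitch.session_model import (
    Condition,
    SessionPlan,
    build_sequence,
)

#: Desk-scale sampling rate used throughout the tests: an integer divisor of
#: the acquisition default that keeps the Welch bins at exactly 4 Hz spacing.
FS = 500.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def short_plan() -> SessionPlan:
    """Two-sequence phase-2 plan (9 attempted + 9 none trials)."""
    events = build_sequence(
        Condition("attempted", 2), t0=10.0, sequence_index=0
    ) + build_sequence(Condition("none", 2), t0=85.0, sequence_index=1)
    return SessionPlan(phase=2, events=events, sample_rate_hz=FS, seed=0)


@pytest.fixture
def noise_epochs(rng) -> EpochSet:
    """12 trials of plain white noise, 8 channels, [-1, 6) s at FS."""
    n = int(7 * FS)
    channels = ("C3", "C4", "Cz", "F3", "F4", "P3", "P4", "T7")
    labels = [Condition("attempted", 2) if i % 2 else Condition("none", 2) for i in range(12)]
    return EpochSet(
        data=rng.standard_normal((12, len(channels), n)),
        times=-1.0 + np.arange(n) / FS,
        labels=labels,
        sample_rate_hz=FS,
        channel_labels=channels,
    )


@pytest.fixture
def separable_features(rng):
    """Two well-separated Gaussian clusters with string labels."""
    X = np.vstack(
        [rng.normal(-2.0, 0.5, (40, 6)), rng.normal(2.0, 0.5, (40, 6))]
    )
    y = np.array(["none"] * 40 + ["attempted"] * 40)
    return X, y
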