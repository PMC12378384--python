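"""Shared fixtures: small synthetic sessions with known ground truth."""

import numpy as np
import pytest

from breathturn import synthio
from breathturn.resp_preproc import RespirationTrace


@pytest.fixture(scope="session")
def conversation():
    """Five minutes of synthetic turn-taking (fixed seed)."""
    return synthio.generate_conversation(300.0, seed=11)


@pytest.fixture(scope="session")
def respiration(conversation):
    """Respiration trace + ground truth coupled to the fixture conversation."""
    return synthio.generate_respiration(conversation, seed=12)


@pytest.fixture()
def sine_trace():
    """Unit sine, period 3 s, 30 s at 200 Hz."""
    rate = 200.0
    t = np.arange(int(30 * rate) + 1) / rate
    return RespirationTrace(samples=np.sin(2 * np.pi * t / 3.0), rate=rate)
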