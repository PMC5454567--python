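import numpy as np
import pandas as pd
import pytest

from legdose import ParticipantModel, ProtocolSpec, simulate_protocol

START = pd.Timestamp("2026-01-05T09:00:00")
WEEK_START = pd.Timestamp("2026-01-05")


@pytest.fixture
def participant() -> ParticipantModel:
    return ParticipantModel()


@pytest.fixture
def dosed_session(participant):
    """One noisy 30-minute dosed calibration session."""
    spec = ProtocolSpec(kind="dosed_mict", seed=11)
    return simulate_protocol(spec, participant, START)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
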