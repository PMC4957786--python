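import numpy as np
import pytest

from prefshift.data import ParticipantDataset, Trial
from prefshift.models import OptionPair
from prefshift.social import PSParams
from prefshift.task import TaskConfig, simulate_participant


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cfg():
    """Task configuration with a short phase 3; protocol otherwise standard."""
    return TaskConfig(phase3_blocks=2)


@pytest.fixture(scope="session")
def ps_agent():
    return PSParams(m_s=-4.5, u_s=1.0, sigma_r=1.0, tau_o=1.1, xi=0.02)


@pytest.fixture(scope="session")
def simulated_participant(ps_agent, small_cfg):
    return simulate_participant(
        ps_agent, small_cfg, np.random.default_rng(7), participant_id="fix0", age=18.0
    )


def make_pair(theta: float, R0: float = 1.0, ratio: float = 3.0) -> OptionPair:
    """Option pair with a prescribed indifference point theta = ln[(RD/R0-1)/D]."""
    D = (ratio - 1.0) * np.exp(-theta)
    return OptionPair(R0=R0, RD=R0 * ratio, D=float(D))


@pytest.fixture
def toy_dataset():
    """Hand-built six-trial dataset spanning all phases and roles."""
    trials = [
        Trial(phase=1, index=0, role="self", pair=make_pair(-4.0), choice=1),
        Trial(phase=1, index=1, role="self", pair=make_pair(-5.0), choice=0),
        Trial(phase=2, index=2, role="other", pair=make_pair(-3.0), choice=1,
              other_choice=1, feedback="correct"),
        Trial(phase=2, index=3, role="other", pair=make_pair(-6.0), choice=1,
              other_choice=0, feedback="incorrect"),
        Trial(phase=3, index=4, role="self", pair=make_pair(-4.5), choice=1),
        Trial(phase=3, index=5, role="other", pair=make_pair(-4.0), choice=0,
              other_choice=1, feedback="incorrect"),
    ]
    return ParticipantDataset(participant_id="toy", trials=trials)
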