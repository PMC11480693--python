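import numpy as np
import pytest

from neuroplay.features import extract_features
from neuroplay.games import GAMES, play_session
from neuroplay.synthetic import (
    FootLatent,
    GeneratorConfig,
    LatentNeuropathy,
    MotorControlParams,
    Participant,
    ParticipantProfile,
    simulate_player,
)

RATE = 50.0  # test sampling rate; the engines are rate-agnostic


def make_participant(small=0.0, large=0.0, burden=0.0, motor=None,
                     pid="P0001") -> Participant:
    profile = ParticipantProfile(pid, 60.0, "male", 80.0, 27.0,
                                 "type2", 10.0, True)
    foot = FootLatent(small, large, burden)
    latent = LatentNeuropathy(foot, foot)
    if motor is None:
        motor = MotorControlParams.ideal()
    return Participant(profile, latent, {"left": motor, "right": motor})


@pytest.fixture(scope="session")
def ideal_streams():
    params = {"left": MotorControlParams.ideal(),
              "right": MotorControlParams.ideal()}
    return {g: simulate_player(params, g, seed=0, rate=RATE) for g in GAMES}


@pytest.fixture(scope="session")
def ideal_results(ideal_streams):
    return play_session(ideal_streams)


@pytest.fixture(scope="session")
def ideal_session(ideal_streams, ideal_results):
    from neuroplay.features import GameSession
    return GameSession(ideal_streams, ideal_results, participant_id="ideal")


@pytest.fixture(scope="session")
def ideal_vectors(ideal_session):
    return extract_features(ideal_session)


@pytest.fixture(scope="session")
def impaired_session():
    """A strongly impaired player's full session."""
    from neuroplay.features import GameSession
    motor = MotorControlParams(reaction_latency=0.7, pressure_noise_sd=0.10,
                               sensing_deadband=0.09, max_force_fraction=0.75,
                               fatigue_rate=0.05, tremor_freq=6.0)
    params = {"left": motor, "right": motor}
    rng = np.random.default_rng(7)
    streams = {g: simulate_player(params, g, rng, rate=RATE) for g in GAMES}
    return GameSession(streams, play_session(streams),
                       participant_id="impaired")


@pytest.fixture(scope="session")
def small_study():
    """A small mixed cohort study shared across tests."""
    from neuroplay.pipeline import simulate_cohort_study
    return simulate_cohort_study(24, GeneratorConfig(), seed=42, rate=25.0)
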