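import numpy as np
import pytest

from groupgame import GameParams, InteractionRecord, TrialLog, run_ensemble, run_trial


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def rec(rnd, sp, he, stimuli, topic, label, guess, exposed=False,
        sp_conf=False, he_conf=False, trial="t"):
    """Loose record builder for hand-constructed analysis logs."""
    return InteractionRecord(
        trial_id=trial,
        round=rnd,
        speaker_id=sp,
        hearer_id=he,
        stimuli=stimuli,
        topic=topic,
        label=label,
        guess=guess,
        success=guess == topic,
        speaker_was_exposed=exposed,
        speaker_is_confederate=sp_conf,
        hearer_is_confederate=he_conf,
    )


@pytest.fixture(scope="session")
def dyad_log():
    return run_trial(
        GameParams(n_agents=2, rounds=60, pairing_mode="fixed_partner", seed=7)
    )


@pytest.fixture(scope="session")
def n8_log():
    return run_trial(GameParams(n_agents=8, rounds=60, seed=21))


@pytest.fixture(scope="session")
def small_ensemble():
    """Four quick N=6 trials for metric plumbing tests."""
    return run_ensemble(GameParams(n_agents=6, rounds=40), 4, 99)
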