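import numpy as np
import pandas as pd
import pytest

from advicegame import synthetic
from advicegame.agents import ParticipantAgentConfig
from advicegame.learning import DevianceParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_trial_log(rng: np.random.Generator, n_trials: int = 20) -> pd.DataFrame:
    """A schema-valid random trial log (not generated by the simulator), for
    oracle and round-trip tests."""
    p_support = np.round(np.arange(0.05, 0.96, 0.05), 2)
    p = rng.choice(p_support, size=n_trials)
    advice_P = rng.choice([-5, -4, -3, -2, -1, 1, 2, 3, 4, 5], size=n_trials)
    advice_R = rng.choice([-5, -4, -3, -2, -1, 1, 2, 3, 4, 5], size=n_trials)
    coin = rng.choice(["black", "white"], size=n_trials)
    acc = lambda a: np.where((a < 0) == (coin == "black"), 1, -1)
    return pd.DataFrame(
        {
            "trial": np.arange(1, n_trials + 1),
            "selection": rng.choice(["participant", "rival"], size=n_trials),
            "p_black_P": p,
            "p_black_R": p,
            "degraded": "none",
            "advice_P": advice_P,
            "advice_R": advice_R,
            "coin_urn": coin,
            "acc_P": acc(advice_P),
            "acc_R": acc(advice_R),
        }
    )


@pytest.fixture
def toy_log(rng):
    return random_trial_log(rng, n_trials=30)


@pytest.fixture(scope="session")
def bias_cohort_log():
    """One 240-trial log generated by a pure-bias participant (Bias = 0.7,
    response noise 0.3)."""
    agent = ParticipantAgentConfig(
        params=DevianceParams(model_id="bias", bias=0.7),
        response_noise_sd=0.3,
    )
    return synthetic.simulate_participant(
        agent, synthetic.schedule_preset("scanner"), seed=2024
    )
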