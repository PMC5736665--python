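"""The three simulated agents of the advice game.

* The **rival adviser** reports the evidence probability plus Gaussian noise
  (sd 0.08 by default), discretized onto the 10-level confidence scale.
* The **client** keeps an influence weight per adviser (summing to 10,
  starting at 5/5), updates them multiplicatively from the squared
  prognostic strength of each advice for the realized outcome, and selects
  the adviser with the higher weight at the next trial's appraisal stage.
* The **participant adviser** is a generative counterpart of the deviance
  models: it computes the confidence the evidence warrants, adds the model-
  predicted deviance plus response noise, and reports the nearest valid
  advice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .learning import DevianceParams, MeritState, TrialCovariates, predict_deviance
from .task_core import Advice, expected_confidence

DEFAULT_RIVAL_NOISE_SD = 0.08
INITIAL_WEIGHT = 5.0
TOTAL_WEIGHT = 10.0


@dataclass(frozen=True)
class ClientState:
    """Influence weights (participant, rival); conserved sum of 10."""

    w_P: float = INITIAL_WEIGHT
    w_O: float = INITIAL_WEIGHT

    def __post_init__(self) -> None:
        if self.w_P < 0 or self.w_O < 0:
            raise ValueError("influence weights must be non-negative")
        if abs(self.w_P + self.w_O - TOTAL_WEIGHT) > 1e-9:
            raise ValueError(
                f"weights must sum to {TOTAL_WEIGHT}, got {self.w_P + self.w_O}"
            )


@dataclass(frozen=True)
class RivalConfig:
    """Gaussian evidence noise of the rival adviser."""

    noise_sd: float = DEFAULT_RIVAL_NOISE_SD

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class ParticipantAgentConfig:
    """Generative participant: a deviance model plus response noise
    (standard deviation in deviance/confidence-scale units)."""

    params: DevianceParams
    response_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.response_noise_sd < 0:
            raise ValueError("response_noise_sd must be non-negative")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _confidence_to_advice(direction: str, c: float, rng: np.random.Generator) -> Advice:
    """Clip a continuous confidence to [1, 5], round, and attach the urn.

    ``direction == "tie"`` (chance evidence) picks the urn by fair coin.
    """
    level = _round_half_up(min(5.0, max(1.0, c)))
    if direction == "tie":
        urn = "black" if rng.random() < 0.5 else "white"
        return Advice(urn=urn, level=level)
    return Advice(urn=direction, level=level)


def rival_advice(
    p_black: float,
    rng: np.random.Generator,
    config: RivalConfig = RivalConfig(),
    epsilon: float | None = None,
) -> Advice:
    """Rival's advice: evidence probability plus N(0, sd) noise, clipped to
    [0, 1] and mapped onto the confidence scale.

    ``epsilon`` substitutes an explicit noise draw (the rng is then used
    only for the fair-coin direction at exactly chance evidence).  With zero
    noise this reduces to the deterministic zero-deviance policy.
    """
    eps = rng.normal(0.0, config.noise_sd) if epsilon is None else epsilon
    q = float(np.clip(p_black + eps, 0.0, 1.0))
    direction, c_star = expected_confidence(q)
    return _confidence_to_advice(direction, c_star, rng)


def client_effective_pa(pa: int, coin_urn: str) -> int:
    """Prognostic strength of an advice for the realized outcome.

    The raw PA code (1..10) is oriented towards the white urn: 10 means
    "certainly white".  When the coin is actually in the black urn the scale
    is reflected (11 - pa) so that the strongest correct advice always scores
    10 and the strongest wrong advice scores 1.
    """
    if not 1 <= pa <= 10:
        raise ValueError(f"pa must be in 1..10, got {pa}")
    if coin_urn == "white":
        return pa
    if coin_urn == "black":
        return 11 - pa
    raise ValueError(f"invalid coin_urn {coin_urn!r}")


def update_client(state: ClientState, pa_P_eff: float, pa_O_eff: float) -> ClientState:
    """Multiplicative influence-weight update from squared prognostic
    strengths:

        w_P' = 10 · w_P·PA_P² / (w_P·PA_P² + w_O·PA_O²),   w_O' = 10 − w_P'

    Equal effective PAs leave any weight pair unchanged.
    """
    num = state.w_P * pa_P_eff**2
    den = num + state.w_O * pa_O_eff**2
    if den == 0:
        raise ZeroDivisionError("degenerate client update: zero denominator")
    w_P = TOTAL_WEIGHT * num / den
    return ClientState(w_P=w_P, w_O=TOTAL_WEIGHT - w_P)


def select_adviser(state: ClientState, rng: np.random.Generator) -> str:
    """Appraisal-stage pick: the adviser with the higher influence weight;
    an exact tie is broken by fair coin."""
    if state.w_P > state.w_O:
        return "participant"
    if state.w_O > state.w_P:
        return "rival"
    return "participant" if rng.random() < 0.5 else "rival"


def participant_advice(
    config: ParticipantAgentConfig,
    p_black: float,
    selection: int,
    merit_state: MeritState,
    rng: np.random.Generator,
) -> Advice:
    """Generate the participant's advice under a deviance model.

    The target projection is the warranted confidence c* plus the model-
    predicted deviance plus Gaussian response noise.  A negative noisy
    projection flips the advice to the evidence-disfavoured urn; the
    magnitude is clipped to [1, 5] and rounded.  At chance evidence the
    warranted confidence is 1, only magnitude deviance applies, and the urn
    is chosen by fair coin.
    """
    if selection not in (1, -1):
        raise ValueError("selection must be coded +1/-1")
    cov = TrialCovariates(selection=selection, merit_value=merit_state.relative_merit)
    dev = predict_deviance(config.params, cov)
    noise = rng.normal(0.0, config.response_noise_sd) if config.response_noise_sd else 0.0
    direction, c_star = expected_confidence(p_black)
    target = c_star + dev + noise
    if direction == "tie":
        return _confidence_to_advice("tie", target, rng)
    if target < 0:
        flipped = "white" if direction == "black" else "black"
        return _confidence_to_advice(flipped, -target, rng)
    return _confidence_to_advice(direction, target, rng)
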