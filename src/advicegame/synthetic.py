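"""Synthetic cohorts for the advice game.

Generates complete trial logs with the statistical structure the analysis
assumes: evidence probabilities randomized per participant, coin locations
sampled from the evidence, blocks of degraded evidence reliability for one
adviser at a time, a noisy rival, a multiplicative-weight client, and
participant advisers whose deviance follows one of the six nested models
plus response noise.  Ground-truth generating parameters are returned in a
separate table so that fitting code can never read them by accident.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import task_core
from .agents import (
    ClientState,
    ParticipantAgentConfig,
    RivalConfig,
    client_effective_pa,
    participant_advice,
    rival_advice,
    select_adviser,
    update_client,
)
from .learning import (
    MODEL_PARAMS,
    PARAM_ORDER,
    DevianceParams,
    MeritState,
    delta_prognostic_value,
    merit_update,
)
from .task_core import EvidenceGrid, client_pa, degrade_evidence, resolve_outcome

#: Default support of the evidence probability (majority side); the colour
#: polarity is randomized per trial, so p_black is drawn from this set or
#: its mirror around 0.5.
DEFAULT_P_SUPPORT = tuple(np.round(np.arange(0.55, 0.96, 0.05), 2))

#: Default response noise of synthetic participants, in deviance units.
DEFAULT_RESPONSE_NOISE_SD = 0.3

DEGRADATION_WINDOW_LEN = 10


@dataclass(frozen=True)
class ExperimentSchedule:
    """Trial count, block structure and degradation windows of one session.

    ``degradation_blocks`` is a list of ``(start, end, target)`` tuples with
    1-based inclusive trial indices; inside such a window the named
    adviser's evidence grid has its contrast reduced by ``reduction``
    squares.
    """

    n_trials: int
    block_length: int
    degradation_blocks: tuple[tuple[int, int, str], ...] = ()
    p_support: tuple[float, ...] = DEFAULT_P_SUPPORT
    random_polarity: bool = True
    reduction: int = task_core.DEFAULT_REDUCTION

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be positive")
        covered = np.zeros(self.n_trials + 1, dtype=bool)
        for start, end, target in self.degradation_blocks:
            if not (1 <= start <= end <= self.n_trials):
                raise ValueError(f"degradation block ({start},{end}) out of range")
            if target not in ("participant", "rival"):
                raise ValueError(f"invalid degradation target {target!r}")
            if covered[start : end + 1].any():
                raise ValueError("degradation blocks overlap")
            covered[start : end + 1] = True

    def degraded_on(self, t: int) -> str:
        """Degradation target on trial t: 'participant', 'rival' or 'none'."""
        for start, end, target in self.degradation_blocks:
            if start <= t <= end:
                return target
        return "none"


def _default_degradation(
    n_blocks: int, block_length: int
) -> tuple[tuple[int, int, str], ...]:
    """Two degradation windows per experimental block, alternating target.

    Windows sit at ~20% and ~65% of each block so that selected and ignored
    phases alternate within every block.
    """
    windows: list[tuple[int, int, str]] = []
    targets = ("participant", "rival")
    k = 0
    for b in range(n_blocks):
        base = b * block_length
        for frac in (0.2, 0.65):
            start = base + int(block_length * frac) + 1
            windows.append((start, start + DEGRADATION_WINDOW_LEN - 1, targets[k % 2]))
            k += 1
    return tuple(windows)


def schedule_preset(name: str) -> ExperimentSchedule:
    """Named schedules: ``online`` = 130 trials (2 blocks of 65),
    ``lab`` = 4 blocks of 70, ``scanner`` = 4 blocks of 60."""
    shapes = {"online": (2, 65), "lab": (4, 70), "scanner": (4, 60)}
    if name not in shapes:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(shapes)}")
    n_blocks, block_length = shapes[name]
    return ExperimentSchedule(
        n_trials=n_blocks * block_length,
        block_length=block_length,
        degradation_blocks=_default_degradation(n_blocks, block_length),
    )


def generate_trial_sequence(
    schedule: ExperimentSchedule, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw the evidence and coin sequence for one session.

    p_black is i.i.d. from the schedule's support (with random colour
    polarity by default); the coin is Bernoulli(p_black) on the *true*
    evidence; per-adviser seen probabilities reflect any degradation window
    active on that trial.
    """
    n = schedule.n_trials
    p_true = rng.choice(np.asarray(schedule.p_support, dtype=float), size=n)
    if schedule.random_polarity:
        flip = rng.random(n) < 0.5
        p_true = np.where(flip, np.round(1.0 - p_true, 10), p_true)
    coin_black = rng.random(n) < p_true
    rows = []
    for i in range(n):
        t = i + 1
        grid = EvidenceGrid.from_p_black(p_true[i])
        degraded = schedule.degraded_on(t)
        grid_P = grid_R = grid
        if degraded == "participant":
            grid_P = degrade_evidence(grid, schedule.reduction)
        elif degraded == "rival":
            grid_R = degrade_evidence(grid, schedule.reduction)
        rows.append(
            {
                "trial": t,
                "p_black_true": float(p_true[i]),
                "p_black_P": grid_P.p_black,
                "p_black_R": grid_R.p_black,
                "degraded": degraded,
                "coin_urn": "black" if coin_black[i] else "white",
            }
        )
    return pd.DataFrame(rows)


def simulate_participant(
    agent: ParticipantAgentConfig,
    schedule: ExperimentSchedule,
    seed: int | np.random.SeedSequence,
    rival: RivalConfig = RivalConfig(),
    literal_pa_mode: bool = False,
) -> pd.DataFrame:
    """Simulate one adviser's full session and return the trial log.

    Stage order within each trial: the client selects by current influence
    weights (appraisal); both advisers see their — possibly degraded —
    evidence and advise; the urn named by the selected adviser is opened;
    the merit state and the client's weights update from the outcome.

    ``literal_pa_mode`` feeds the raw white-oriented PA codes to the client
    update instead of reflecting them onto the realized outcome.
    """
    rng = np.random.default_rng(seed)
    sequence = generate_trial_sequence(schedule, rng)
    client = ClientState()
    gamma = agent.params.gamma if "gamma" in MODEL_PARAMS[agent.params.model_id] else 0.0
    merit = MeritState(gamma=gamma)
    rows = []
    for rec in sequence.itertuples(index=False):
        selection = select_adviser(client, rng)
        s_code = 1 if selection == "participant" else -1
        advice_P = participant_advice(agent, rec.p_black_P, s_code, merit, rng)
        advice_R = rival_advice(rec.p_black_R, rng, rival)
        outcome, _ = resolve_outcome(advice_P, advice_R, selection, rec.coin_urn)
        rows.append(
            {
                "trial": rec.trial,
                "selection": selection,
                "p_black_P": rec.p_black_P,
                "p_black_R": rec.p_black_R,
                "degraded": rec.degraded,
                "advice_P": advice_P.signed,
                "advice_R": advice_R.signed,
                "coin_urn": rec.coin_urn,
                "acc_P": outcome.accuracy_P,
                "acc_R": outcome.accuracy_R,
                "w_P": client.w_P,
            }
        )
        dpv = delta_prognostic_value(
            advice_P, outcome.accuracy_P, advice_R, outcome.accuracy_R
        )
        merit, _ = merit_update(merit, dpv)
        pa_P, pa_R = client_pa(advice_P), client_pa(advice_R)
        if not literal_pa_mode:
            pa_P = client_effective_pa(pa_P, rec.coin_urn)
            pa_R = client_effective_pa(pa_R, rec.coin_urn)
        client = update_client(client, pa_P, pa_R)
    log = pd.DataFrame(rows)
    if isinstance(seed, np.random.SeedSequence):
        log.attrs["seed"] = (
            f"SeedSequence(entropy={seed.entropy}, spawn_key={seed.spawn_key})"
        )
    else:
        log.attrs["seed"] = str(seed)
    log.attrs["literal_pa_mode"] = str(literal_pa_mode)
    return log


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class CohortSpec:
    """A cohort of simulated advisers sharing a schedule and a generating
    model, with per-participant parameters sampled around group means.

    ``param_means``/``param_sds`` cover the free parameters of ``model_id``
    (canonical names: bias, beta_selection, beta_merit, beta_interaction,
    gamma).  A parameter with sd 0 is fixed at its mean.  γ draws are
    clipped to ``gamma_bounds``.  If ``fne_rho`` is set, a per-participant
    Fear-of-Negative-Evaluation score is emitted whose population
    correlation with the generating β_selection is +ρ (defensive advisers —
    positive β_selection — score higher).
    """

    n_participants: int
    model_id: str
    param_means: dict[str, float]
    param_sds: dict[str, float] = field(default_factory=dict)
    schedule: ExperimentSchedule = field(default_factory=lambda: schedule_preset("scanner"))
    response_noise_sd: float = DEFAULT_RESPONSE_NOISE_SD
    seed: int = 0
    gamma_bounds: tuple[float, float] = (0.05, 0.95)
    fne_rho: float | None = None
    literal_pa_mode: bool = False

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        active = MODEL_PARAMS[self.model_id]  # raises KeyError on bad id
        for name in self.param_means:
            if name not in active:
                raise ValueError(f"{name!r} is not a parameter of {self.model_id!r}")


#: Default spread of per-participant generating parameters around the group
#: means, roughly matching the between-participant variability reported for
#: human cohorts on this task (SEM × sqrt(N)).
DEFAULT_PARAM_SDS = {
    "bias": 0.5,
    "beta_selection": 0.2,
    "beta_merit": 0.15,
    "beta_interaction": 0.15,
    "gamma": 0.1,
}

#: Brief FNE questionnaire range used for emulated scores.
FNE_LOCATION, FNE_SCALE, FNE_RANGE = 36.0, 9.0, (12, 60)


def _sample_params(
    spec: CohortSpec, rng: np.random.Generator
) -> list[DevianceParams]:
    active = MODEL_PARAMS[spec.model_id]
    out = []
    for _ in range(spec.n_participants):
        kwargs: dict[str, float] = {}
        for name in active:
            mean = spec.param_means.get(name, 0.0)
            sd = spec.param_sds.get(name, DEFAULT_PARAM_SDS[name])
            value = mean + sd * rng.standard_normal() if sd > 0 else mean
            if name == "gamma":
                value = float(np.clip(value, *spec.gamma_bounds))
            kwargs[name] = float(value)
        out.append(DevianceParams(model_id=spec.model_id, **kwargs))
    return out


def _emulate_fne(
    truths: pd.DataFrame, rho: float, rng: np.random.Generator
) -> pd.DataFrame:
    """FNE scores correlated +ρ with generating β_selection (defensive ↔ high)."""
    beta = truths["beta_selection"].to_numpy(dtype=float)
    sd = beta.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot emulate FNE correlation: constant beta_selection")
    z = (beta - beta.mean()) / sd
    latent = rho * z + np.sqrt(1.0 - rho**2) * rng.standard_normal(beta.size)
    score = np.clip(np.rint(FNE_LOCATION + FNE_SCALE * latent), *FNE_RANGE)
    return pd.DataFrame(
        {"participant_id": truths["participant_id"], "fne_score": score.astype(int)}
    )


def generate_cohort(
    spec: CohortSpec,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, pd.DataFrame | None]:
    """Generate a full synthetic cohort.

    Returns ``(logs, ground_truth, fne)`` where ``logs`` maps participant id
    to trial log, ``ground_truth`` holds one row of generating parameters
    per participant, and ``fne`` is a score table (or None if ``fne_rho``
    is unset).
    """
    root = np.random.SeedSequence(spec.seed)
    param_ss, fne_ss, *participant_ss = root.spawn(spec.n_participants + 2)
    params = _sample_params(spec, np.random.default_rng(param_ss))
    logs: dict[str, pd.DataFrame] = {}
    truth_rows = []
    for i, (p, ss) in enumerate(zip(params, participant_ss)):
        pid = f"sim{i + 1:03d}"
        agent = ParticipantAgentConfig(
            params=p, response_noise_sd=spec.response_noise_sd
        )
        logs[pid] = simulate_participant(
            agent, spec.schedule, ss, literal_pa_mode=spec.literal_pa_mode
        )
        row = {"participant_id": pid, "model_id": spec.model_id}
        row.update({name: getattr(p, name) for name in PARAM_ORDER})
        truth_rows.append(row)
    truth = pd.DataFrame(truth_rows)
    fne = None
    if spec.fne_rho is not None:
        fne = _emulate_fne(truth, spec.fne_rho, np.random.default_rng(fne_ss))
    return logs, truth, fne
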