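"""Relative-merit learning and the six nested advice-deviance models.

The adviser tracks a running comparison of their own versus the rival's
prognostic value with a delta rule:

    ΔPV(t)  = level_P(t)·acc_P(t) − level_R(t)·acc_R(t)
    PE(t)   = ΔPV(t) − RM(t)
    RM(t+1) = RM(t) + γ·PE(t)

Advice deviance on trial t is then modelled as a linear function of the
client's selection S(t) ∈ {+1 selected, −1 ignored} and the sign (or, in the
amplitude variant, the raw value) of relative merit:

    deviance(t) = Bias + β_sel·S(t) + β_mer·m(t) + β_int·S(t)·m(t)

The six model identifiers select nested subsets of the terms:

    bias         deviance = Bias
    client       + β_sel·S
    merit        + β_mer·sign(RM)           (no selection terms)
    mixed        Bias + β_sel·S + β_mer·sign(RM)
    interaction  full model, m = sign(RM)
    amplitude    full model, m = RM (magnitude and sign)

``sign(0) = +1`` by convention, so merit labels are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .task_core import Advice, prognostic_value

MODEL_IDS = ("bias", "client", "merit", "mixed", "interaction", "amplitude")

#: Free parameters per model, in canonical order.
MODEL_PARAMS: dict[str, tuple[str, ...]] = {
    "bias": ("bias",),
    "client": ("bias", "beta_selection"),
    "merit": ("bias", "beta_merit", "gamma"),
    "mixed": ("bias", "beta_selection", "beta_merit", "gamma"),
    "interaction": ("bias", "beta_selection", "beta_merit", "beta_interaction", "gamma"),
    "amplitude": ("bias", "beta_selection", "beta_merit", "beta_interaction", "gamma"),
}

PARAM_ORDER = ("bias", "beta_selection", "beta_merit", "beta_interaction", "gamma")


@dataclass
class MeritState:
    """Scalar relative merit plus its learning rate γ ∈ [0, 1]."""

    gamma: float
    relative_merit: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")


@dataclass(frozen=True)
class DevianceParams:
    """Parameter vector for one of the six nested deviance models.

    Parameters that are inactive under ``model_id`` must be 0 (γ may be
    omitted for the bias and client models, where no merit trace is used).
    """

    model_id: str
    bias: float = 0.0
    beta_selection: float = 0.0
    beta_merit: float = 0.0
    beta_interaction: float = 0.0
    gamma: float = 0.0

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        active = MODEL_PARAMS[self.model_id]
        for name in ("beta_selection", "beta_merit", "beta_interaction"):
            if name not in active and getattr(self, name) != 0.0:
                raise ValueError(f"{name} must be 0 for model {self.model_id!r}")
        if "gamma" in active and not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")

    def as_vector(self) -> np.ndarray:
        """Full 5-vector in canonical order (inactive entries are 0)."""
        return np.array([getattr(self, p) for p in PARAM_ORDER], dtype=float)


@dataclass(frozen=True)
class TrialCovariates:
    """Per-trial regressors for the deviance models."""

    selection: int  # +1 selected by client, -1 ignored
    merit_value: float

    @property
    def merit_sign(self) -> int:
        return 1 if self.merit_value >= 0 else -1


def delta_prognostic_value(
    advice_P: Advice, acc_P: int, advice_R: Advice, acc_R: int
) -> int:
    """Participant's minus rival's prognostic value on one trial; in [-10, 10]."""
    return prognostic_value(advice_P, acc_P) - prognostic_value(advice_R, acc_R)


def merit_update(state: MeritState, delta_pv: float) -> tuple[MeritState, float]:
    """One delta-rule step; returns the new state and the prediction error."""
    pe = delta_pv - state.relative_merit
    new_rm = state.relative_merit + state.gamma * pe
    return MeritState(gamma=state.gamma, relative_merit=new_rm), pe


def merit_trace(delta_pv: np.ndarray, gamma: float, rm0: float = 0.0) -> np.ndarray:
    """Relative merit *entering* each trial, given the ΔPV sequence.

    Element t is RM accumulated from outcomes of trials 1..t-1 (so element 0
    is ``rm0``).  The recursion RM(t+1) = (1-γ)·RM(t) + γ·ΔPV(t) is an
    exponential filter, evaluated with ``scipy.signal.lfilter``.
    """
    delta_pv = np.asarray(delta_pv, dtype=float)
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must be in [0, 1], got {gamma}")
    n = delta_pv.size
    rm = np.empty(n, dtype=float)
    rm[0] = rm0
    if n > 1:
        # zi carries the initial condition through the IIR filter
        filtered, _ = lfilter(
            [gamma], [1.0, -(1.0 - gamma)], delta_pv[:-1], zi=[(1.0 - gamma) * rm0]
        )
        rm[1:] = filtered
    return rm


def predict_deviance(params: DevianceParams, cov: TrialCovariates) -> float:
    """Model-predicted advice deviance for one trial's covariates."""
    m = cov.merit_value if params.model_id == "amplitude" else float(cov.merit_sign)
    s = float(cov.selection)
    if params.model_id == "bias":
        return params.bias
    if params.model_id == "client":
        return params.bias + params.beta_selection * s
    if params.model_id == "merit":
        return params.bias + params.beta_merit * m
    if params.model_id == "mixed":
        return params.bias + params.beta_selection * s + params.beta_merit * m
    # interaction / amplitude: the full linear model
    return (
        params.bias
        + params.beta_selection * s
        + params.beta_merit * m
        + params.beta_interaction * s * m
    )


def run_model(
    params: DevianceParams,
    selection: np.ndarray,
    delta_pv: np.ndarray,
) -> pd.DataFrame:
    """Run a deviance model over a full trial sequence.

    Parameters
    ----------
    params
        Model identity and parameter values.
    selection
        Per-trial client selection, coded +1 (participant selected) / -1
        (ignored); this is the appraisal-stage choice, known before advising.
    delta_pv
        Per-trial ΔPV; the merit entering trial t uses outcomes through t-1.

    Returns
    -------
    DataFrame with one row per trial and columns ``predicted_deviance``,
    ``relative_merit`` (entering the trial), ``merit_sign`` and ``merit_pe``
    (the prediction error generated by that trial's outcome).
    """
    selection = np.asarray(selection, dtype=float)
    delta_pv = np.asarray(delta_pv, dtype=float)
    if selection.shape != delta_pv.shape or selection.ndim != 1:
        raise ValueError("selection and delta_pv must be 1-D and equally long")
    if selection.size == 0:
        raise ValueError("empty trial sequence")
    if not np.all(np.isin(selection, (-1.0, 1.0))):
        raise ValueError("selection must be coded +1/-1")

    gamma = params.gamma if "gamma" in MODEL_PARAMS[params.model_id] else 0.0
    rm = merit_trace(delta_pv, gamma)
    pe = delta_pv - rm
    sign = np.where(rm >= 0, 1.0, -1.0)
    m = rm if params.model_id == "amplitude" else sign
    pred = (
        params.bias
        + params.beta_selection * selection
        + params.beta_merit * m
        + params.beta_interaction * selection * m
    )
    return pd.DataFrame(
        {
            "predicted_deviance": pred,
            "relative_merit": rm,
            "merit_sign": sign.astype(int),
            "merit_pe": pe,
        }
    )
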