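"""Behavioural analysis of advice deviance.

Implements the full pipeline applied to a cohort of trial logs: per-trial
deviance, 2×2 labelling by client selection (selected vs ignored) and the
sign of model-estimated relative merit (positive vs negative), per-
participant cell means with a two-way repeated-measures ANOVA, the overall
ignored-vs-selected contrast, strategy classification from the fitted
selection weight, the FNE correlation, and cohort-level deviance summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM

from .fitting import prepare_arrays
from .learning import DevianceParams, run_model

CELLS = [
    ("selected", "positive"),
    ("selected", "negative"),
    ("ignored", "positive"),
    ("ignored", "negative"),
]

#: Exclusion rule for degenerate responders: fewer distinct confidence
#: levels than this means the participant did not use the scale.
MIN_DISTINCT_LEVELS = 3


def observed_deviance(log: pd.DataFrame) -> np.ndarray:
    """Per-trial advice deviance of the participant (vs the seen evidence)."""
    _, _, obs = prepare_arrays(log)
    return obs


def label_trials(log: pd.DataFrame, gamma: float) -> pd.DataFrame:
    """Label every trial by selection and by the sign of relative merit.

    The merit trace is recomputed with the interaction model's fitted
    learning rate ``gamma``; merit entering trial t reflects outcomes
    through t−1 and sign(0) counts as positive.  Labels do not depend on
    the deviance values themselves.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must be in [0, 1], got {gamma}")
    for col in ("acc_P", "acc_R", "coin_urn"):
        if col not in log.columns or log[col].isna().any():
            raise ValueError(f"missing outcome field {col!r}")
    S, dpv, obs = prepare_arrays(log)
    trace = run_model(
        DevianceParams(model_id="interaction", gamma=gamma), S, dpv
    )
    return pd.DataFrame(
        {
            "trial": log["trial"].to_numpy(),
            "deviance": obs,
            "selection": np.where(S > 0, "selected", "ignored"),
            "merit_sign": np.where(
                trace["merit_sign"].to_numpy() > 0, "positive", "negative"
            ),
            "relative_merit": trace["relative_merit"].to_numpy(),
        }
    )


def cell_means(labelled: pd.DataFrame) -> pd.Series | None:
    """The four (selection × merit) mean deviances for one participant, or
    None if any cell is empty."""
    grouped = labelled.groupby(["selection", "merit_sign"], observed=False)[
        "deviance"
    ].mean()
    try:
        return pd.Series({c: grouped.loc[c] for c in CELLS})
    except KeyError:
        return None


@dataclass
class ConditionSummary:
    """Cohort-level 2×2 summary: per-participant cell means, cohort means ±
    SEM, the repeated-measures ANOVA, and the overall ignored-vs-selected
    paired contrast."""

    per_participant: pd.DataFrame  # participant × (selection, merit) cells
    cohort_means: pd.Series
    cohort_sems: pd.Series
    anova: pd.DataFrame  # effects × (F, num df, den df, p)
    paired_t: float
    paired_p: float
    n_used: int
    excluded: list[str]

    @property
    def max_cell(self) -> tuple[str, str]:
        return tuple(self.cohort_means.idxmax())


def condition_analysis(labelled: dict[str, pd.DataFrame]) -> ConditionSummary:
    """2×2 repeated-measures analysis over a cohort of labelled tables.

    Participants with an empty cell are excluded with a warning; at least
    two usable participants are required.  Effects tested: merit sign,
    selection, and their interaction (each F(1, n−1)), plus a paired t-test
    of overall ignored vs selected mean deviance.
    """
    rows = {}
    excluded = []
    for pid, table in labelled.items():
        cells = cell_means(table)
        if cells is None:
            excluded.append(pid)
        else:
            rows[pid] = cells
    if excluded:
        warnings.warn(
            f"excluded {len(excluded)} participant(s) with empty 2x2 cells: "
            f"{sorted(excluded)}",
            UserWarning,
            stacklevel=2,
        )
    if len(rows) < 2:
        raise ValueError("need at least 2 participants with all four cells")
    per_part = pd.DataFrame(rows).T
    per_part.columns = pd.MultiIndex.from_tuples(
        per_part.columns, names=["selection", "merit_sign"]
    )
    per_part.index.name = "participant"
    long = per_part.stack(["selection", "merit_sign"], future_stack=True).rename(
        "deviance"
    ).reset_index()
    fitted = AnovaRM(
        long, depvar="deviance", subject="participant",
        within=["selection", "merit_sign"],
    ).fit()
    anova = fitted.anova_table.rename(
        index={
            "selection": "selection",
            "merit_sign": "merit",
            "selection:merit_sign": "interaction",
        },
        columns={"F Value": "F", "Num DF": "num_df", "Den DF": "den_df",
                 "Pr > F": "p"},
    )
    ignored = per_part["ignored"].mean(axis=1)
    selected = per_part["selected"].mean(axis=1)
    t, p = stats.ttest_rel(ignored, selected)
    return ConditionSummary(
        per_participant=per_part,
        cohort_means=per_part.mean(axis=0),
        cohort_sems=per_part.sem(axis=0),
        anova=anova,
        paired_t=float(t),
        paired_p=float(p),
        n_used=len(rows),
        excluded=sorted(excluded),
    )


@dataclass
class StrategyReport:
    """Per-participant strategy classes and the group test of β_selection."""

    classes: pd.Series  # participant -> 'competitive' | 'defensive'
    mean_beta: float
    sem_beta: float
    t: float
    p: float


def classify_strategy(beta_selection: pd.Series) -> StrategyReport:
    """Competitive iff the fitted β_selection is negative (lower confidence
    when selected); zero counts as defensive by convention.  Also reports
    the two-tailed one-sample t-test of β_selection against 0."""
    beta = beta_selection.astype(float)
    classes = pd.Series(
        np.where(beta < 0, "competitive", "defensive"), index=beta.index
    )
    t, p = stats.ttest_1samp(beta, 0.0)
    return StrategyReport(
        classes=classes,
        mean_beta=float(beta.mean()),
        sem_beta=float(beta.sem()),
        t=float(t),
        p=float(p),
    )


@dataclass
class CorrelationReport:
    r: float
    r_squared: float
    p: float
    n: int


def correlate_fne(
    beta_selection: pd.Series, fne: pd.DataFrame, min_pairs: int = 10
) -> CorrelationReport:
    """Pearson correlation between FNE score and fitted β_selection.

    ``fne`` must have columns ``participant_id`` and ``fne_score`` and match
    the fit table's participant identifiers (unmatched IDs raise).
    """
    fne_s = fne.set_index("participant_id")["fne_score"].astype(float)
    missing = fne_s.index.difference(beta_selection.index)
    if len(missing):
        raise ValueError(f"FNE table has unmatched participant IDs: {list(missing)}")
    beta = beta_selection.loc[fne_s.index].astype(float)
    if len(beta) < min_pairs:
        raise ValueError(f"need at least {min_pairs} matched pairs, got {len(beta)}")
    if fne_s.nunique() < 2 or beta.nunique() < 2:
        raise ValueError("correlation undefined: constant input vector")
    r, p = stats.pearsonr(fne_s, beta)
    return CorrelationReport(r=float(r), r_squared=float(r**2), p=float(p),
                             n=int(len(beta)))


@dataclass
class DevianceOverview:
    per_participant: pd.Series
    cohort_mean: float
    t: float
    p: float
    cohen_d: float


def deviance_overview(logs: dict[str, pd.DataFrame]) -> DevianceOverview:
    """Per-participant mean deviance plus the one-sample test against zero
    (two-tailed t, Cohen's d = mean / sd across participants)."""
    if len(logs) < 2:
        raise ValueError("need at least 2 participants")
    means = pd.Series(
        {pid: float(observed_deviance(log).mean()) for pid, log in logs.items()}
    )
    t, p = stats.ttest_1samp(means, 0.0)
    sd = means.std(ddof=1)
    d = float(means.mean() / sd) if sd > 0 else float("nan")
    return DevianceOverview(
        per_participant=means,
        cohort_mean=float(means.mean()),
        t=float(t),
        p=float(p),
        cohen_d=d,
    )


def usable_participants(
    logs: dict[str, pd.DataFrame], min_levels: int = MIN_DISTINCT_LEVELS
) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """Drop participants who did not use the confidence scale (fewer than
    ``min_levels`` distinct advice values); mirrors the exclusion applied to
    human cohorts before fitting."""
    kept, dropped = {}, []
    for pid, log in logs.items():
        if log["advice_P"].nunique() < min_levels:
            dropped.append(pid)
        else:
            kept[pid] = log
    if dropped:
        warnings.warn(
            f"excluded {len(dropped)} participant(s) with <{min_levels} "
            f"distinct confidence levels: {sorted(dropped)}",
            UserWarning,
            stacklevel=2,
        )
    return kept, sorted(dropped)


def compare_cohorts(
    labelled_by_cohort: dict[str, dict[str, pd.DataFrame]]
) -> pd.DataFrame:
    """Mixed-effects comparison across cohorts: cell-mean deviance modelled
    with fixed effects selection × merit + cohort and a participant random
    intercept.  Returns the fixed-effect coefficient table."""
    import statsmodels.formula.api as smf

    frames = []
    for cohort, labelled in labelled_by_cohort.items():
        for pid, table in labelled.items():
            cells = cell_means(table)
            if cells is None:
                continue
            df = cells.rename("deviance").reset_index()
            df.columns = ["selection", "merit_sign", "deviance"]
            df["cohort"] = cohort
            df["participant"] = f"{cohort}:{pid}"
            frames.append(df)
    data = pd.concat(frames, ignore_index=True)
    model = smf.mixedlm(
        "deviance ~ C(selection) * C(merit_sign) + C(cohort)",
        data,
        groups=data["participant"],
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
    table = pd.DataFrame(
        {"coef": fit.fe_params, "se": fit.bse_fe, "p": fit.pvalues[fit.fe_params.index]}
    )
    return table


def sliding_deviance_plot(
    logs: dict[str, pd.DataFrame], window: int = 5, ax=None
):
    """Trial-by-trial cohort averages of deviance and selection (a smoothed
    visual companion to the condition analysis; not a tested statistic)."""
    import matplotlib.pyplot as plt

    n = min(len(log) for log in logs.values())
    dev = np.mean([observed_deviance(log)[:n] for log in logs.values()], axis=0)
    sel = np.mean(
        [(log["selection"].to_numpy()[:n] == "participant").astype(float)
         for log in logs.values()],
        axis=0,
    )
    kernel = np.ones(window) / window
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(np.convolve(dev, kernel, mode="valid"), label="advice deviance")
    ax2 = ax.twinx()
    ax2.plot(np.convolve(sel, kernel, mode="valid"), color="green",
             label="selection rate")
    ax.set_xlabel("trial")
    ax.set_ylabel("mean deviance")
    ax2.set_ylabel("mean selection")
    return ax
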