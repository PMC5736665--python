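"""The 2x2 behavioural analysis on the main cohort.

Using the interaction-model fits (02_fit_and_recover.py), labels every
trial by client selection (selected/ignored) and the sign of the fitted
relative-merit trace (positive/negative), then reports:
  * overall overconfidence (one-sample t of mean deviance vs 0, Cohen's d),
  * the ignored-vs-selected paired contrast,
  * the 2x2 repeated-measures ANOVA (merit, selection, interaction),
  * per-participant strategy classes (competitive vs defensive),
  * the correlation of emulated FNE scores with the fitted selection weight.

The signature result is that advice deviance peaks in the (ignored,
positive-merit) cell: advisers shout loudest when their merit is overlooked.
Writes results/behaviour_report.json and results/cell_means.csv.
"""

import argparse
import json
import warnings

import pandas as pd

from advicegame import analysis
from advicegame.io import read_cohort_dir

from common import COHORTS, RESULTS


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.parse_args()

    logs = read_cohort_dir(COHORTS / "main")
    fits = pd.read_csv(RESULTS / "fits_interaction.csv").set_index("participant")
    fne = pd.read_csv(COHORTS / "main" / "fne.csv")

    logs, excluded = analysis.usable_participants(logs)
    labelled = {pid: analysis.label_trials(log, fits.loc[pid, "gamma"])
                for pid, log in logs.items()}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        summary = analysis.condition_analysis(labelled)
    overview = analysis.deviance_overview(logs)
    strategy = analysis.classify_strategy(fits.loc[list(logs), "beta_selection"])
    corr = analysis.correlate_fne(fits.loc[list(logs), "beta_selection"], fne)

    print(f"overall deviance: mean {overview.cohort_mean:.2f}, "
          f"t = {overview.t:.2f}, p = {overview.p:.2g}, d = {overview.cohen_d:.2f}")
    print(f"ignored vs selected: t = {summary.paired_t:.2f}, "
          f"p = {summary.paired_p:.2g}")
    print("cell means:")
    print(summary.cohort_means.round(3).to_string())
    print(f"highest cell: {summary.max_cell}")
    print(summary.anova.round(4).to_string())
    n_comp = int((strategy.classes == "competitive").sum())
    print(f"strategy: {n_comp}/{len(strategy.classes)} competitive; "
          f"beta_selection mean {strategy.mean_beta:.3f} ± {strategy.sem_beta:.3f} "
          f"(t = {strategy.t:.2f}, p = {strategy.p:.2g})")
    print(f"FNE ~ beta_selection: r = {corr.r:.2f}, r^2 = {corr.r_squared:.2f}, "
          f"p = {corr.p:.3f} (n = {corr.n})")

    report = {
        "excluded": excluded,
        "deviance": vars(overview) | {"per_participant": None},
        "paired_contrast": {"t": summary.paired_t, "p": summary.paired_p},
        "anova": summary.anova.to_dict(),
        "max_cell": list(summary.max_cell),
        "strategy": {"n_competitive": n_comp, "mean": strategy.mean_beta,
                     "sem": strategy.sem_beta, "t": strategy.t, "p": strategy.p},
        "fne": vars(corr),
    }
    report["deviance"].pop("per_participant")
    (RESULTS / "behaviour_report.json").write_text(
        json.dumps(report, indent=2, default=str))
    cells = summary.per_participant.copy()
    cells.columns = ["_".join(c) for c in cells.columns]
    cells.to_csv(RESULTS / "cell_means.csv")


if __name__ == "__main__":
    main()
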