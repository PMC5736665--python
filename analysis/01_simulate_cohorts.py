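"""Generate the synthetic cohorts used by the downstream analyses.

Writes, under scratch/cohorts/:
  * main/   — 30 advisers playing the full selection-by-merit strategy
              (scanner schedule, 240 trials), with emulated FNE scores,
  * bias/   — 12 advisers with a pure overconfidence bias (model-recovery
              control).

Each directory holds one trial-log CSV per participant, ground_truth.csv
with the generating parameters, and (for main/) fne.csv.
"""

import argparse

from advicegame import synthetic
from advicegame.io import write_trial_log

from common import COHORTS, bias_cohort_spec, main_cohort_spec


def write_cohort(spec: synthetic.CohortSpec, out_dir) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    logs, truth, fne = synthetic.generate_cohort(spec)
    for pid, log in logs.items():
        write_trial_log(log, out_dir / f"{pid}.csv", {"participant": pid})
    truth.to_csv(out_dir / "ground_truth.csv", index=False)
    if fne is not None:
        fne.to_csv(out_dir / "fne.csv", index=False)
    print(f"{out_dir.name}: {len(logs)} participants x "
          f"{spec.schedule.n_trials} trials (model {spec.model_id})")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=7)
    args = parser.parse_args()
    write_cohort(main_cohort_spec(seed=args.seed), COHORTS / "main")
    write_cohort(bias_cohort_spec(seed=args.seed + 4), COHORTS / "bias")


if __name__ == "__main__":
    main()
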