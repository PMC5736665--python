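"""Shared study conditions for the numbered analysis scripts.

The main synthetic cohort mirrors the scanner session format (4 blocks of
60 trials) with group-mean generating parameters at the scale estimated for
human advisers: overconfidence bias 0.7, a competitive selection weight
−0.1, a small merit weight 0.05, a negative selection-by-merit interaction
−0.3, and merit learning rate 0.3, with response noise sd 0.3.
"""

from pathlib import Path

from advicegame import synthetic

RESULTS = Path(__file__).resolve().parent.parent / "results"
#: Regenerable cohort data (bulky trial logs) live outside the results tree.
COHORTS = Path(__file__).resolve().parent.parent / "scratch" / "cohorts"

INTERACTION_MEANS = {
    "bias": 0.7,
    "beta_selection": -0.1,
    "beta_merit": 0.05,
    "beta_interaction": -0.3,
    "gamma": 0.3,
}


def main_cohort_spec(seed: int = 7, n_participants: int = 30,
                     fne_rho: float | None = 0.4) -> synthetic.CohortSpec:
    return synthetic.CohortSpec(
        n_participants=n_participants,
        model_id="interaction",
        param_means=INTERACTION_MEANS,
        schedule=synthetic.schedule_preset("scanner"),
        seed=seed,
        fne_rho=fne_rho,
    )


def bias_cohort_spec(seed: int = 11, n_participants: int = 12) -> synthetic.CohortSpec:
    return synthetic.CohortSpec(
        n_participants=n_participants,
        model_id="bias",
        param_means={"bias": 0.7},
        schedule=synthetic.schedule_preset("scanner"),
        seed=seed,
    )
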