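import numpy as np
import pandas as pd
import pytest

from advicegame import analysis, synthetic
from advicegame.agents import ParticipantAgentConfig
from advicegame.analysis import (
    CELLS,
    classify_strategy,
    condition_analysis,
    correlate_fne,
    deviance_overview,
    label_trials,
    usable_participants,
)
from advicegame.learning import DevianceParams

from conftest import random_trial_log


def _log_with_dpv(dpv_signs):
    """Tiny hand-built log where each trial's ΔPV is +4, −2, or 0."""
    rows = []
    for t, d in enumerate(dpv_signs, start=1):
        if d == 4:       # P: 4-correct, R: wrong level... use (4,+1) vs (0? )
            adv_p, acc_p, adv_r, acc_r, coin = 4, 1, -2, -1, "white"
        elif d == -2:    # P wrong level 1, R correct level 1
            adv_p, acc_p, adv_r, acc_r, coin = 1, -1, -1, 1, "black"
        else:
            adv_p, acc_p, adv_r, acc_r, coin = 2, 1, 2, 1, "white"
        rows.append(dict(trial=t, selection="participant", p_black_P=0.25,
                         p_black_R=0.25, degraded="none", advice_P=adv_p,
                         advice_R=adv_r, coin_urn=coin, acc_P=acc_p, acc_R=acc_r))
    return pd.DataFrame(rows)


class TestLabelTrials:
    def test_hand_iterated_merit_labels(self):
        # gamma = 1: merit entering trials (1,2,3) is (0, +4, -2)
        log = _log_with_dpv([4, -2, 0])
        table = label_trials(log, gamma=1.0)
        assert list(table["merit_sign"]) == ["positive", "positive", "negative"]
        assert list(table["selection"]) == ["selected"] * 3

    def test_zero_delta_pv_labels_all_positive(self):
        log = _log_with_dpv([0, 0, 0, 0])
        table = label_trials(log, gamma=0.8)
        assert (table["merit_sign"] == "positive").all()
        assert (table["relative_merit"] == 0).all()

    def test_labels_do_not_depend_on_deviance(self):
        log = _log_with_dpv([4, -2, 0])
        shifted = log.copy()
        shifted["advice_P"] = [4, 1, 2]  # same urns/accuracy, confidence varies
        a = label_trials(log, 0.5)[["selection", "merit_sign"]]
        b = label_trials(shifted, 0.5)[["selection", "merit_sign"]]
        pd.testing.assert_frame_equal(a, b)

    def test_missing_outcome_rejected(self):
        log = _log_with_dpv([4, 0]).drop(columns="acc_R")
        with pytest.raises(ValueError, match="acc_R"):
            label_trials(log, 0.5)

    def test_gamma_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            label_trials(_log_with_dpv([0]), 1.2)


def _toy_labelled(values_by_cell, n_per_cell=2):
    rows = []
    t = 1
    for (sel, mer), value in values_by_cell.items():
        for k in range(n_per_cell):
            rows.append(dict(trial=t, deviance=value + 0.1 * k, selection=sel,
                             merit_sign=mer, relative_merit=0.0))
            t += 1
    return pd.DataFrame(rows)


class TestConditionAnalysis:
    def test_cell_means_match_hand_arithmetic(self):
        cells_a = {c: v for c, v in zip(CELLS, [0.0, 0.4, 1.0, 0.2])}
        cells_b = {c: v for c, v in zip(CELLS, [0.2, 0.6, 1.4, 0.0])}
        summary = condition_analysis(
            {"a": _toy_labelled(cells_a), "b": _toy_labelled(cells_b)}
        )
        # each toy cell holds (v, v+0.1) so the cell mean is v + 0.05
        assert summary.per_participant.loc["a", ("ignored", "positive")] == \
            pytest.approx(1.05)
        assert summary.cohort_means[("ignored", "positive")] == pytest.approx(1.25)
        assert summary.n_used == 2

    def test_empty_cell_participant_excluded_with_warning(self):
        cells = {c: v for c, v in zip(CELLS, [0.0, 0.4, 1.0, 0.2])}
        complete = {f"p{i}": _toy_labelled(cells) for i in range(3)}
        broken = _toy_labelled(cells)
        broken = broken[broken["merit_sign"] == "positive"]
        with pytest.warns(UserWarning, match="empty 2x2"):
            summary = condition_analysis({**complete, "bad": broken})
        assert summary.excluded == ["bad"]
        assert summary.n_used == 3

    def test_fewer_than_two_usable_raises(self):
        cells = {c: v for c, v in zip(CELLS, [0.0, 0.4, 1.0, 0.2])}
        with pytest.raises(ValueError):
            condition_analysis({"only": _toy_labelled(cells)})

    def test_statistics_match_independent_reference(self, rng):
        """F and p values agree with pingouin's repeated-measures ANOVA on
        random cell tables, and the paired contrast with scipy, to 1e-8."""
        pingouin = pytest.importorskip("pingouin")
        for rep in range(5):
            labelled = {
                f"p{i}": _toy_labelled(
                    {c: rng.normal(0.5, 0.4) for c in CELLS}, n_per_cell=3
                )
                for i in range(8)
            }
            summary = condition_analysis(labelled)
            long = summary.per_participant.stack(
                ["selection", "merit_sign"], future_stack=True
            ).rename("deviance").reset_index()
            ref = pingouin.rm_anova(
                data=long, dv="deviance", within=["selection", "merit_sign"],
                subject="participant", detailed=True,
            ).set_index("Source")
            assert summary.anova.loc["selection", "F"] == pytest.approx(
                ref.loc["selection", "F"], abs=1e-8)
            assert summary.anova.loc["merit", "F"] == pytest.approx(
                ref.loc["merit_sign", "F"], abs=1e-8)
            assert summary.anova.loc["interaction", "F"] == pytest.approx(
                ref.loc["selection * merit_sign", "F"], abs=1e-8)
            assert summary.anova.loc["interaction", "p"] == pytest.approx(
                ref.loc["selection * merit_sign", "p_unc"], abs=1e-8)


class TestStrategy:
    def test_sign_rule_with_boundary(self):
        beta = pd.Series({"a": -0.07, "b": 0.1, "c": 0.0})
        report = classify_strategy(beta)
        assert report.classes.to_dict() == {
            "a": "competitive", "b": "defensive", "c": "defensive"
        }

    def test_group_test_matches_scipy(self, rng):
        from scipy import stats

        beta = pd.Series(rng.normal(-0.07, 0.2, size=40))
        report = classify_strategy(beta)
        t, p = stats.ttest_1samp(beta, 0.0)
        assert report.t == pytest.approx(float(t))
        assert report.p == pytest.approx(float(p))


class TestFNECorrelation:
    def test_recovers_built_in_correlation(self):
        spec = synthetic.CohortSpec(
            n_participants=69, model_id="client",
            param_means={"bias": 0.5, "beta_selection": 0.0},
            schedule=synthetic.schedule_preset("online"), seed=17, fne_rho=0.4,
        )
        _, truth, fne = synthetic.generate_cohort(spec)
        beta = truth.set_index("participant_id")["beta_selection"]
        report = correlate_fne(beta, fne)
        assert report.n == 69
        assert report.r == pytest.approx(0.4, abs=0.15)
        assert report.r_squared == pytest.approx(report.r**2)

    def test_constant_fne_rejected(self):
        beta = pd.Series(np.linspace(-0.2, 0.2, 12),
                         index=[f"p{i}" for i in range(12)])
        fne = pd.DataFrame({"participant_id": beta.index, "fne_score": 30})
        with pytest.raises(ValueError, match="constant"):
            correlate_fne(beta, fne)

    def test_unmatched_ids_rejected(self):
        beta = pd.Series(np.linspace(-0.2, 0.2, 12),
                         index=[f"p{i}" for i in range(12)])
        fne = pd.DataFrame({"participant_id": ["p0", "zz"],
                            "fne_score": [20, 40]})
        with pytest.raises(ValueError, match="unmatched"):
            correlate_fne(beta, fne)

    def test_too_few_pairs_rejected(self):
        beta = pd.Series([0.1, -0.1], index=["a", "b"])
        fne = pd.DataFrame({"participant_id": ["a", "b"], "fne_score": [20, 40]})
        with pytest.raises(ValueError, match="pairs"):
            correlate_fne(beta, fne)


class TestDevianceOverview:
    def test_zero_deviance_cohort_not_significant(self):
        agent = ParticipantAgentConfig(
            params=DevianceParams(model_id="bias", bias=0.0),
            response_noise_sd=0.0,
        )
        sched = synthetic.ExperimentSchedule(n_trials=60, block_length=60)
        logs = {f"p{i}": synthetic.simulate_participant(agent, sched, seed=i)
                for i in range(4)}
        report = deviance_overview(logs)
        assert abs(report.cohort_mean) < 0.25
        assert report.p > 0.05 or abs(report.cohort_mean) < 0.05

    def test_biased_cohort_mean_near_generating_bias(self):
        agent = ParticipantAgentConfig(
            params=DevianceParams(model_id="bias", bias=0.7),
            response_noise_sd=0.3,
        )
        sched = synthetic.schedule_preset("scanner")
        logs = {f"p{i}": synthetic.simulate_participant(agent, sched, seed=50 + i)
                for i in range(6)}
        report = deviance_overview(logs)
        assert report.cohort_mean == pytest.approx(0.7, abs=0.1)

    def test_cohen_d_hand_fixture(self, rng):
        logs = {pid: random_trial_log(rng, 25) for pid in ("a", "b", "c")}
        report = deviance_overview(logs)
        means = report.per_participant
        assert report.cohen_d == pytest.approx(means.mean() / means.std(ddof=1))


class TestExclusions:
    def test_flat_responder_dropped(self, rng):
        keep = random_trial_log(rng, 30)
        flat = keep.copy()
        flat["advice_P"] = 3
        flat["acc_P"] = np.where(flat["coin_urn"] == "white", 1, -1)
        with pytest.warns(UserWarning, match="distinct confidence"):
            kept, dropped = usable_participants({"good": keep, "flat": flat})
        assert list(kept) == ["good"]
        assert dropped == ["flat"]


def test_cohort_comparison_smoke(rng):
    """Mixed-effects cohort comparison returns a coefficient table including
    the cohort fixed effect."""
    def cohort(seed):
        cells = {c: v for c, v in zip(CELLS, [0.0, 0.4, 1.0, 0.2])}
        return {f"p{seed}{i}": _toy_labelled(
            {c: v + rng.normal(0, 0.1) for c, v in cells.items()})
            for i in range(6)}
    table = analysis.compare_cohorts({"virtual": cohort(1), "live": cohort(2)})
    assert any("cohort" in ix for ix in table.index)
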