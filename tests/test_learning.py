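import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from advicegame.learning import (
    MODEL_IDS,
    MODEL_PARAMS,
    DevianceParams,
    MeritState,
    TrialCovariates,
    delta_prognostic_value,
    merit_trace,
    merit_update,
    predict_deviance,
    run_model,
)
from advicegame.task_core import Advice


def brute_force_model(params: DevianceParams, S, dpv):
    """Independent per-trial re-derivation of the model traces (plain
    Python, no vectorization), used as the oracle for run_model."""
    gamma = params.gamma if "gamma" in MODEL_PARAMS[params.model_id] else 0.0
    rm = 0.0
    preds, rms, pes = [], [], []
    for t in range(len(S)):
        rms.append(rm)
        sign = 1.0 if rm >= 0 else -1.0
        m = rm if params.model_id == "amplitude" else sign
        preds.append(
            params.bias
            + params.beta_selection * S[t]
            + params.beta_merit * m
            + params.beta_interaction * S[t] * m
        )
        pe = dpv[t] - rm
        pes.append(pe)
        rm = rm + gamma * pe
    return np.array(preds), np.array(rms), np.array(pes)


class TestMeritLearning:
    @pytest.mark.parametrize(
        "lv_p, acc_p, lv_r, acc_r, expected",
        [(5, 1, 2, -1, 7), (3, -1, 3, -1, 0), (1, 1, 5, 1, -4)],
    )
    def test_delta_prognostic_value(self, lv_p, acc_p, lv_r, acc_r, expected):
        adv = lambda lv: Advice("white", lv)
        assert delta_prognostic_value(adv(lv_p), acc_p, adv(lv_r), acc_r) == expected

    def test_delta_rule_step(self):
        state, pe = merit_update(MeritState(gamma=0.5), 4.0)
        assert (state.relative_merit, pe) == (2.0, 4.0)

    def test_degenerate_learning_rates(self):
        frozen, _ = merit_update(MeritState(gamma=0.0, relative_merit=1.5), 9.0)
        assert frozen.relative_merit == 1.5
        full, _ = merit_update(MeritState(gamma=1.0, relative_merit=1.5), -3.0)
        assert full.relative_merit == -3.0

    def test_trace_by_hand_iteration(self):
        # gamma=1: merit entering each trial equals the previous trial's dPV
        assert merit_trace([4.0, -2.0, 0.0], 1.0) == pytest.approx([0, 4, -2])

    @settings(derandomize=True)
    @given(
        gamma=st.floats(0.0, 1.0),
        dpv=st.lists(st.integers(-10, 10), min_size=1, max_size=60),
    )
    def test_trace_bounded_by_max_delta_pv(self, gamma, dpv):
        trace = merit_trace(np.array(dpv, dtype=float), gamma)
        assert np.all(np.abs(trace) <= 10 + 1e-12)


class TestDevianceModels:
    def test_group_mean_prediction(self):
        params = DevianceParams(model_id="interaction", bias=0.67,
                                beta_selection=-0.07, gamma=0.3)
        assert predict_deviance(params, TrialCovariates(1, 0.0)) == pytest.approx(0.60)

    def test_single_active_interaction_term(self):
        params = DevianceParams(model_id="interaction", beta_interaction=1.0,
                                gamma=0.3)
        assert predict_deviance(params, TrialCovariates(-1, 2.0)) == -1.0

    def test_bias_model_is_constant(self):
        params = DevianceParams(model_id="bias", bias=0.5)
        for s, m in [(1, 3.0), (-1, -2.0)]:
            assert predict_deviance(params, TrialCovariates(s, m)) == 0.5

    def test_inactive_parameters_rejected(self):
        with pytest.raises(ValueError):
            DevianceParams(model_id="bias", beta_selection=0.3)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            DevianceParams(model_id="quadratic")

    def test_nesting_reductions(self, rng):
        """With inactive weights at 0 the richer models reproduce the
        poorer ones exactly."""
        S = rng.choice([-1.0, 1.0], size=40)
        dpv = rng.integers(-10, 11, size=40).astype(float)
        full = dict(bias=0.4, beta_selection=-0.2, beta_merit=0.1,
                    beta_interaction=-0.3, gamma=0.35)
        inter = run_model(DevianceParams(model_id="interaction", **full), S, dpv)
        mixed_p = {**full, "beta_interaction": 0.0}
        mixed = run_model(DevianceParams(model_id="mixed", bias=mixed_p["bias"],
                                         beta_selection=mixed_p["beta_selection"],
                                         beta_merit=mixed_p["beta_merit"],
                                         gamma=mixed_p["gamma"]), S, dpv)
        inter_as_mixed = run_model(
            DevianceParams(model_id="interaction", **mixed_p), S, dpv)
        pd.testing.assert_frame_equal(inter_as_mixed, mixed)
        client = run_model(DevianceParams(model_id="client", bias=0.4,
                                          beta_selection=-0.2), S, dpv)
        inter_as_client = run_model(
            DevianceParams(model_id="interaction", bias=0.4, beta_selection=-0.2,
                           gamma=0.35), S, dpv)
        assert np.allclose(inter_as_client["predicted_deviance"],
                           client["predicted_deviance"])
        bias_only = run_model(DevianceParams(model_id="bias", bias=0.4), S, dpv)
        assert np.allclose(bias_only["predicted_deviance"], 0.4)
        assert not np.allclose(inter["predicted_deviance"],
                               mixed["predicted_deviance"])

    def test_negative_selection_weight_is_competitive(self, rng):
        """β_selection < 0 predicts strictly larger deviance on ignored
        trials — the competitive signature."""
        S = np.array([1.0, -1.0] * 20)
        dpv = rng.integers(-10, 11, size=40).astype(float)
        out = run_model(
            DevianceParams(model_id="client", bias=0.5, beta_selection=-0.2),
            S, dpv)
        pred = out["predicted_deviance"].to_numpy()
        assert np.all(pred[S < 0] > pred[S > 0].max() - 1e-12)

    @pytest.mark.parametrize("model_id", MODEL_IDS)
    def test_run_model_matches_brute_force(self, model_id, rng):
        for _ in range(5):
            n = 20
            S = rng.choice([-1.0, 1.0], size=n)
            dpv = rng.integers(-10, 11, size=n).astype(float)
            kwargs = {
                name: (rng.uniform(0, 1) if name == "gamma"
                       else rng.normal(0, 0.5))
                for name in MODEL_PARAMS[model_id]
            }
            params = DevianceParams(model_id=model_id, **kwargs)
            out = run_model(params, S, dpv)
            preds, rms, pes = brute_force_model(params, S, dpv)
            assert np.allclose(out["predicted_deviance"], preds, atol=1e-12)
            assert np.allclose(out["relative_merit"], rms, atol=1e-12)
            assert np.allclose(out["merit_pe"], pes, atol=1e-12)

    def test_all_zero_delta_pv_gives_positive_sign_throughout(self):
        out = run_model(DevianceParams(model_id="merit", beta_merit=0.3, gamma=0.5),
                        np.ones(10), np.zeros(10))
        assert (out["relative_merit"] == 0).all()
        assert (out["merit_sign"] == 1).all()

    def test_malformed_selection_rejected(self):
        with pytest.raises(ValueError):
            run_model(DevianceParams(model_id="bias"), np.array([1.0, 0.5]),
                      np.array([1.0, 2.0]))
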