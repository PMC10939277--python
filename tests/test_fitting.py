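"""Simulation-based two-step parameter fitting: identities and recovery."""

import numpy as np
import pandas as pd
import pytest

from flowparse import fitting as ft
from flowparse import observer as ob
from flowparse.psychometrics import fit_all


def make_prediction_trials(bias, v_self=3.6, participant=0):
    """Noise-free prediction trials with an exact opposite-direction bias."""
    rows = []
    for v in (4.0, 5.0, 6.0):
        for occ in (0.5, 0.6, 0.7):
            for prof in ("static", "opposite"):
                shift = bias * v_self if prof == "opposite" else 0.0
                resp = occ * v / (v + shift)
                for k in range(3):
                    # tiny deterministic jitter so SDs are defined
                    rows.append((participant, v, prof, occ, resp + 1e-6 * (k - 1)))
    df = pd.DataFrame(
        rows, columns=["participant_id", "ball_speed_mps", "motion_profile",
                       "occlusion_s", "response_s"]
    )
    df["error_s"] = df["response_s"] - df["occlusion_s"]
    return df


class TestSummaries:
    def test_identical_conditions_give_zero_differences(self):
        df = make_prediction_trials(bias=0.0)
        out = ft.summarize_prediction_differences(df, "opposite")
        np.testing.assert_allclose(out["d_mean"], 0.0, atol=1e-9)

    def test_noise_free_bias_gives_expected_mean_error_difference(self):
        # occ 0.7, v 4, bias 0.2: 2.8/4.72 - 0.7 = -0.107 s
        df = make_prediction_trials(bias=0.2)
        out = ft.summarize_prediction_differences(df, "opposite")
        cell = out[(out["ball_speed_mps"] == 4.0) & (out["occlusion_s"] == 0.7)]
        assert cell["d_mean"].iloc[0] == pytest.approx(2.8 / 4.72 - 0.7, abs=1e-5)

    def test_missing_static_cells_raise(self):
        df = make_prediction_trials(bias=0.2)
        with pytest.raises(ValueError):
            ft.summarize_prediction_differences(
                df[df["motion_profile"] != "static"], "opposite"
            )

    def test_speed_summary_shape(self, small_cohort):
        fits = fit_all(small_cohort["speed"])
        one = fits[fits["participant_id"] == 0]
        out = ft.summarize_speed_differences(one, "opposite")
        assert list(out["ball_speed_mps"]) == [4.0, 5.0, 6.0]


class TestSimulators:
    def test_prediction_scaling_identity_is_exact(self):
        # noise off: timing-error difference equals occ*(v/(v+a*3.6) - 1)
        pop = ob.PopulationSpec(weber_speed_mean=0.0, weber_speed_sd=0.0, weber_distance=0.0)
        sim = ft.PredictionTaskSimulator(pop, np.random.default_rng(0), repetitions=3, n_sim=25)
        a = 0.27
        d_mean, _ = sim.diff_summaries(a, 0.0)
        expected = sim.occ * (sim.v / (sim.v + a * 3.6) - 1.0)
        np.testing.assert_allclose(
            d_mean, np.broadcast_to(expected, d_mean.shape), atol=1e-9
        )

    def test_speed_simulator_pse_shift_tracks_accuracy_param(self):
        pop = ob.PopulationSpec()
        sim = ft.SpeedTaskSimulator(pop, np.random.default_rng(1), n_sim=25)
        d_pse, _ = sim.diff_summaries(0.2, 0.0)
        assert d_pse.mean() == pytest.approx(0.2 * 3.6, abs=0.08)

    def test_common_random_numbers_make_objective_deterministic(self):
        pop = ob.PopulationSpec()
        sim = ft.PredictionTaskSimulator(pop, np.random.default_rng(2), repetitions=13)
        a, b = sim.diff_summaries(0.1, 0.0), sim.diff_summaries(0.1, 0.0)
        np.testing.assert_array_equal(a[0], b[0])


class TestTwoStepFit:
    def test_prediction_recovery_single_participant(self):
        pop = ob.PopulationSpec()
        rng = np.random.default_rng(31)
        obs = [ob.ObserverParams(0, bias_opposite=0.3, precision_opposite=0.0,
                                 weber_speed=0.10, weber_distance=0.05)]
        trials = ob.simulate_prediction_experiment(
            ob.PredictionDesign(n_participants=1, repetitions=13), pop, rng, observers=obs
        )
        eff = ft.fit_participant_prediction(trials, pop, "opposite", rng)
        assert eff.accuracy_param == pytest.approx(0.30, abs=0.10)

    def test_null_recovery_single_participant(self):
        pop = ob.PopulationSpec()
        rng = np.random.default_rng(37)
        obs = [ob.ObserverParams(0, bias_opposite=0.0, precision_opposite=0.0,
                                 weber_speed=0.10, weber_distance=0.05)]
        trials = ob.simulate_prediction_experiment(
            ob.PredictionDesign(n_participants=1, repetitions=13), pop, rng, observers=obs
        )
        eff = ft.fit_participant_prediction(trials, pop, "opposite", rng)
        assert abs(eff.accuracy_param) < 0.1

    def test_objective_minimised_near_generative_value(self):
        pop = ob.PopulationSpec()
        rng = np.random.default_rng(41)
        obs = [ob.ObserverParams(0, bias_opposite=0.2, weber_speed=0.10, weber_distance=0.05)]
        trials = ob.simulate_prediction_experiment(
            ob.PredictionDesign(n_participants=1, repetitions=13), pop, rng, observers=obs
        )
        summary = ft.summarize_prediction_differences(trials, "opposite")
        sim = ft.PredictionTaskSimulator(pop, rng, repetitions=13)
        obs_vec = summary["d_mean"].to_numpy()

        def objective(a):
            return ft._rmedse(sim.diff_summaries(a, 0.0)[0], obs_vec)

        assert objective(0.2) < objective(0.7)
        assert objective(0.2) < objective(-0.3)

    def test_fit_is_deterministic_under_fixed_seed(self):
        pop = ob.PopulationSpec()
        obs = [ob.ObserverParams(0, bias_opposite=0.25, weber_speed=0.10, weber_distance=0.05)]
        trials = ob.simulate_prediction_experiment(
            ob.PredictionDesign(n_participants=1, repetitions=13), pop,
            np.random.default_rng(5), observers=obs,
        )
        a = ft.fit_participant_prediction(trials, pop, "opposite", np.random.default_rng(9))
        b = ft.fit_participant_prediction(trials, pop, "opposite", np.random.default_rng(9))
        assert a.accuracy_param == b.accuracy_param
        assert a.precision_param == b.precision_param

    def test_two_step_ordering_matters(self):
        # fitting precision on biased data without first fitting accuracy
        # absorbs the bias into an inflated precision estimate
        pop = ob.PopulationSpec()
        rng = np.random.default_rng(43)
        obs = [ob.ObserverParams(0, bias_opposite=0.35, precision_opposite=0.0,
                                 weber_speed=0.10, weber_distance=0.05)]
        trials = ob.simulate_prediction_experiment(
            ob.PredictionDesign(n_participants=1, repetitions=13), pop, rng, observers=obs
        )
        summary = ft.summarize_prediction_differences(trials, "opposite")
        sim = ft.PredictionTaskSimulator(pop, rng, repetitions=13)
        acc, _ = ft.fit_accuracy_param(summary["d_mean"].to_numpy(), sim)
        p_proper, _ = ft.fit_precision_param(summary["d_sd"].to_numpy(), sim, acc)
        p_first, _ = ft.fit_precision_param(summary["d_sd"].to_numpy(), sim, 0.0)
        assert abs(p_proper) <= abs(p_first)


class TestCohortSummaries:
    def _effects(self, n=40, slope=1.0, shared=True, seed=0):
        rng = np.random.default_rng(seed)
        true = rng.normal(0.2, 0.3, n)
        speed = true + rng.normal(0, 0.05, n)
        base = true if shared else rng.normal(0.2, 0.3, n)
        pred = slope * base + rng.normal(0, 0.05, n)
        prec = rng.normal(0.1, 0.05, (n, 2))
        rows = []
        for i in range(n):
            rows.append((i, "prediction", "opposite", pred[i], prec[i, 0]))
            rows.append((i, "speed_estimation", "opposite", speed[i], prec[i, 1]))
        return pd.DataFrame(
            rows, columns=["participant_id", "task", "direction",
                           "accuracy_param", "precision_param"]
        )

    def test_shared_parameter_slope_near_one(self):
        res = ft.cross_task_regression(self._effects())
        acc = res[res["domain"] == "accuracy"].iloc[0]
        assert acc["ci_low"] < 1.0 < acc["ci_high"]

    def test_doubled_parameter_slope_near_two(self):
        res = ft.cross_task_regression(self._effects(slope=2.0, seed=1))
        acc = res[res["domain"] == "accuracy"].iloc[0]
        assert acc["slope"] == pytest.approx(2.0, abs=0.2)

    def test_independent_parameters_null_slope(self):
        res = ft.cross_task_regression(self._effects(shared=False, seed=2))
        acc = res[res["domain"] == "accuracy"].iloc[0]
        assert acc["ci_low"] < 0.0 < acc["ci_high"]

    def test_degenerate_regressor_refused(self):
        eff = self._effects()
        eff.loc[eff["task"] == "speed_estimation", "accuracy_param"] = 0.5
        with pytest.raises(ValueError):
            ft.cross_task_regression(eff)

    def test_one_sample_tests_layout_and_nulls(self):
        eff = self._effects()
        out = ft.one_sample_tests(eff)
        assert {"task", "direction", "domain", "mean", "p_value"} <= set(out.columns)
        acc = out[(out["task"] == "prediction") & (out["domain"] == "accuracy")]
        assert acc["p_value"].iloc[0] < 0.05  # mean 0.2 with SEM ~0.05

    def test_one_sample_refuses_constant_values(self):
        eff = self._effects()
        eff["accuracy_param"] = 0.3
        out = ft.one_sample_tests(eff)
        acc = out[out["domain"] == "accuracy"]
        assert acc["note"].str.contains("refused").all()
        assert acc["p_value"].isna().all()
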