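"""Generative observer model: bias propagation, noise moments, design sizes."""

import numpy as np
import pytest

from flowparse import observer as ob
from flowparse.kinematics import TrialGeometry


def quiet_observer(bias_opposite=0.2, precision_opposite=0.0, weber_speed=1e-12):
    """An observer whose perceptual noise is numerically negligible."""
    return ob.ObserverParams(
        participant_id=0,
        bias_opposite=bias_opposite,
        precision_opposite=precision_opposite,
        weber_speed=weber_speed,
        weber_distance=0.0,
    )


class TestDrawObserver:
    def test_zero_sds_give_identical_observers(self, rng):
        pop = ob.PopulationSpec(bias_sd=0, precision_effect_sd=0, weber_speed_sd=0)
        a = ob.draw_observer(pop, rng)
        b = ob.draw_observer(pop, rng)
        assert a.bias_opposite == b.bias_opposite == pop.bias_mean
        assert a.weber_speed == b.weber_speed == pop.weber_speed_mean

    def test_population_moments_recovered(self):
        pop = ob.PopulationSpec()
        rng = np.random.default_rng(99)
        draws = np.array([ob.draw_observer(pop, rng).bias_opposite for _ in range(10_000)])
        assert draws.mean() == pytest.approx(0.20, abs=0.01)
        assert draws.std() == pytest.approx(0.30, abs=0.01)

    def test_seed_determinism(self):
        pop = ob.PopulationSpec()
        a = ob.draw_observer(pop, np.random.default_rng(5))
        b = ob.draw_observer(pop, np.random.default_rng(5))
        assert a == b

    def test_truncations_respected(self):
        pop = ob.PopulationSpec(weber_speed_mean=0.02, weber_speed_sd=0.05,
                                precision_effect_mean=-0.5, precision_effect_sd=1.0)
        rng = np.random.default_rng(1)
        for _ in range(200):
            o = ob.draw_observer(pop, rng)
            assert o.weber_speed > 0.01
            assert o.precision_opposite > -0.9


class TestPerceivedSpeed:
    def test_opposite_bias_shifts_mean_by_fraction_of_self_speed(self):
        obs = quiet_observer()
        v = ob.perceived_speed_sample(4.0, "opposite", obs, 3.6, np.random.default_rng(0))
        assert v == pytest.approx(4.0 + 0.2 * 3.6, abs=1e-9)  # 4.72

    def test_static_profile_is_unbiased(self):
        obs = quiet_observer()
        v = ob.perceived_speed_sample(4.0, "static", obs, 3.6, np.random.default_rng(0))
        assert v == pytest.approx(4.0, abs=1e-9)

    def test_noise_moments_follow_weber_and_precision(self):
        # SD = weber * mean * (1 + precision effect)
        obs = ob.ObserverParams(0, bias_opposite=0.2, precision_opposite=0.2,
                                weber_speed=0.10, weber_distance=0.05)
        rng = np.random.default_rng(4)
        samples = ob.perceived_speed_sample(5.0, "opposite", obs, 3.6, rng, size=10_000)
        expected_sd = 0.10 * (5.0 + 0.72) * 1.2
        assert samples.std() == pytest.approx(expected_sd, rel=0.02)
        assert samples.mean() == pytest.approx(5.72, abs=3 * expected_sd / 100)

    def test_samples_respect_floor(self):
        obs = ob.ObserverParams(0, bias_opposite=0.0, weber_speed=2.0, weber_distance=0.0)
        rng = np.random.default_rng(8)
        samples = ob.perceived_speed_sample(0.5, "static", obs, 3.6, rng, size=2000)
        assert (samples > ob.PERCEPT_FLOOR).all()


class TestPredictionTrials:
    def test_veridical_percepts_give_exact_timing(self):
        geom = TrialGeometry(ball_speed=4, occlusion_duration=0.6)
        trial = ob.simulate_prediction_trial(
            geom, "static", quiet_observer(), ob.PopulationSpec(), np.random.default_rng(0)
        )
        assert trial["response_s"] == pytest.approx(0.6, abs=1e-9)

    def test_opposite_bias_makes_press_early(self):
        # d / (v + bias * v_self): 2.8 / 4.72 = 0.593 s, 0.107 s early
        geom = TrialGeometry(ball_speed=4, occlusion_duration=0.7)
        trial = ob.simulate_prediction_trial(
            geom, "opposite", quiet_observer(), ob.PopulationSpec(), np.random.default_rng(0)
        )
        assert trial["response_s"] == pytest.approx(2.8 / 4.72, abs=1e-6)
        assert trial["error_s"] == pytest.approx(2.8 / 4.72 - 0.7, abs=1e-6)

    def test_negative_same_direction_bias_makes_press_late(self):
        obs = ob.ObserverParams(0, bias_opposite=0.0, bias_same=-0.06,
                                weber_speed=1e-12, weber_distance=0.0)
        geom = TrialGeometry(ball_speed=4, occlusion_duration=0.6)
        trial = ob.simulate_prediction_trial(
            geom, "same", obs, ob.PopulationSpec(), np.random.default_rng(0)
        )
        assert trial["response_s"] > 0.6

    def test_extrapolation_identity_on_every_trial(self, small_cohort):
        df = small_cohort["prediction"]
        np.testing.assert_allclose(
            df["response_s"] * df["v_perceived_mps"], df["d_perceived_m"], rtol=1e-12
        )


class TestExperimentDesign:
    @pytest.mark.parametrize("reps,expected", [(5, 240), (13, 624)])
    def test_rows_per_participant_with_static_extras(self, reps, expected):
        d = ob.PredictionDesign(n_participants=1, repetitions=reps)
        assert d.trials_per_participant == expected

    def test_main_design_rows_at_13_reps(self):
        d = ob.PredictionDesign(n_participants=1, repetitions=13, include_static_extra=False)
        assert d.trials_per_participant == 3 * 3 * 3 * 13 == 351

    def test_zero_noise_static_cells_have_zero_error(self):
        pop = ob.PopulationSpec(bias_sd=0, precision_effect_sd=0,
                                weber_speed_mean=1e-12, weber_speed_sd=0, weber_distance=0)
        d = ob.PredictionDesign(n_participants=2, repetitions=3)
        obs = [quiet_observer(bias_opposite=0.0), quiet_observer(bias_opposite=0.0)]
        obs = [ob.ObserverParams(i, 0.0, weber_speed=1e-12, weber_distance=0.0) for i in range(2)]
        df = ob.simulate_prediction_experiment(d, pop, np.random.default_rng(0), observers=obs)
        static = df[df["motion_profile"] == "static"]
        np.testing.assert_allclose(static["error_s"], 0.0, atol=1e-9)

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError):
            ob.PredictionDesign(n_participants=0)
        with pytest.raises(ValueError):
            ob.PredictionDesign(speeds=())

    def test_null_population_profiles_indistinguishable(self):
        # no generative effect: per-profile means agree within 2 SEM
        pop = ob.PopulationSpec.null()
        d = ob.PredictionDesign(n_participants=4, repetitions=100,
                                include_static_extra=False)
        df = ob.simulate_prediction_experiment(d, pop, np.random.default_rng(3))
        g = df.groupby("motion_profile")["error_s"]
        means, sems = g.mean(), g.sem()
        spread = means.max() - means.min()
        assert spread < 2 * (sems.max() + sems.min())


class TestTwoIFC:
    def test_much_faster_cloud_always_chosen(self):
        trial = ob.simulate_2ifc_trial(
            4.0, 11.0, "static", quiet_observer(), ob.PopulationSpec(), np.random.default_rng(0)
        )
        assert trial["chose_cloud"] is True

    def test_matched_cloud_chosen_half_the_time(self):
        obs = ob.ObserverParams(0, bias_opposite=0.2, weber_speed=0.10, weber_distance=0.05)
        rng = np.random.default_rng(17)
        pop = ob.PopulationSpec()
        # cloud at the ball's biased percept mean
        chosen = [
            ob.simulate_2ifc_trial(4.0, 4.72, "opposite", obs, pop, rng)["chose_cloud"]
            for _ in range(10_000)
        ]
        assert np.mean(chosen) == pytest.approx(0.5, abs=0.02)

    def test_choice_probability_crosses_half_at_biased_pse(self):
        # brute-force psychometric sweep: the 50% point sits at v + 0.72
        obs = ob.ObserverParams(0, bias_opposite=0.2, weber_speed=0.10, weber_distance=0.05)
        pop = ob.PopulationSpec()
        rng = np.random.default_rng(23)
        n = 20_000
        ball = ob.perceived_speed_sample(4.0, "opposite", obs, 3.6, rng, size=n)
        grid = np.linspace(4.0, 5.6, 33)
        p = np.empty(grid.size)
        for i, c in enumerate(grid):
            cloud = np.maximum(c + obs.weber_speed * c * rng.standard_normal(n), ob.PERCEPT_FLOOR)
            p[i] = np.mean(cloud > ball)
        pse = np.interp(0.5, p, grid)
        assert pse == pytest.approx(4.72, abs=0.05)


class TestSpeedExperiment:
    def test_staircase_count_and_trial_bounds(self, small_cohort):
        df = small_cohort["speed"]
        per_part = df.groupby("participant_id")["staircase_id"].nunique()
        assert (per_part == 18).all()
        totals = df.groupby("participant_id").size()
        assert totals.between(540, 666).all()

    def test_simulation_is_seed_reproducible(self):
        pop = ob.PopulationSpec()
        d = ob.SpeedDesign(n_participants=2)
        a = ob.simulate_speed_experiment(d, pop, np.random.default_rng(42))
        b = ob.simulate_speed_experiment(d, pop, np.random.default_rng(42))
        assert a.equals(b)

    def test_timing_error_sd_scales_with_occlusion(self):
        # Weber-like behaviour: response SD grows with occlusion duration
        pop = ob.PopulationSpec()
        obs = [ob.ObserverParams(0, 0.0, weber_speed=0.10, weber_distance=0.05)]
        d = ob.PredictionDesign(n_participants=1, repetitions=400,
                                occlusions=(0.5, 1.0), profiles=("static",),
                                speeds=(5.0,), include_static_extra=False)
        df = ob.simulate_prediction_experiment(d, pop, np.random.default_rng(6), observers=obs)
        sds = df.groupby("occlusion_s")["response_s"].std()
        assert sds[1.0] / sds[0.5] == pytest.approx(2.0, rel=0.2)
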