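"""Ground-truth recoverability of the synthetic-session generator."""

import numpy as np
import pytest
from scipy import stats

from poselab import synth
from poselab.design import (CHOICE_DIRECTIONS, DesignGrid,
                            FRONTOPARALLEL_TILT, SurfacePose)
from poselab.circstats import wrap_diff


class TestDeterminism:
    def test_behavior_bit_identical_under_seed(self, grid):
        spec = synth.default_behavior_spec(grid)
        a = synth.simulate_behavior(spec, grid, 2, seed=9)
        b = synth.simulate_behavior(spec, grid, 2, seed=9)
        assert a.equals(b)

    def test_spike_trains_bit_identical_under_seed(self):
        spec = synth.NeuronSpec()
        pose = SurfacePose(90.0, 30.0, 57.0)
        a = synth.simulate_neuron_trial(spec, pose, 90.0, seed=5)
        b = synth.simulate_neuron_trial(spec, pose, 90.0, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_session_serialization_roundtrip(self, grid, tmp_path):
        cohort = synth.make_neuron_cohort(2, seed=0)
        sess = synth.simulate_session(cohort, n_blocks=1, seed=1)
        synth.session_to_csv(sess, tmp_path)
        for name in ("trials.csv", "spikes.csv", "eyes.csv", "truth.json"):
            assert (tmp_path / name).exists()


class TestBehaviorGenerator:
    def test_kappa_cap_nearly_all_correct(self, grid):
        spec = synth.BehaviorSpec(
            kappa_by_condition={(s, d): 18.0 for s in grid.slants if s > 0
                                for d in grid.distances},
            lapse_rate=0.0)
        t = synth.simulate_behavior(spec, grid, 5, seed=2)
        slanted = t[t["slant"] > 0]
        assert slanted["correct"].mean() >= 0.97

    def test_low_kappa_uniform_choices(self, grid):
        spec = synth.BehaviorSpec(
            kappa_by_condition={(s, d): 1e-4 for s in grid.slants if s > 0
                                for d in grid.distances},
            lapse_rate=0.0)
        t = synth.simulate_behavior(spec, grid, 20, seed=3)
        slanted = t[t["slant"] > 0]
        counts = slanted.groupby("choice").size()
        assert stats.chisquare(counts).pvalue > 0.01

    def test_error_histogram_matches_discretized_density(self, grid):
        """Empirical tilt-error distribution at kappa = 4 agrees with the
        exact discretized probabilities within multinomial error."""
        spec = synth.BehaviorSpec(
            kappa_by_condition={(s, d): 4.0 for s in grid.slants if s > 0
                                for d in grid.distances},
            lapse_rate=0.0)
        t = synth.simulate_behavior(spec, grid, 200, seed=7)
        slanted = t[t["slant"] > 0]
        err = wrap_diff(slanted["choice"].to_numpy(),
                        slanted["tilt"].to_numpy()) % 360.0
        counts = np.array([(err == e).sum() for e in range(0, 360, 45)])
        expect = synth.discretized_choice_probs(4.0) * counts.sum()
        assert stats.chisquare(counts, expect).pvalue > 0.01

    def test_invalid_kappa_rejected(self):
        with pytest.raises(ValueError):
            synth.BehaviorSpec(kappa_by_condition={(30.0, 57.0): 0.0})

    def test_frontoparallel_choices_uniform(self, grid):
        spec = synth.default_behavior_spec(grid)
        t = synth.simulate_behavior(spec, grid, 50, seed=8)
        fp = t[t["slant"] == 0]
        counts = fp.groupby("choice").size()
        assert stats.chisquare(counts).pvalue > 0.01


class TestNeuronGenerator:
    def test_no_choice_term_rates_equal_pre_post_onset(self):
        """choice_kappa = 0: the rate profile is flat from latency onward."""
        spec = synth.NeuronSpec(choice_kappa=0.0)
        segs = synth.plane_trial_rate_segments(
            spec, SurfacePose(90.0, 30.0, 57.0), 90.0)
        stim = [s for s in segs if s[0] >= spec.visual_latency]
        assert len({round(s[2], 9) for s in stim}) == 1

    def test_rate_profile_choice_independent_before_onset(self):
        spec = synth.NeuronSpec(choice_kappa=3.0)
        pose = SurfacePose(90.0, 30.0, 57.0)
        for choice in (0.0, 90.0, 180.0):
            segs = synth.plane_trial_rate_segments(spec, pose, choice)
            pre = [s for s in segs if s[1] <= spec.choice_onset]
            ref = [s for s in synth.plane_trial_rate_segments(spec, pose, 45.0)
                   if s[1] <= spec.choice_onset]
            assert pre == ref

    def test_zero_gain_flat_baseline(self):
        spec = synth.NeuronSpec(gain=0.0, dc=0.0, choice_kappa=0.0)
        pose = SurfacePose(0.0, 45.0, 97.0)
        rng = np.random.default_rng(0)
        trains = [synth.simulate_neuron_trial(spec, pose, np.nan, seed=rng)
                  for _ in range(100)]
        rate = np.mean([len(s[(s >= 0)]) for s in trains])
        assert rate == pytest.approx(spec.baseline_rate, rel=0.1)

    def test_empirical_matrix_matches_analytic_rates(self, grid):
        """Separable spec, 20 blocks: empirical mean-rate matrix within
        Poisson counting error of baseline + DC + g H F."""
        spec = synth.NeuronSpec(choice_kappa=0.0)
        window = (52.0, 1000.0)
        M = synth.simulate_tuning_matrix(spec, n_blocks=20, seed=4,
                                         window=window)
        truth = synth.expected_rate_matrix(spec, grid, window=window)
        dur = (window[1] - window[0]) / 1000.0
        se = np.sqrt(truth / (20 * dur))
        z = (M - truth) / se
        assert np.abs(z).max() < 4.5
        assert np.abs(z).mean() < 1.5

    def test_convergence_rate_of_empirical_means(self, grid):
        """Mean absolute error of the empirical matrix shrinks ~n^(-1/2)."""
        spec = synth.NeuronSpec(choice_kappa=0.0)
        truth = synth.expected_rate_matrix(spec, grid)
        err = {}
        for n in (8, 128):
            M = synth.simulate_tuning_matrix(spec, n_blocks=n, seed=6)
            err[n] = np.abs(M - truth).mean()
        assert err[128] < err[8] / 2.0

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            synth.NeuronSpec(bingham_lambdas=(-1.0, -2.0))
        with pytest.raises(ValueError):
            synth.NeuronSpec(choice_onset=40.0, visual_latency=50.0,
                             choice_kappa=1.0)

    def test_frontoparallel_tilt_uninformative_before_onset(self):
        """Frontoparallel rate segments do not depend on any nominal tilt:
        the pose itself erases tilt, so pre-onset responses carry no tilt
        information by construction."""
        spec = synth.NeuronSpec(choice_kappa=2.0)
        a = SurfacePose(FRONTOPARALLEL_TILT, 0.0, 57.0)
        b = SurfacePose(123.0, 0.0, 57.0)
        assert a == b
        sa = synth.plane_trial_rate_segments(spec, a, 90.0)
        sb = synth.plane_trial_rate_segments(spec, b, 90.0)
        assert sa == sb


class TestSaccadeGenerator:
    def test_untuned_direction_rates_indistinguishable(self):
        spec = synth.NeuronSpec(saccade_kappa=0.0)
        rng = np.random.default_rng(1)
        groups = []
        for d in CHOICE_DIRECTIONS:
            rates = []
            for _ in range(20):
                out = synth.simulate_saccade_trial(spec, d, seed=rng)
                s = out["spikes"]
                lat = out["latency_ms"]
                rates.append(((s >= lat - 100) & (s < lat)).sum() * 10.0)
            groups.append(rates)
        assert stats.f_oneway(*groups).pvalue > 0.05

    def test_longer_latency_smaller_slope(self):
        """Two latency groups from the same spec: the fitted pre-saccadic
        slope is smaller for the longer-latency group (slope ~ 1/latency by
        construction)."""
        spec = synth.NeuronSpec()
        slopes = {}
        for lat in (100.0, 180.0):
            segs = synth.saccade_rate_segments(spec, spec.saccade_pref, lat)
            ramp = [(0.5 * (a + b), r) for a, b, r in segs
                    if r > spec.baseline_rate + 1e-9 and b <= lat]
            t, r = np.array(ramp).T
            slopes[lat] = np.polyfit(t, r, 1)[0]
        assert slopes[180.0] < slopes[100.0]
        assert slopes[100.0] / slopes[180.0] == pytest.approx(1.8, rel=0.05)

    def test_eye_velocity_crosses_threshold_at_latency(self):
        from poselab.spikes import eye_speed
        eyes = synth.make_eye_traces(0.0, latency_ms=137.0)
        sp = eye_speed(eyes["x_l"], eyes["y_l"], smooth_ms=0)
        first = eyes["t_ms"][np.flatnonzero(sp >= 150.0)[0]]
        assert first == pytest.approx(137.0, abs=1.5)

    def test_off_grid_direction_rejected(self):
        with pytest.raises(ValueError):
            synth.simulate_saccade_trial(synth.NeuronSpec(), 50.0, seed=0)
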