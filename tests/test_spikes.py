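"""Spike density functions, latency, windows, z-scoring, saccade onset."""

import numpy as np
import pandas as pd
import pytest

from poselab import synth
from poselab.design import SurfacePose
from poselab.spikes import (AnalysisWindows, SDFKernel, baseline_rates,
                            bin_spikes, saccade_onset, spike_density,
                            spike_density_matrix, visual_latency, window_rate,
                            window_rates, zscore_frontoparallel)


class TestKernel:
    def test_unit_area_and_causality(self):
        k = SDFKernel()
        t = np.arange(-50, 400, 0.01)
        vals = k.evaluate(t)
        assert np.all(vals[t < 0] == 0)
        assert np.trapezoid(vals, t) == pytest.approx(1.0, abs=1e-4)

    def test_peak_time_closed_form(self):
        """Kernel argmax at ln(tau_r/tau_d)/(tau_r - tau_d) ~ 3.04 ms."""
        k = SDFKernel()
        assert k.peak_time_ms == pytest.approx(3.0445, abs=1e-3)
        tr = spike_density([100.0], 0.0, 500.0)
        assert abs(np.argmax(tr) - (100 + k.peak_time_ms)) <= 1.0


class TestSpikeDensity:
    def test_empty_train_zero_trace(self):
        assert not spike_density([], 0.0, 1000.0).any()

    def test_integral_equals_spike_count(self, rng):
        spikes = np.sort(rng.uniform(100, 700, size=37))
        tr = spike_density(spikes, 0.0, 1200.0)
        assert tr.sum() / 1000.0 == pytest.approx(37.0, abs=1e-6)

    def test_linearity_in_spike_count(self):
        one = spike_density([300.0], 0.0, 1000.0)
        five = spike_density([300.0] * 5, 0.0, 1000.0)
        np.testing.assert_allclose(five, 5 * one, atol=1e-9)

    def test_matrix_matches_single(self, rng):
        trains = [np.sort(rng.uniform(0, 900, rng.integers(1, 30)))
                  for _ in range(5)]
        M = spike_density_matrix(trains, 0.0, 1000.0)
        for i, s in enumerate(trains):
            np.testing.assert_allclose(M[i], spike_density(s, 0.0, 1000.0),
                                       atol=1e-9)


class TestWindows:
    def test_rate_arithmetic(self):
        spikes = np.linspace(10, 140, 10)
        assert window_rate(spikes, (0.0, 150.0)) == pytest.approx(66.6667,
                                                                  abs=1e-3)

    def test_empty_window_zero(self):
        assert window_rate([500.0], (0.0, 150.0)) == 0.0

    def test_partition_conserves_counts(self, rng):
        spikes = np.sort(rng.uniform(0, 1000, 200))
        w = AnalysisWindows()
        full = window_rate(spikes, (w.sd_start, w.spc_end))
        sd = window_rate(spikes, w.sd)
        spc = window_rate(spikes, w.spc)
        dur_sd = w.sd_end - w.sd_start
        dur_spc = w.spc_end - w.sd_end
        recon = (sd * dur_sd + spc * dur_spc) / (dur_sd + dur_spc)
        assert recon == pytest.approx(full, abs=1e-9)

    def test_zero_length_window_rejected(self):
        with pytest.raises(ValueError):
            window_rate([1.0], (100.0, 100.0))

    def test_window_ordering_enforced(self):
        with pytest.raises(ValueError):
            AnalysisWindows(sd_start=300.0, sd_end=200.0)


class TestVisualLatency:
    def _neuron_traces(self, latency, gain, n_trials, seed):
        spec = synth.NeuronSpec(visual_latency=latency, gain=gain,
                                choice_kappa=0.0)
        rng = np.random.default_rng(seed)
        pose = SurfacePose(90.0, 45.0, 57.0)
        trains = [synth.simulate_neuron_trial(spec, pose, np.nan, seed=rng)
                  for _ in range(n_trials)]
        # start traces before stimulus onset so the causal kernel has
        # history at t=0 (no boundary-truncation dip)
        sdfs = spike_density_matrix(trains, -300.0, 1000.0)
        base = baseline_rates(trains)
        return sdfs, base

    def test_detects_injected_latency(self):
        sdfs, base = self._neuron_traces(50.0, 60.0, 160, seed=0)
        lat = visual_latency(sdfs, base, t0=-300.0, search_start=0.0)
        assert lat is not None and 45.0 <= lat <= 60.0

    def test_baseline_only_neuron_returns_none(self):
        spec = synth.NeuronSpec(gain=0.0, dc=0.0, choice_kappa=0.0)
        rng = np.random.default_rng(1)
        pose = SurfacePose(90.0, 45.0, 57.0)
        trains = [synth.simulate_neuron_trial(spec, pose, np.nan, seed=rng)
                  for _ in range(40)]
        sdfs = spike_density_matrix(trains, -300.0, 1000.0)
        assert visual_latency(sdfs, baseline_rates(trains), t0=-300.0,
                              search_start=0.0) is None

    def test_false_positive_rate_controlled(self):
        """Pure-baseline neurons are declared responsive at roughly the
        nominal alpha of the responsiveness gate."""
        rng = np.random.default_rng(2)
        pose = SurfacePose(90.0, 45.0, 57.0)
        hits = 0
        n_neurons = 200
        for _ in range(n_neurons):
            spec = synth.NeuronSpec(gain=0.0, dc=0.0, choice_kappa=0.0,
                                    baseline_rate=float(rng.uniform(5, 20)))
            trains = [synth.simulate_neuron_trial(spec, pose, np.nan,
                                                  seed=rng)
                      for _ in range(20)]
            sdfs = spike_density_matrix(trains, -300.0, 1000.0)
            if visual_latency(sdfs, baseline_rates(trains), t0=-300.0,
                              search_start=0.0) is not None:
                hits += 1
        # alpha plus two binomial standard errors
        assert hits / n_neurons <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_neurons)


class TestZScoring:
    def _rates(self, rng, n_neurons=2, n_trials=12):
        rows = []
        for ni in range(n_neurons):
            for d in (37.0, 57.0):
                for t in range(n_trials):
                    rows.append((ni, len(rows), d, 0.0,
                                 rng.normal(20 + 5 * ni + d / 10, 4), 8.0))
        return pd.DataFrame(rows, columns=["neuron_id", "trial_id",
                                           "distance_cm", "slant", "rate_hz",
                                           "baseline_hz"])

    def test_cells_standardized(self, rng):
        out = zscore_frontoparallel(self._rates(rng))
        for _, g in out.table.groupby(["neuron_id", "distance_cm"]):
            assert g["z"].mean() == pytest.approx(0.0, abs=1e-12)
            assert g["z"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_constant_cell_flagged(self, rng):
        df = self._rates(rng)
        df.loc[df["distance_cm"] == 37.0, "rate_hz"] = 10.0
        out = zscore_frontoparallel(df)
        assert any(f[2] == "zero_variance" for f in out.flagged)
        assert not ((out.table["distance_cm"] == 37.0)).any()

    def test_idempotent_on_standardized_cells(self, rng):
        df = self._rates(rng)
        once = zscore_frontoparallel(df)
        df2 = df.merge(once.table[["trial_id", "z"]], on="trial_id")
        df2["rate_hz"] = df2["z"]
        df2["baseline_hz"] = 0.0
        twice = zscore_frontoparallel(df2[["neuron_id", "trial_id",
                                           "distance_cm", "slant", "rate_hz",
                                           "baseline_hz"]])
        merged = once.table.merge(twice.table, on="trial_id",
                                  suffixes=("_1", "_2"))
        np.testing.assert_allclose(merged["z_1"], merged["z_2"], atol=1e-9)


class TestSaccadeOnset:
    def test_scheduled_crossing_detected(self):
        eyes = synth.make_eye_traces(90.0, latency_ms=150.0)
        onset = saccade_onset(eyes, t0=float(eyes["t_ms"][0]))
        assert onset == pytest.approx(150.0, abs=3.0)

    def test_fixation_only_returns_none(self):
        n = 500
        eyes = {k: np.zeros(n) for k in ("x_l", "y_l", "x_r", "y_r")}
        assert saccade_onset(eyes) is None

    def test_velocity_crosses_threshold_once(self):
        """The generated trace's speed has exactly one rising crossing of
        150 deg/s."""
        from poselab.spikes import eye_speed
        eyes = synth.make_eye_traces(45.0, latency_ms=120.0)
        sp = eye_speed(eyes["x_l"], eyes["y_l"], smooth_ms=0)
        above = sp >= 150.0
        rising = np.flatnonzero(~above[:-1] & above[1:])
        assert len(rising) == 1

    def test_cohort_latency_mean_recovered(self):
        rng = np.random.default_rng(3)
        spec = synth.NeuronSpec()
        lats, detected = [], []
        for _ in range(60):
            out = synth.simulate_saccade_trial(spec, 90.0, seed=rng)
            lats.append(out["latency_ms"])
            onset = saccade_onset(out["eyes"],
                                  t0=float(out["eyes"]["t_ms"][0]))
            detected.append(onset)
        sem = np.std(lats) / np.sqrt(len(lats))
        assert abs(np.mean(detected) - np.mean(lats)) <= 3 * sem + 3.0
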