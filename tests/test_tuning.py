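"""TDI, Bingham orientation fits, von Mises direction fits, gates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from poselab import synth
from poselab.design import DesignGrid, orientation_index
from poselab.geometry import pose_to_normal
from poselab.tuning import (TuningMatrix, bingham_predict, fit_bingham,
                            fit_von_mises, tdi, tdi_map, tuning_gates,
                            vm_hwhh)
from poselab.circstats import wrap_diff


def _tilt_curve(means, spread):
    """Responses_by_tilt dict with exact per-tilt means and SSE control:
    two trials per tilt at mean +- spread."""
    return {t * 45.0: [m - spread, m + spread] for t, m in enumerate(means)}


class TestTDI:
    def test_noiseless_tuned_is_one(self):
        curve = _tilt_curve([10, 12, 15, 20, 15, 12, 10, 9], spread=0.0)
        assert tdi(curve).tdi == 1.0

    def test_flat_responses_zero(self):
        curve = _tilt_curve([10.0] * 8, spread=2.0)
        assert tdi(curve).tdi == 0.0

    def test_direct_arithmetic_half(self):
        """Rmax=20, Rmin=10, sqrt(SSE/(N-M))=5 -> TDI = 10/(10+10) = 0.5."""
        # SSE = 25*(16-8) = 200; per tilt 2*spread^2 = 25 -> spread
        spread = np.sqrt(12.5)
        curve = _tilt_curve([20, 10, 10, 10, 10, 10, 10, 10], spread=spread)
        res = tdi(curve)
        assert res.tdi == pytest.approx(0.5, abs=1e-12)
        assert res.r_max == 20.0 and res.r_min == 10.0

    def test_literal_denominator_variant(self):
        spread = np.sqrt(12.5)
        curve = _tilt_curve([20, 10, 10, 10, 10, 10, 10, 10], spread=spread)
        res = tdi(curve, literal_denominator=True)
        assert res.tdi == pytest.approx(10.0 / (10.0 + 2 * 25.0), abs=1e-12)

    @given(offset=st.floats(-50, 50), scale=st.floats(0.1, 20),
           seed=st.integers(0, 100))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_invariance_to_offset_and_positive_scale(self, offset, scale,
                                                     seed):
        rng = np.random.default_rng(seed)
        curve = {t * 45.0: rng.normal(10 + 3 * t, 2, size=4) for t in range(8)}
        base = tdi(curve).tdi
        shifted = {k: np.asarray(v) * scale + offset for k, v in curve.items()}
        assert tdi(shifted).tdi == pytest.approx(base, rel=1e-9)

    def test_undefined_when_no_residual_dof(self):
        with pytest.raises(ValueError):
            tdi({t * 45.0: [10.0] for t in range(8)})

    def test_bounds_on_random_curves(self, rng):
        for _ in range(20):
            curve = {t * 45.0: rng.normal(rng.uniform(5, 40), 3, 5)
                     for t in range(8)}
            assert 0.0 <= tdi(curve).tdi <= 1.0


class TestBingham:
    def setup_method(self):
        self.grid = DesignGrid()
        self.oris = orientation_index(self.grid)
        self.normals = np.array([pose_to_normal(t, s) for t, s in self.oris])

    def test_noiseless_roundtrip_exact(self):
        rates = bingham_predict(self.normals, 270.0, 45.0, -2.0, -1.0, 20.0,
                                30.0, 5.0)
        fit = fit_bingham(self.oris, rates)
        assert fit.pref_tilt == pytest.approx(270.0, abs=0.1)
        assert fit.pref_slant == pytest.approx(45.0, abs=0.1)
        assert fit.fit_r == pytest.approx(1.0, abs=1e-9)
        assert fit.lambda1 <= fit.lambda2 <= 0

    def test_recovery_at_snr_10(self):
        """Median preferred tilt/slant error over replicates < 5 deg with
        noise sd = amplitude/10."""
        rates = bingham_predict(self.normals, 270.0, 45.0, -2.0, -1.0, 20.0,
                                30.0, 5.0)
        errs_t, errs_s = [], []
        for seed in range(12):
            rng = np.random.default_rng(seed)
            fit = fit_bingham(self.oris, rates + rng.normal(0, 3.0, 33))
            errs_t.append(abs(wrap_diff(fit.pref_tilt, 270.0)))
            errs_s.append(abs(fit.pref_slant - 45.0))
        assert np.median(errs_t) < 5.0
        assert np.median(errs_s) < 5.0

    def test_isotropic_axis_flagged(self):
        rates = bingham_predict(self.normals, 90.0, 30.0, -1.5, -1.5, 0.0,
                                20.0, 4.0)
        fit = fit_bingham(self.oris, rates)
        assert fit.isotropic
        assert np.isnan(fit.axis_rotation)

    def test_preference_may_exceed_sampled_slant(self):
        """Responses still rising at the 60-deg sampling edge can place the
        fitted preference beyond it."""
        rates = bingham_predict(self.normals, 180.0, 80.0, -1.0, -0.5, 0.0,
                                25.0, 5.0)
        fit = fit_bingham(self.oris, rates)
        assert fit.pref_slant > 60.0


class TestVonMises:
    dirs = np.arange(0.0, 360.0, 45.0)

    def _curve(self, pref, kappa, amp=20.0, base=5.0):
        return base + amp * np.exp(kappa * (np.cos(np.deg2rad(
            self.dirs - pref)) - 1.0))

    def test_noiseless_exact_recovery(self):
        fit = fit_von_mises(self.dirs, self._curve(90.0, 4.0))
        assert fit.pref == pytest.approx(90.0, abs=1e-6)
        assert fit.kappa == pytest.approx(4.0, abs=1e-6)
        assert fit.fit_r == pytest.approx(1.0, abs=1e-12)

    def test_hwhh_closed_form_limits(self):
        assert vm_hwhh(50.0)[0] < 15.0
        w, capped = vm_hwhh(np.log(2) / 2 - 1e-6)
        assert capped and w == 180.0
        # hwhh decreasing in kappa
        widths = [vm_hwhh(k)[0] for k in (1.0, 2.0, 4.0, 8.0)]
        assert all(a > b for a, b in zip(widths, widths[1:]))

    def test_recovery_under_poisson_noise(self):
        rng = np.random.default_rng(0)
        truth = self._curve(90.0, 4.0)
        means = rng.poisson(truth[:, None] * 0.5, size=(8, 20)).mean(axis=1) / 0.5
        fit = fit_von_mises(self.dirs, means)
        assert abs(wrap_diff(fit.pref, 90.0)) <= 10.0

    def test_flat_curve_pref_unidentifiable(self):
        fit = fit_von_mises(self.dirs, np.full(8, 12.0))
        assert not fit.pref_identifiable


class TestGates:
    def _plane_rates(self, spec, n_blocks, seed, grid):
        rng = np.random.default_rng(seed)
        rows = []
        dur = 0.148
        for b in range(n_blocks):
            for t, s in orientation_index(grid):
                for d in grid.distances:
                    from poselab.design import SurfacePose, FRONTOPARALLEL_TILT
                    pose = SurfacePose(t if s > 0 else FRONTOPARALLEL_TILT, s, d)
                    mu = spec.baseline_rate + spec.evoked_rate(pose, grid)
                    if s == 0:      # 8 frontoparallel repeats per distance
                        for _ in range(8):
                            rows.append((t, s, d, rng.poisson(mu * dur) / dur))
                    else:
                        rows.append((t, s, d, rng.poisson(mu * dur) / dur))
        return pd.DataFrame(rows, columns=["tilt", "slant", "distance_cm",
                                           "rate_hz"])

    def test_strongly_tuned_neuron_gated_in_everywhere(self, grid):
        spec = synth.NeuronSpec(gain=60.0, distance_profile=(0.8, 1.0, 0.7, 0.6))
        rates = self._plane_rates(spec, 6, 0, grid)
        g = tuning_gates(rates, n_blocks=6)
        assert all(g.orientation_tuned.values())
        assert g.distance_tuned
        assert g.slant_tuned

    def test_insufficient_blocks_excluded(self, grid):
        spec = synth.NeuronSpec()
        rates = self._plane_rates(spec, 3, 1, grid)
        g = tuning_gates(rates, n_blocks=3)
        assert g.excluded

    def test_gate_invariant_to_trial_order(self, grid):
        spec = synth.NeuronSpec(gain=25.0)
        rates = self._plane_rates(spec, 5, 2, grid)
        g1 = tuning_gates(rates, n_blocks=5)
        shuffled = rates.sample(frac=1.0, random_state=9).reset_index(drop=True)
        g2 = tuning_gates(shuffled, n_blocks=5)
        assert g1.orientation_tuned == g2.orientation_tuned
        assert g1.distance_tuned == g2.distance_tuned

    def test_untuned_choice_gate_usually_silent(self):
        """choice_kappa = 0 neurons trip the choice gate at ~alpha."""
        rng = np.random.default_rng(3)
        hits = 0
        n = 40
        for _ in range(n):
            z = pd.DataFrame({
                "z": rng.normal(size=128),
                "choice": np.tile(np.arange(0.0, 360.0, 45.0), 16)})
            plane = pd.DataFrame({
                "tilt": np.tile(np.arange(0.0, 360.0, 45.0), 20),
                "slant": 30.0, "distance_cm": 57.0,
                "rate_hz": rng.normal(20, 4, 160)})
            g = tuning_gates(plane, z_fp=z, n_blocks=5)
            hits += bool(g.choice_tuned)
        assert hits / n <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n)


class TestTuningMatrix:
    def test_from_trials_shapes_and_counts(self, grid, rng):
        spec = synth.NeuronSpec()
        rows = []
        for b in range(3):
            for t, s in orientation_index(grid):
                for d in grid.distances:
                    rows.append((t, s, d, rng.normal(20, 3)))
        df = pd.DataFrame(rows, columns=["tilt", "slant", "distance_cm",
                                         "rate_hz"])
        tm = TuningMatrix.from_trials(df, grid)
        assert tm.means.shape == (33, 4)
        assert (tm.counts == 3).all()
        assert np.isfinite(tm.means).all()

    def test_tdi_map_covers_all_conditions(self, grid, rng):
        rows = []
        for rep in range(3):
            for t, s in orientation_index(grid):
                if s == 0:
                    continue
                for d in grid.distances:
                    rows.append((t, s, d, rng.normal(15 + t / 40, 2)))
        df = pd.DataFrame(rows, columns=["tilt", "slant", "distance_cm",
                                         "rate_hz"])
        out = tdi_map(df)
        assert len(out) == 16
        assert out["tdi"].between(0, 1).all()
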