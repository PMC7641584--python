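"""Synthetic sessions with known ground truth.

Generates behavior (von Mises choice errors discretized onto the 45 deg
report grid), Poisson spike trains with multiplicatively separable — or
deliberately inseparable — Bingham x distance tuning, choice-related gain
modulation injected at a known onset time, saccade-direction-tuned
pre-saccadic ramps whose slope is inversely proportional to the drawn
latency, and 1 kHz eye traces whose speed crosses the 150 deg/s detection
threshold at the scheduled saccade onset.  Every analysis stage in the
package therefore has a recoverable target.

Timeline conventions (ms): plane trials run from -300 (fixation) to 1000
(stimulus offset) relative to stimulus onset; saccade trials run from -300
relative to target onset until 100 ms after the saccade lands.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .design import (DesignGrid, SurfacePose, BlockPlan, build_block,
                     CHOICE_DIRECTIONS, FRONTOPARALLEL_TILT)
from .tuning import bingham_predict
from .geometry import pose_to_normal

KAPPA_CAP = 18.0


# ---------------------------------------------------------------------------
# Behavior

@dataclass
class BehaviorSpec:
    """Generative model of the subject's choices.

    ``kappa_by_condition`` maps (slant, distance) -> von Mises concentration
    of the tilt error; frontoparallel conditions are uniform by definition.
    A lapse trial picks uniformly among the 8 choices.
    """

    kappa_by_condition: dict
    lapse_rate: float = 0.02

    def __post_init__(self) -> None:
        for cond, k in self.kappa_by_condition.items():
            if not (0 < k <= KAPPA_CAP):
                raise ValueError(f"kappa for {cond} must be in (0, {KAPPA_CAP}]")
        if not (0.0 <= self.lapse_rate <= 1.0):
            raise ValueError("lapse_rate must be in [0, 1]")


def default_behavior_spec(grid: DesignGrid | None = None) -> BehaviorSpec:
    """Sensitivity increasing with slant, inverted-U over distance peaking
    at fixation (57 cm) — the qualitative structure of the measured maps."""
    grid = grid or DesignGrid()
    slant_gain = {15.0: 2.2, 30.0: 4.5, 45.0: 7.0, 60.0: 9.5}
    dist_weight = {37.0: 0.55, 57.0: 1.0, 97.0: 0.45, 137.0: 0.30}
    kappas = {}
    for s in grid.slants:
        if s == 0:
            continue
        for d in grid.distances:
            g = slant_gain.get(float(s), 2.0 + 7.5 * float(s) / 60.0)
            w = dist_weight.get(float(d), 0.5)
            kappas[(float(s), float(d))] = min(g * w, KAPPA_CAP)
    return BehaviorSpec(kappa_by_condition=kappas)


def discretized_choice_probs(kappa: float) -> np.ndarray:
    """Probability of each tilt error in {0,45,...,315} (relative choice):
    von Mises density at the 45-deg bin centers, renormalized."""
    offs = np.arange(0.0, 360.0, 45.0)
    w = kappa * (np.cos(np.deg2rad(offs)) - 1.0)
    p = np.exp(w)
    return p / p.sum()


def simulate_behavior(spec: BehaviorSpec, grid: DesignGrid, n_blocks: int,
                      seed: int, session: str = "s0") -> pd.DataFrame:
    """Simulate choices for ``n_blocks`` blocks of the discrimination task.

    Slanted trials draw a tilt error from the discretized von Mises (mixed
    with a uniform lapse); frontoparallel trials choose uniformly.
    Returns a trial table with session, block, trial_id, tilt, slant,
    distance_cm, choice, correct.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks >= 1")
    rng = np.random.default_rng(seed)
    dirs = np.asarray(CHOICE_DIRECTIONS)
    frames = []
    for b in range(n_blocks):
        plan = build_block(grid, seed=int(rng.integers(2 ** 31)))
        t = plan.plane_trials.copy()
        choices = np.empty(len(t))
        for i, row in enumerate(t.itertuples()):
            if row.slant == 0:
                choices[i] = rng.choice(dirs)
            else:
                kappa = spec.kappa_by_condition[(float(row.slant),
                                                 float(row.distance_cm))]
                if rng.random() < spec.lapse_rate:
                    choices[i] = rng.choice(dirs)
                else:
                    err = rng.choice(dirs, p=discretized_choice_probs(kappa))
                    choices[i] = (row.tilt + err) % 360.0
        t["choice"] = choices
        t["correct"] = np.where(t["slant"] > 0, t["choice"] == t["tilt"], np.nan)
        t["block"] = b
        t["session"] = session
        frames.append(t)
    out = pd.concat(frames, ignore_index=True)
    out["trial_id"] = np.arange(len(out))
    return out


# ---------------------------------------------------------------------------
# Neurons

@dataclass
class NeuronSpec:
    """Ground-truth parameters of one synthetic neuron."""

    preferred_tilt: float = 90.0
    preferred_slant: float = 45.0
    bingham_lambdas: tuple = (-2.0, -1.0)     # lambda1 <= lambda2 <= 0
    axis_angle: float = 0.0
    distance_profile: tuple = (0.6, 1.0, 0.5, 0.3)   # gains per distance
    dc: float = 4.0                            # untuned evoked offset, sp/s
    baseline_rate: float = 8.0
    gain: float = 30.0
    visual_latency: float = 50.0               # ms
    choice_kappa: float = 2.0                  # 0 = no choice tuning
    choice_pref: float = 90.0
    choice_onset: float = 200.0                # ms
    choice_ramp_ms: float = 0.0                # 0 = step at onset
    saccade_kappa: float = 3.0
    saccade_pref: float = 90.0
    saccade_threshold_hz: float = 42.0
    saccade_lead_frac: float = 0.75            # ramp spans this fraction of SL
    slant_drift_per_distance: float = 0.0      # inseparability knob, deg/step

    def __post_init__(self) -> None:
        l1, l2 = self.bingham_lambdas
        if not (l1 <= l2 <= 0):
            raise ValueError("need lambda1 <= lambda2 <= 0")
        if any(g < 0 for g in self.distance_profile):
            raise ValueError("distance gains must be nonnegative")
        if self.choice_kappa > 0 and self.choice_onset <= self.visual_latency:
            raise ValueError("choice_onset must follow visual_latency")

    def orientation_tuning(self, tilt, slant, distance_index: int = 1,
                           grid: DesignGrid | None = None) -> float:
        """H(theta) in [0, 1]; with a nonzero slant drift the preferred
        slant shifts by ``slant_drift_per_distance`` per distance step
        behind fixation (inseparable ground truth)."""
        grid = grid or DesignGrid()
        fix_idx = grid.distances.index(grid.fixation_distance)
        steps = max(0, distance_index - fix_idx)
        pref_s = min(self.preferred_slant
                     + self.slant_drift_per_distance * steps, 90.0)
        n = pose_to_normal(FRONTOPARALLEL_TILT if slant == 0 else tilt, slant)
        val = bingham_predict(n[None, :], self.preferred_tilt, pref_s,
                              self.bingham_lambdas[0], self.bingham_lambdas[1],
                              self.axis_angle, 1.0, 0.0)
        return float(val[0])

    def distance_tuning(self, distance_index: int) -> float:
        prof = np.asarray(self.distance_profile, dtype=float)
        return float(prof[distance_index] / prof.max())

    def evoked_rate(self, pose: SurfacePose, grid: DesignGrid | None = None
                    ) -> float:
        """DC + g H(theta) F(D), spikes/s above baseline."""
        grid = grid or DesignGrid()
        j = grid.distances.index(pose.distance)
        h = self.orientation_tuning(pose.tilt, pose.slant, j, grid)
        return self.dc + self.gain * h * self.distance_tuning(j)

    def choice_gain(self, choice: float) -> float:
        if self.choice_kappa <= 0 or not np.isfinite(choice):
            return 1.0
        d = np.deg2rad(choice - self.choice_pref)
        return float(np.exp(self.choice_kappa * (np.cos(d) - 1.0)))

    def saccade_gain(self, direction: float) -> float:
        if self.saccade_kappa <= 0:
            return 1.0
        d = np.deg2rad(direction - self.saccade_pref)
        return float(np.exp(self.saccade_kappa * (np.cos(d) - 1.0)))


def _piecewise_poisson(segments, rng) -> np.ndarray:
    """Exact sampling of an inhomogeneous Poisson process with piecewise-
    constant rate.  ``segments``: [(t0, t1, rate_hz)].  Negative rates are
    clipped to 0 (and warned about by the caller)."""
    times = []
    for t0, t1, rate in segments:
        if t1 <= t0:
            continue
        lam = max(rate, 0.0) * (t1 - t0) / 1000.0
        n = rng.poisson(lam)
        if n:
            times.append(rng.uniform(t0, t1, size=n))
    if not times:
        return np.empty(0)
    return np.sort(np.concatenate(times))


def plane_trial_rate_segments(spec: NeuronSpec, pose: SurfacePose,
                              choice: float, duration: float = 1000.0,
                              t_pre: float = 300.0,
                              grid: DesignGrid | None = None) -> list:
    """Piecewise-constant rate profile of one plane trial, ms re stimulus
    onset: baseline before the visual latency; baseline + evoked from
    latency to the choice onset; afterwards the evoked component is scaled
    by the von Mises choice gain (step by default, linear ramp optional)."""
    evoked = spec.evoked_rate(pose, grid)
    base = spec.baseline_rate
    cg = spec.choice_gain(choice)
    segs = [(-t_pre, spec.visual_latency, base)]
    if spec.choice_kappa <= 0 or not np.isfinite(choice):
        segs.append((spec.visual_latency, duration, base + evoked))
        return segs
    segs.append((spec.visual_latency, spec.choice_onset, base + evoked))
    if spec.choice_ramp_ms > 0:
        ramp_end = min(spec.choice_onset + spec.choice_ramp_ms, duration)
        n_steps = max(int(spec.choice_ramp_ms // 5), 1)
        edges = np.linspace(spec.choice_onset, ramp_end, n_steps + 1)
        for a, b in zip(edges[:-1], edges[1:]):
            frac = ((a + b) / 2 - spec.choice_onset) / spec.choice_ramp_ms
            segs.append((a, b, base + evoked * (1 + frac * (cg - 1))))
        segs.append((ramp_end, duration, base + evoked * cg))
    else:
        segs.append((spec.choice_onset, duration, base + evoked * cg))
    return segs


def simulate_neuron_trial(spec: NeuronSpec, pose: SurfacePose, choice: float,
                          duration: float = 1000.0, seed=None,
                          t_pre: float = 300.0,
                          grid: DesignGrid | None = None) -> np.ndarray:
    """Spike times (ms re stimulus onset) of one plane trial."""
    if duration < 1000.0:
        raise ValueError("stimulus epoch is 1 s; duration >= 1000 ms")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    segs = plane_trial_rate_segments(spec, pose, choice, duration, t_pre, grid)
    return _piecewise_poisson(segs, rng)


def saccade_rate_segments(spec: NeuronSpec, direction: float,
                          latency_ms: float, t_pre: float = 300.0,
                          t_post: float = 100.0) -> list:
    """Rate profile of a saccade trial, ms re target onset.  The rate ramps
    linearly from baseline starting ``saccade_lead_frac * latency`` before
    the saccade, reaching baseline + (threshold - baseline) * vm(direction)
    at saccade onset — so the slope is proportional to 1/latency."""
    base = spec.baseline_rate
    peak = base + (spec.saccade_threshold_hz - base) * spec.saccade_gain(direction)
    onset = latency_ms
    ramp_start = onset * (1.0 - spec.saccade_lead_frac)
    segs = [(-t_pre, ramp_start, base)]
    n_steps = max(int((onset - ramp_start) // 2), 1)
    edges = np.linspace(ramp_start, onset, n_steps + 1)
    for a, b in zip(edges[:-1], edges[1:]):
        frac = ((a + b) / 2 - ramp_start) / (onset - ramp_start)
        segs.append((a, b, base + (peak - base) * frac))
    segs.append((onset, onset + t_post, peak))
    return segs


def make_eye_traces(direction: float, latency_ms: float, t_pre: float = 300.0,
                    t_post: float = 100.0, amplitude: float = 11.0,
                    profile_ms: float = 40.0) -> dict:
    """Binocular 1 kHz eye traces for a saccade of ``amplitude`` degrees in
    ``direction`` landing after ``latency_ms``.  The speed profile is a
    raised-cosine pulse scheduled so its first >= 150 deg/s sample falls
    exactly at the saccade onset."""
    n = int(round(t_pre + latency_ms + t_post))
    t = np.arange(n, dtype=float) - t_pre          # ms re target onset
    v_peak = amplitude / (profile_ms / 1000.0) * 2.0   # deg/s, area = amplitude
    thr_frac = 150.0 / v_peak
    # sin^2(pi x) = thr_frac at x = asin(sqrt(thr_frac))/pi
    x_thr = np.arcsin(np.sqrt(min(thr_frac, 1.0))) / np.pi
    t0 = latency_ms - x_thr * profile_ms
    phase = np.clip((t - t0) / profile_ms, 0.0, 1.0)
    speed = v_peak * np.sin(np.pi * phase) ** 2
    disp = np.cumsum(speed) / 1000.0               # deg
    th = np.deg2rad(direction)
    x = disp * np.cos(th)
    y = disp * np.sin(th)
    return {"t_ms": t, "x_l": x, "y_l": y, "x_r": x.copy(), "y_r": y.copy()}


def simulate_saccade_trial(spec: NeuronSpec, direction: float, seed=None,
                           latency_ms: float | None = None,
                           latency_mean: float = 137.0,
                           latency_sd: float = 25.0) -> dict:
    """One saccade trial: spike times (ms re target onset), eye traces, and
    the drawn latency.  Nonpositive latency draws are redrawn."""
    if float(direction) % 45.0 != 0.0:
        raise ValueError("direction must be on the 45 deg grid")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if latency_ms is None:
        latency_ms = 0.0
        while latency_ms <= 40.0:
            latency_ms = float(rng.normal(latency_mean, latency_sd))
    spikes = _piecewise_poisson(saccade_rate_segments(spec, direction,
                                                      latency_ms), rng)
    eyes = make_eye_traces(direction, latency_ms)
    return {"spikes": spikes, "eyes": eyes, "latency_ms": latency_ms,
            "direction": float(direction)}


# ---------------------------------------------------------------------------
# Cohorts and sessions

def make_neuron_cohort(n: int, seed: int, choice_fraction: float = 0.5,
                       choice_onset: float = 200.0, choice_kappa: float = 2.0,
                       slant_drift: float = 0.0,
                       align_saccade_to_tilt: bool = True,
                       gain_range: tuple = (15.0, 45.0)) -> list[NeuronSpec]:
    """Random cohort with uniformly scattered preferred orientations.

    A ``choice_fraction`` of neurons get choice tuning (onset at
    ``choice_onset`` ms) with choice preference equal to the preferred tilt;
    saccade preferences align with tilt (plus small scatter) when requested.
    """
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n):
        tilt = float(rng.uniform(0, 360))
        slant = float(rng.uniform(15, 75))
        lam = np.sort(-rng.uniform(0.5, 3.0, size=2))
        prof = rng.uniform(0.2, 1.0, size=4)
        has_choice = rng.random() < choice_fraction
        sac_pref = (tilt + rng.normal(0, 20)) % 360 if align_saccade_to_tilt \
            else float(rng.uniform(0, 360))
        cohort.append(NeuronSpec(
            preferred_tilt=tilt, preferred_slant=slant,
            bingham_lambdas=(float(lam[0]), float(lam[1])),
            axis_angle=float(rng.uniform(-90, 90)),
            distance_profile=tuple(prof),
            baseline_rate=float(rng.uniform(5, 15)),
            gain=float(rng.uniform(*gain_range)),
            visual_latency=float(rng.uniform(45, 60)),
            choice_kappa=choice_kappa if has_choice else 0.0,
            choice_pref=tilt, choice_onset=choice_onset,
            saccade_kappa=float(rng.uniform(2, 5)),
            saccade_pref=sac_pref,
            slant_drift_per_distance=slant_drift))
    return cohort


def expected_rate_matrix(spec: NeuronSpec, grid: DesignGrid | None = None,
                         window: tuple = (52.0, 200.0)) -> np.ndarray:
    """Analytic mean rate (spikes/s) per orientation x distance cell for a
    window inside the stimulus epoch, averaging the choice gain over a
    uniform choice distribution when the window overlaps the choice epoch."""
    grid = grid or DesignGrid()
    from .design import orientation_index
    t0, t1 = window
    pre_frac = np.clip((min(t1, spec.choice_onset) - t0) / (t1 - t0), 0, 1) \
        if spec.choice_kappa > 0 else 1.0
    mean_cg = np.mean([spec.choice_gain(c) for c in CHOICE_DIRECTIONS])
    oris = orientation_index(grid)
    M = np.zeros((len(oris), len(grid.distances)))
    for i, (tilt, slant) in enumerate(oris):
        for j, d in enumerate(grid.distances):
            pose = SurfacePose(tilt if slant > 0 else FRONTOPARALLEL_TILT,
                               slant, d)
            ev = spec.evoked_rate(pose, grid)
            scale = pre_frac + (1 - pre_frac) * mean_cg
            M[i, j] = spec.baseline_rate + ev * scale
    return M


def simulate_tuning_matrix(spec: NeuronSpec, n_blocks: int, seed: int,
                           grid: DesignGrid | None = None,
                           window: tuple = (52.0, 200.0)) -> np.ndarray:
    """Trial-mean 33 x 4 rate matrix with Poisson counting noise at the
    analytic rates — the fast path for cohort-level experiments that do not
    need full spike trains."""
    grid = grid or DesignGrid()
    rng = np.random.default_rng(seed)
    mu = expected_rate_matrix(spec, grid, window)
    dur_s = (window[1] - window[0]) / 1000.0
    counts = rng.poisson(mu * dur_s, size=(n_blocks,) + mu.shape)
    return counts.mean(axis=0) / dur_s


@dataclass
class SessionData:
    """One synthetic session: trial table, spike times, eye traces, truth."""

    trials: pd.DataFrame
    spikes: dict                     # (neuron_id, trial_id) -> ndarray ms
    eyes: dict                       # trial_id -> eye-trace dict
    neurons: list
    seed: int
    sample_rate_hz: int = 1000

    def truth(self) -> dict:
        return {"seed": self.seed,
                "neurons": [asdict(n) for n in self.neurons]}


def simulate_session(neurons: list[NeuronSpec], n_blocks: int, seed: int,
                     grid: DesignGrid | None = None,
                     behavior: BehaviorSpec | None = None,
                     session: str = "s0") -> SessionData:
    """End-to-end session: behavior drives choices, choices condition the
    spike generator (sensory -> choice causality), saccade trials include
    eye traces."""
    grid = grid or DesignGrid()
    behavior = behavior or default_behavior_spec(grid)
    rng = np.random.default_rng(seed)
    trials = simulate_behavior(behavior, grid, n_blocks,
                               seed=int(rng.integers(2 ** 31)), session=session)
    # saccade trials appended after plane trials
    sacc_frames = []
    next_id = len(trials)
    for b in range(n_blocks):
        plan = build_block(grid, seed=int(rng.integers(2 ** 31)))
        s = plan.saccade_trials.copy()
        s["block"] = b
        s["session"] = session
        sacc_frames.append(s)
    sacc = pd.concat(sacc_frames, ignore_index=True)
    sacc["trial_id"] = np.arange(next_id, next_id + len(sacc))
    sacc["choice"] = np.nan
    sacc["correct"] = np.nan
    all_trials = pd.concat([trials, sacc], ignore_index=True)

    spikes = {}
    eyes = {}
    latencies = {}
    for row in all_trials.itertuples():
        if row.kind == "plane":
            pose = SurfacePose(row.tilt if row.slant > 0 else FRONTOPARALLEL_TILT,
                               row.slant, row.distance_cm)
            for ni, spec in enumerate(neurons):
                spikes[(ni, row.trial_id)] = simulate_neuron_trial(
                    spec, pose, row.choice, seed=rng)
        else:
            lat = None
            for ni, spec in enumerate(neurons):
                out = simulate_saccade_trial(spec, row.saccade_dir, seed=rng,
                                             latency_ms=lat)
                lat = out["latency_ms"]
                spikes[(ni, row.trial_id)] = out["spikes"]
            eyes[row.trial_id] = make_eye_traces(row.saccade_dir, lat)
            latencies[row.trial_id] = lat
    all_trials["latency_ms"] = all_trials["trial_id"].map(latencies)
    return SessionData(trials=all_trials, spikes=spikes, eyes=eyes,
                       neurons=neurons, seed=seed)


def session_to_csv(session: SessionData, outdir) -> None:
    """Serialize to trials.csv / spikes.csv / eyes.csv / truth.json."""
    import json
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    session.trials.to_csv(out / "trials.csv", index=False)
    rows = [(ni, tid, t) for (ni, tid), s in session.spikes.items() for t in s]
    pd.DataFrame(rows, columns=["neuron_id", "trial_id", "spike_time_ms"]
                 ).to_csv(out / "spikes.csv", index=False)
    eye_rows = []
    for tid, e in session.eyes.items():
        eye_rows.append(pd.DataFrame({
            "trial_id": tid, "t_ms": e["t_ms"], "x_l": e["x_l"],
            "y_l": e["y_l"], "x_r": e["x_r"], "y_r": e["y_r"]}))
    if eye_rows:
        pd.concat(eye_rows, ignore_index=True).to_csv(out / "eyes.csv",
                                                      index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(session.truth(), fh, indent=1)
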