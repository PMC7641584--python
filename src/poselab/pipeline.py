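"""Pipeline orchestration: simulate -> analyze -> report.

Each stage reads and writes plain CSV/JSON under one output directory and
records content hashes in a run manifest, so reruns with an unchanged
config reuse cached stage outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import geometry as geo
from . import separability as sep
from . import spikes as spk
from . import synth
from . import timing as tim
from . import tuning as tun
from .design import DesignGrid, CHOICE_DIRECTIONS

log = logging.getLogger("poselab")


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "poselab_run"
    n_neurons: int = 8
    n_blocks: int = 5
    choice_fraction: float = 0.5
    choice_onset_ms: float = 200.0
    choice_kappa: float = 2.0
    slant_drift: float = 0.0
    sd_start: float = 52.0
    sd_end: float = 202.0
    spc_end: float = 1000.0
    alpha: float = 0.05
    onset_persist_ms: int = 30
    run_saccade_analyses: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def section_hash(self, keys) -> str:
        d = {k: getattr(self, k) for k in sorted(keys)}
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


SIM_KEYS = ("seed", "n_neurons", "n_blocks", "choice_fraction",
            "choice_onset_ms", "choice_kappa", "slant_drift")
ANA_KEYS = SIM_KEYS + ("sd_start", "sd_end", "spc_end", "alpha",
                       "onset_persist_ms", "run_saccade_analyses")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    stages: list = field(default_factory=list)

    def record(self, stage: str, outdir: Path, files: list, cfg_hash: str,
               ok: bool = True, error: str = "") -> None:
        self.stages.append({
            "stage": stage, "ok": ok, "error": error,
            "config_hash": cfg_hash, "timestamp": time.time(),
            "files": {f: _sha256(outdir / f) for f in files
                      if (outdir / f).exists()}})

    def save(self, outdir: Path) -> None:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump({"stages": self.stages}, fh, indent=1)

    @classmethod
    def load(cls, outdir: Path) -> "RunManifest":
        p = outdir / "manifest.json"
        if not p.exists():
            return cls()
        with open(p) as fh:
            return cls(stages=json.load(fh)["stages"])

    def cached(self, stage: str, cfg_hash: str, outdir: Path) -> bool:
        for s in reversed(self.stages):
            if s["stage"] == stage and s["ok"] and s["config_hash"] == cfg_hash:
                return all((outdir / f).exists() and _sha256(outdir / f) == h
                           for f, h in s["files"].items())
        return False


# ---------------------------------------------------------------------------
# Stages

def stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    log.info("simulate: seed=%d n_neurons=%d n_blocks=%d",
             cfg.seed, cfg.n_neurons, cfg.n_blocks)
    cohort = synth.make_neuron_cohort(
        cfg.n_neurons, seed=cfg.seed, choice_fraction=cfg.choice_fraction,
        choice_onset=cfg.choice_onset_ms, choice_kappa=cfg.choice_kappa,
        slant_drift=cfg.slant_drift)
    session = synth.simulate_session(cohort, n_blocks=cfg.n_blocks,
                                     seed=cfg.seed + 1)
    synth.session_to_csv(session, outdir)


def _load_session(outdir: Path):
    trials = pd.read_csv(outdir / "trials.csv")
    sp = pd.read_csv(outdir / "spikes.csv")
    spikes = {k: g["spike_time_ms"].to_numpy()
              for k, g in sp.groupby(["neuron_id", "trial_id"])}
    return trials, spikes


def stage_analyze(cfg: PipelineConfig, outdir: Path) -> None:
    grid = DesignGrid()
    trials, spikes = _load_session(outdir)
    windows = spk.AnalysisWindows(cfg.sd_start, cfg.sd_end, cfg.spc_end)
    plane = trials[trials["kind"] == "plane"]
    sacc = trials[trials["kind"] == "saccade"]
    neuron_ids = sorted({n for n, _ in spikes})

    # behavioral sensitivity
    sens = beh.sensitivity_map(plane, n_floor=8)
    sens.to_csv(outdir / "sensitivity.csv", index=False)
    sens.attrs["summary"].to_csv(outdir / "sensitivity_summary.csv", index=False)

    kernel = spk.SDFKernel()
    per_neuron = []
    sep_rows, geom_rows, tdi_frames = [], [], []
    zsdf_traces = []           # (8, T) per neuron for choice-onset
    fp_ids = plane[plane["slant"] == 0]["trial_id"].to_numpy()
    fp_choice = dict(zip(plane["trial_id"], plane["choice"]))
    fp_dist = dict(zip(plane["trial_id"], plane["distance_cm"]))

    for ni in neuron_ids:
        trains = {tid: spikes.get((ni, tid), np.empty(0))
                  for tid in plane["trial_id"]}
        base = {tid: spk.window_rate(s, (-150.0, 0.0))
                for tid, s in trains.items()}
        rate_rows = []
        for wname, win in (("sd", windows.sd), ("spc", windows.spc)):
            for tid, s in trains.items():
                rate_rows.append((ni, tid, wname,
                                  spk.window_rate(s, win), base[tid]))
        rates = pd.DataFrame(rate_rows, columns=[
            "neuron_id", "trial_id", "window", "rate_hz", "baseline_hz"])
        rates = rates.merge(plane[["trial_id", "tilt", "slant",
                                   "distance_cm", "choice"]], on="trial_id")

        zres = spk.zscore_frontoparallel(
            rates[rates["window"] == "spc"].assign(slant=lambda d: d["slant"]))
        z_fp = zres.table.merge(plane[["trial_id", "choice"]], on="trial_id")

        sac_rows = []
        for tid, d in zip(sacc["trial_id"], sacc["saccade_dir"]):
            s = spikes.get((ni, tid), np.empty(0))
            b = spk.window_rate(s, (-150.0, 0.0))
            sac_rows.append((d, spk.window_rate(s, (200.0, 400.0)) - b))
        sac_rates = pd.DataFrame(sac_rows, columns=["direction", "rate_hz"])

        gates = tun.tuning_gates(rates[rates["window"] == "sd"], z_fp,
                                 sac_rates, alpha=cfg.alpha,
                                 n_blocks=cfg.n_blocks)

        neuron_row = {"neuron_id": ni, "excluded": gates.excluded,
                      "choice_tuned": gates.choice_tuned,
                      "saccade_tuned": gates.saccade_tuned,
                      "orientation_any": gates.orientation_any,
                      "distance_tuned": gates.distance_tuned}

        for wname in ("sd", "spc"):
            sub = rates[rates["window"] == wname]
            tm = tun.TuningMatrix.from_trials(sub, grid)
            tdi_t = tun.tdi_map(sub)
            tdi_t.insert(0, "window", wname)
            tdi_t.insert(0, "neuron_id", ni)
            tdi_frames.append(tdi_t)
            try:
                fit = sep.fit_separable(tm.means)
                add = sep.fit_additive(tm.means)
                cmpres = sep.compare_models(tm.means, fit, add,
                                            n_permutations=2000, seed=cfg.seed)
                sep_rows.append((ni, wname, fit.dc, fit.gain, fit.tolerance,
                                 fit.residual_norm, add.residual_norm,
                                 cmpres.winner, fit.n_excluded_distances))
                neuron_row[f"tolerance_{wname}"] = fit.tolerance
            except (sep.DegenerateMatrixError, ValueError):
                sep_rows.append((ni, wname, np.nan, np.nan, np.nan, np.nan,
                                 np.nan, "failed", 4))

            # Bingham preferences per distance -> principal orientation
            normals = []
            for j, d in enumerate(grid.distances):
                col = tm.means[:, j]
                if np.isnan(col).any() or np.std(col) == 0:
                    continue
                bf = tun.fit_bingham(tm.orientations, col, n_restarts=4)
                if bf.converged and np.isfinite(bf.pref_tilt):
                    normals.append(geo.pose_to_normal(bf.pref_tilt,
                                                      min(bf.pref_slant, 90.0)))
            if normals:
                pri = geo.principal_orientation(np.array(normals))
                rot = geo.rotate_to_pole(np.array(normals), pri)
                for dv in geo.deviations(rot):
                    geom_rows.append((ni, wname, pri.tp, pri.sp,
                                      dv.delta_psi, dv.delta_angle))
                if wname == "sd":
                    neuron_row["principal_tilt_sd"] = pri.tp

        # choice tuning curve from SPC z-rates
        if len(z_fp) > 0:
            curve = z_fp.groupby("choice")["z"].mean()
            if len(curve) == 8:
                vm = tun.fit_von_mises(curve.index.to_numpy(),
                                       curve.to_numpy())
                neuron_row["choice_pref"] = vm.pref
                neuron_row["choice_kappa_hat"] = vm.kappa
        if len(sac_rates) > 0 and sac_rates["direction"].nunique() == 8:
            curve = sac_rates.groupby("direction")["rate_hz"].mean()
            vm = tun.fit_von_mises(curve.index.to_numpy(), curve.to_numpy())
            neuron_row["saccade_pref"] = vm.pref
            neuron_row["saccade_kappa_hat"] = vm.kappa
        per_neuron.append(neuron_row)

        # per-choice mean z-SDF traces on frontoparallel trials
        fp_trains = [trains[t] for t in fp_ids]
        sdf = spk.spike_density_matrix(fp_trains, 0.0, cfg.spc_end, kernel)
        dists = np.array([fp_dist[t] for t in fp_ids])
        zs = np.zeros_like(sdf)
        for d in np.unique(dists):
            m = dists == d
            mu, sd_ = sdf[m].mean(), sdf[m].std()
            zs[m] = (sdf[m] - mu) / (sd_ if sd_ > 0 else 1.0)
        choices = np.array([fp_choice[t] for t in fp_ids])
        ctr = np.full((8, sdf.shape[1]), np.nan)
        for k, c in enumerate(CHOICE_DIRECTIONS):
            m = choices == c
            if m.any():
                ctr[k] = zs[m].mean(axis=0)
        zsdf_traces.append(ctr)

    pd.DataFrame(sep_rows, columns=[
        "neuron_id", "window", "dc", "gain", "tolerance", "residual_mult",
        "residual_add", "winner", "n_excluded_distances"]
        ).to_csv(outdir / "separability.csv", index=False)
    pd.DataFrame(geom_rows, columns=[
        "neuron_id", "window_set", "tp", "sp", "delta_psi", "delta_angle"]
        ).to_csv(outdir / "geometry.csv", index=False)
    pd.concat(tdi_frames, ignore_index=True).to_csv(outdir / "tdi.csv",
                                                    index=False)
    neurons = pd.DataFrame(per_neuron)
    neurons.to_csv(outdir / "neurons.csv", index=False)

    # population choice onset
    timing = {}
    tr = np.array([np.where(np.isnan(c), 0.0, c) for c in zsdf_traces])
    if len(tr) >= 2:
        res = tim.choice_onset(tr, t0=0.0, t_end=cfg.spc_end, alpha=cfg.alpha,
                               persist_ms=cfg.onset_persist_ms)
        timing["choice_onset_ms"] = res.onset_ms
        timing["choice_onset_iterations"] = res.iterations
        timing["choice_onset_converged"] = res.converged
        timing["choice_onset_history"] = res.history

    if cfg.run_saccade_analyses and len(sacc) > 0:
        dir_traces = []
        lat_by_trial = dict(zip(sacc["trial_id"], sacc["latency_ms"]))
        t0s = -300.0
        for ni in neuron_ids:
            per_dir = np.zeros((8, int(300 + 100)))
            for k, d in enumerate(CHOICE_DIRECTIONS):
                ids = sacc[sacc["saccade_dir"] == d]["trial_id"].to_numpy()
                aligned = [spikes.get((ni, t), np.empty(0)) - lat_by_trial[t]
                           for t in ids if np.isfinite(lat_by_trial.get(t, np.nan))]
                if aligned:
                    per_dir[k] = spk.spike_density_matrix(
                        aligned, t0s, 100.0, kernel).mean(axis=0)
            dir_traces.append(per_dir)
        if len(dir_traces) >= 2:
            res = tim.saccade_activity_start(np.array(dir_traces), t0=t0s,
                                             alpha=cfg.alpha,
                                             persist_ms=cfg.onset_persist_ms)
            timing["saccade_start_ms"] = res.onset_ms
            timing["saccade_start_converged"] = res.converged
    with open(outdir / "timing.json", "w") as fh:
        json.dump(timing, fh, indent=1, default=float)

    # alignment: principal tilt vs choice pref; tilt vs saccade pref
    al_rows = []
    if "principal_tilt_sd" in neurons and "choice_pref" in neurons:
        ok = neurons.dropna(subset=["principal_tilt_sd", "choice_pref"])
        for _, r in ok.iterrows():
            al_rows.append((r["neuron_id"], "tilt_vs_choice",
                            float(beh.tilt_error(r["choice_pref"],
                                                 r["principal_tilt_sd"]))))
    if "principal_tilt_sd" in neurons and "saccade_pref" in neurons:
        ok = neurons.dropna(subset=["principal_tilt_sd", "saccade_pref"])
        for _, r in ok.iterrows():
            al_rows.append((r["neuron_id"], "tilt_vs_saccade",
                            float(beh.tilt_error(r["saccade_pref"],
                                                 r["principal_tilt_sd"]))))
    pd.DataFrame(al_rows, columns=["neuron_id", "pair", "circular_difference"]
                 ).to_csv(outdir / "alignment.csv", index=False)


def stage_report(cfg: PipelineConfig, outdir: Path) -> None:
    neurons = pd.read_csv(outdir / "neurons.csv")
    sep_t = pd.read_csv(outdir / "separability.csv")
    tdi_t = pd.read_csv(outdir / "tdi.csv")
    geom = pd.read_csv(outdir / "geometry.csv")

    tol = sep_t.pivot_table(index="neuron_id", columns="window",
                            values="tolerance")
    merged = neurons.merge(tol, on="neuron_id", how="left")
    rows = []
    for cflag, g in merged.groupby(merged.get("choice_tuned", False)):
        rows.append(("choice_tuned" if cflag else "not_choice_tuned",
                     g["sd"].mean() if "sd" in g else np.nan,
                     g["spc"].mean() if "spc" in g else np.nan, len(g)))
    pd.DataFrame(rows, columns=["subpopulation", "tolerance_sd",
                                "tolerance_spc", "n"]
                 ).to_csv(outdir / "report_tolerance.csv", index=False)

    tdi_map = tdi_t[tdi_t["window"] == "sd"].groupby(
        ["slant", "distance_cm"])["tdi"].mean().reset_index()
    tdi_map.to_csv(outdir / "report_tdi_map.csv", index=False)

    dev = geom.groupby("window_set")["delta_angle"].describe()
    dev.to_csv(outdir / "report_deviations.csv")

    c = neurons.get("choice_tuned", pd.Series(dtype=bool)).fillna(False).astype(bool)
    s = neurons.get("saccade_tuned", pd.Series(dtype=bool)).fillna(False).astype(bool)
    venn = {"choice_only": int((c & ~s).sum()),
            "saccade_only": int((~c & s).sum()),
            "both": int((c & s).sum()),
            "neither": int((~c & ~s).sum()),
            "total": int(len(neurons))}
    with open(outdir / "report_venn.json", "w") as fh:
        json.dump(venn, fh, indent=1)


STAGES = {"simulate": (stage_simulate, SIM_KEYS),
          "analyze": (stage_analyze, ANA_KEYS),
          "report": (stage_report, ANA_KEYS)}
STAGE_ORDER = ["simulate", "analyze", "report"]


def run(cfg: PipelineConfig, stages=None, force: bool = False) -> RunManifest:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest.load(outdir)
    wanted = stages or STAGE_ORDER
    failed = False
    for name in STAGE_ORDER:
        if name not in wanted:
            continue
        fn, keys = STAGES[name]
        cfg_hash = cfg.section_hash(keys)
        if failed:
            manifest.record(name, outdir, [], cfg_hash, ok=False,
                            error="skipped: upstream failure")
            continue
        if not force and manifest.cached(name, cfg_hash, outdir):
            log.info("%s: cached, skipping", name)
            continue
        before = {p.name for p in outdir.iterdir()}
        try:
            t0 = time.time()
            fn(cfg, outdir)
            log.info("%s: done in %.1fs", name, time.time() - t0)
            after = {p.name for p in outdir.iterdir()}
            manifest.record(name, outdir, sorted(after - before | (
                after & before)), cfg_hash)
        except Exception as exc:        # stage failure recorded, rest skipped
            log.exception("%s failed", name)
            manifest.record(name, outdir, [], cfg_hash, ok=False,
                            error=str(exc))
            failed = True
    manifest.save(outdir)
    return manifest
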