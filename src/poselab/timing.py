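"""Population-level event timing.

Detects the onset of choice-related activity (which splits the stimulus
epoch into sensory-dominant and sensory-plus-choice windows), the start of
pre-saccadic activity, the latency-quartile growth-rate / threshold
structure of saccade-related ramps, and circular alignment statistics
between tilt, choice, and saccade preferences.

The onset estimators share one fixed-point loop: (1) assign each neuron's
preferred condition from mean rates in the current window, (2) build the
eight population time courses relative to the preferred condition,
(3) find the first millisecond where a one-way ANOVA across the eight
curves rejects at p < alpha, (4) re-window from that time and repeat until
the estimate no longer changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .circstats import (wrap_diff, circ_median, circ_median_test, circ_var,
                        concentration_difference_test)


@dataclass
class OnsetResult:
    onset_ms: float | None
    iterations: int
    converged: bool
    p_trace: np.ndarray | None = None
    history: list = field(default_factory=list)


def _anova_f_trace(rel: np.ndarray) -> np.ndarray:
    """Vectorized per-ms one-way ANOVA p-values.

    ``rel``: (n_neurons, n_groups, T) — at each time point the groups are
    the columns, observations the neurons.
    """
    n, k, T = rel.shape
    gm = rel.mean(axis=0)                       # (k, T)
    grand = gm.mean(axis=0)                     # (T,)
    ssb = n * ((gm - grand) ** 2).sum(axis=0)
    ssw = ((rel - gm[None]) ** 2).sum(axis=(0, 1))
    dfb, dfw = k - 1, k * (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / dfb) / (ssw / dfw)
    p = stats.f.sf(F, dfb, dfw)
    return np.where(np.isfinite(p), p, 1.0)


def _first_sustained(p: np.ndarray, alpha: float, persist: int,
                     lo: int, hi: int) -> int | None:
    run = 0
    for i in range(max(lo, 0), min(hi, len(p))):
        run = run + 1 if p[i] < alpha else 0
        if run >= persist:
            return i - persist + 1
    return None


def _relative_traces(traces: np.ndarray, pref_idx: np.ndarray) -> np.ndarray:
    """Re-index the condition axis of (n, 8, T) traces so index 0 is each
    neuron's preferred condition, then +45, +90, ... in 45-deg steps."""
    n, k, T = traces.shape
    rel = np.empty_like(traces)
    for i in range(n):
        rel[i] = np.roll(traces[i], -pref_idx[i], axis=0)
    return rel


def choice_onset(traces: np.ndarray, t0: float = 0.0, t_end: float = 1000.0,
                 alpha: float = 0.05, persist_ms: int = 1,
                 max_iter: int = 20, freeze_pref: bool = False) -> OnsetResult:
    """Population onset of choice-related activity.

    ``traces``: (n_neurons, 8, T) per-neuron per-choice mean z-scored SDFs
    aligned to stimulus onset at ``t0`` ms (1 ms sampling).  Preferred
    choices are initially assigned from the full-epoch rates; unless
    ``freeze_pref``, they are updated each iteration from the current
    window.  Returns None onset if the curves never significantly diverge.
    """
    traces = np.asarray(traces, dtype=float)
    n, k, T = traces.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 neurons and >= 2 conditions")
    i_end = int(round(t_end - t0))
    i_stim = int(round(0.0 - t0))
    window = (i_stim, i_end)
    onset_idx = None
    history = []
    pref = None
    p = None
    for it in range(1, max_iter + 1):
        if pref is None or not freeze_pref:
            wmean = traces[:, :, window[0]:window[1]].mean(axis=2)
            pref = np.argmax(wmean, axis=1)
        rel = _relative_traces(traces, pref)
        p = _anova_f_trace(rel)
        new_idx = _first_sustained(p, alpha, persist_ms, i_stim, i_end)
        history.append(None if new_idx is None else float(t0 + new_idx))
        if new_idx is None:
            return OnsetResult(None, it, converged=True, p_trace=p,
                               history=history)
        if new_idx == onset_idx:
            return OnsetResult(float(t0 + new_idx), it, converged=True,
                               p_trace=p, history=history)
        if len(history) >= 3 and history[-1] == history[-3]:
            mid = 0.5 * (history[-1] + history[-2])     # 2-cycle: midpoint
            return OnsetResult(mid, it, converged=False, p_trace=p,
                               history=history)
        onset_idx = new_idx
        window = (new_idx, i_end)
    return OnsetResult(float(t0 + onset_idx) if onset_idx is not None else None,
                       max_iter, converged=False, p_trace=p, history=history)


def saccade_activity_start(traces: np.ndarray, t0: float,
                           alpha: float = 0.05, persist_ms: int = 1,
                           max_iter: int = 20) -> OnsetResult:
    """Start of pre-saccadic direction selectivity.

    ``traces``: (n_neurons, 8, T) per-direction mean SDFs aligned to the
    saccade onset, time axis from ``t0`` (negative) to >= 0.  The same
    fixed-point loop as :func:`choice_onset` runs with windows
    [start, saccade onset].  Returned onset is negative (ms before onset).
    """
    traces = np.asarray(traces, dtype=float)
    i_zero = int(round(0.0 - t0))
    onset_idx = None
    history = []
    window = (0, i_zero)
    p = None
    for it in range(1, max_iter + 1):
        wmean = traces[:, :, window[0]:window[1]].mean(axis=2)
        pref = np.argmax(wmean, axis=1)
        rel = _relative_traces(traces, pref)
        p = _anova_f_trace(rel)
        new_idx = _first_sustained(p, alpha, persist_ms, 0, i_zero)
        history.append(None if new_idx is None else float(t0 + new_idx))
        if new_idx is None:
            return OnsetResult(None, it, converged=True, p_trace=p,
                               history=history)
        if new_idx == onset_idx:
            return OnsetResult(float(t0 + new_idx), it, converged=True,
                               p_trace=p, history=history)
        if len(history) >= 3 and history[-1] == history[-3]:
            mid = 0.5 * (history[-1] + history[-2])
            return OnsetResult(mid, it, converged=False, p_trace=p,
                               history=history)
        onset_idx = new_idx
        window = (new_idx, i_zero)
    return OnsetResult(float(t0 + onset_idx) if onset_idx is not None else None,
                       max_iter, converged=False, p_trace=p, history=history)


# ---------------------------------------------------------------------------
# Latency-quartile growth-rate analysis

@dataclass
class QuartileRamp:
    quartile: int
    mean_latency_ms: float
    activity_start_ms: float | None
    growth_rate: float | None          # spikes/s per ms
    threshold_crossing_ms: float | None


@dataclass
class LatencyQuartileResult:
    quartiles: list
    threshold_hz: float
    threshold_time_ms: float
    gr_sl_slope: float
    gr_sl_intercept: float
    gr_sl_pvalue: float


def latency_quartile_analysis(sdfs: np.ndarray, latencies: np.ndarray,
                              t0: float, baseline_window=(-300.0, -200.0),
                              search_window=(-50.0, 0.0), alpha: float = 0.05,
                              persist_ms: int = 20, min_per_quartile: int = 10,
                              kernel_delay_ms: float = 21.0,
                              smooth_ms: int = 15) -> LatencyQuartileResult:
    """Latency-conditioned pre-saccadic ramps from preferred-direction trials.

    ``sdfs``: (n_trials, T) saccade-aligned traces starting at ``t0`` ms.
    Trials are split into latency quartiles; each quartile's mean time
    course yields an activity start (first sustained deviation from
    baseline), a putative initiation threshold is the rate at the time in
    ``search_window`` minimizing across-quartile spread, and the growth
    rate is the LS slope from activity start to the threshold crossing.
    Returns the per-quartile ramps and the growth-rate vs mean-latency
    regression.

    Because the causal SDF kernel delays the trace by its group delay
    (``kernel_delay_ms``; ~21 ms at the default time constants), traces are
    shifted earlier by that amount before analysis so ramp timing and the
    threshold refer to the underlying rate; set 0 to disable.
    """
    sdfs = np.asarray(sdfs, dtype=float)
    shift = int(round(kernel_delay_ms))
    if shift > 0:
        pad = np.repeat(sdfs[:, -1:], shift, axis=1)
        sdfs = np.concatenate([sdfs[:, shift:], pad], axis=1)
    lat = np.asarray(latencies, dtype=float)
    if len(lat) < 4 * min_per_quartile:
        raise ValueError(f"need >= {4 * min_per_quartile} trials")
    if np.ptp(lat) == 0:
        raise ValueError("degenerate latency distribution (all equal)")
    order = np.argsort(lat, kind="stable")
    folds = np.array_split(order, 4)
    i_b0, i_b1 = (int(round(b - t0)) for b in baseline_window)
    i_s0, i_s1 = (int(round(s - t0)) for s in search_window)

    qmeans = np.stack([sdfs[f].mean(axis=0) for f in folds])
    if smooth_ms > 1:                 # denoise the mean time courses
        box = np.ones(smooth_ms) / smooth_ms
        qmeans = np.apply_along_axis(
            lambda v: np.convolve(v, box, mode="same"), 1, qmeans)
    spread = qmeans[:, i_s0:i_s1 + 1].var(axis=0)
    k_star = int(np.argmin(spread))
    thr_time = float(t0 + i_s0 + k_star)
    threshold = float(qmeans[:, i_s0 + k_star].mean())

    ramps = []
    for q, f in enumerate(folds):
        tr = sdfs[f]
        base = tr[:, i_b0:i_b1].mean(axis=1)
        # per-ms paired comparison against each trial's own baseline
        diff = tr - base[:, None]
        n = len(f)
        se = diff.std(axis=0, ddof=1) / np.sqrt(n)
        with np.errstate(divide="ignore", invalid="ignore"):
            tt = diff.mean(axis=0) / se
        p = 2.0 * stats.t.sf(np.abs(tt), df=n - 1)
        p = np.where(np.isfinite(p), p, 1.0)
        start_idx = _first_sustained(p, alpha, persist_ms, i_b1,
                                     int(round(0.0 - t0)))
        qm = qmeans[q]
        mean_lat = float(lat[f].mean())
        if start_idx is None:
            ramps.append(QuartileRamp(q + 1, mean_lat, None, None, None))
            continue
        cross = np.flatnonzero(qm[start_idx:] >= threshold)
        if len(cross) == 0:
            ramps.append(QuartileRamp(q + 1, mean_lat, float(t0 + start_idx),
                                      None, None))
            continue
        end_idx = start_idx + int(cross[0])
        if end_idx - start_idx < 3:
            end_idx = min(start_idx + 3, sdfs.shape[1] - 1)
        tt_axis = np.arange(start_idx, end_idx + 1, dtype=float)
        slope = float(np.polyfit(tt_axis, qm[start_idx:end_idx + 1], 1)[0])
        ramps.append(QuartileRamp(q + 1, mean_lat, float(t0 + start_idx),
                                  slope, float(t0 + end_idx)))

    ok = [r for r in ramps if r.growth_rate is not None]
    if len(ok) >= 3:
        reg = stats.linregress([r.mean_latency_ms for r in ok],
                               [r.growth_rate for r in ok])
        slope, icpt, pv = float(reg.slope), float(reg.intercept), float(reg.pvalue)
    else:
        slope = icpt = pv = float("nan")
    return LatencyQuartileResult(quartiles=ramps, threshold_hz=threshold,
                                 threshold_time_ms=thr_time,
                                 gr_sl_slope=slope, gr_sl_intercept=icpt,
                                 gr_sl_pvalue=pv)


# ---------------------------------------------------------------------------
# Preference alignment

@dataclass
class AlignmentResult:
    differences: np.ndarray           # signed circular differences, degrees
    median_deg: float
    median_p: float                   # circular median test vs 0
    circular_variance: float
    n: int


def preference_alignment(pref_a, pref_b, min_pairs: int = 5
                         ) -> AlignmentResult:
    """Circular differences between paired preferences (a - b), with a
    circular median test against 0 and the circular variance of the
    differences.  Swapping the inputs negates the differences."""
    a = np.asarray(pref_a, dtype=float)
    b = np.asarray(pref_b, dtype=float)
    if a.shape != b.shape or len(a) < min_pairs:
        raise ValueError(f"need >= {min_pairs} matched pairs")
    d = wrap_diff(a, b)
    return AlignmentResult(differences=d, median_deg=circ_median(d),
                           median_p=circ_median_test(d, 0.0),
                           circular_variance=float(circ_var(d)), n=len(d))


def compare_alignment_concentration(diffs_a, diffs_b):
    """Concentration-difference test between two groups of circular
    preference differences (Wallraff rank procedure); returns (stat, p)."""
    return concentration_difference_test(diffs_a, diffs_b)


def compare_deviation_cdfs(dev_a, dev_b):
    """Two-sample Kolmogorov-Smirnov test on angular-deviation samples;
    returns (statistic, p)."""
    res = stats.ks_2samp(np.asarray(dev_a, dtype=float),
                         np.asarray(dev_b, dtype=float))
    return float(res.statistic), float(res.pvalue)
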