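"""Single-neuron tuning quantification.

Covers the tilt discrimination index (TDI), Bingham fits of 3D orientation
tuning on the (tilt, slant) hemisphere, von Mises fits of choice / saccade
direction tuning, and the ANOVA-based significance gates that decide which
neurons and conditions enter downstream analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import DesignGrid, orientation_index
from .geometry import pose_to_normal
from .circstats import wrap_diff


# ---------------------------------------------------------------------------
# Tuning matrix container

@dataclass
class TuningMatrix:
    """Orientations-by-distances matrix of trial-mean rates.

    Rows follow :func:`poselab.design.orientation_index` (frontoparallel
    first, then slant-major/tilt-minor); columns follow the grid's distance
    order.  ``vars`` are within-cell variances (ddof=1), ``counts`` per-cell
    trial counts.
    """

    means: np.ndarray
    vars: np.ndarray
    counts: np.ndarray
    orientations: list          # [(tilt, slant)] row labels
    distances: tuple
    window: tuple | None = None

    @classmethod
    def from_trials(cls, trials: pd.DataFrame, grid: DesignGrid | None = None,
                    rate_col: str = "rate_hz", window: tuple | None = None
                    ) -> "TuningMatrix":
        """Build from a per-trial table with tilt, slant, distance_cm, rate."""
        grid = grid or DesignGrid()
        oris = orientation_index(grid)
        dists = grid.distances
        shape = (len(oris), len(dists))
        means = np.full(shape, np.nan)
        vars_ = np.full(shape, np.nan)
        counts = np.zeros(shape, dtype=int)
        dcol = trials["distance_cm"].to_numpy(dtype=float)
        scol = trials["slant"].to_numpy(dtype=float)
        tcol = trials["tilt"].to_numpy(dtype=float)
        r = trials[rate_col].to_numpy(dtype=float)
        for i, (tilt, slant) in enumerate(oris):
            if slant == 0:
                omask = scol == 0
            else:
                omask = (scol == slant) & (tcol == tilt)
            for j, d in enumerate(dists):
                cell = r[omask & (dcol == d)]
                counts[i, j] = len(cell)
                if len(cell) > 0:
                    means[i, j] = cell.mean()
                    vars_[i, j] = cell.var(ddof=1) if len(cell) > 1 else 0.0
        return cls(means=means, vars=vars_, counts=counts,
                   orientations=oris, distances=tuple(dists), window=window)


# ---------------------------------------------------------------------------
# Tilt discrimination index

@dataclass
class TDIResult:
    tdi: float
    r_max: float
    r_min: float
    sse: float
    n_trials: int
    n_tilts: int


def tdi(responses_by_tilt: dict, literal_denominator: bool = False) -> TDIResult:
    """Tilt discrimination index for one slant-distance tilt curve.

    TDI = (Rmax - Rmin) / (Rmax - Rmin + 2 sqrt(SSE/(N - M))) where Rmax,
    Rmin are the extreme tilt-mean responses, SSE the within-tilt sum of
    squared errors, N the trial count, and M the number of tilts.  Values
    near 1 mean strong modulation relative to variability.
    ``literal_denominator`` uses 2*SSE/(N-M) (no square root) instead.
    """
    means = []
    sse = 0.0
    n = 0
    for tilt, resp in responses_by_tilt.items():
        r = np.asarray(resp, dtype=float)
        if len(r) < 2:
            raise ValueError(f"tilt {tilt}: need >=2 trials per tilt")
        means.append(r.mean())
        sse += float(((r - r.mean()) ** 2).sum())
        n += len(r)
    m = len(means)
    if n <= m:
        raise ValueError("TDI undefined: N <= M")
    r_max, r_min = max(means), min(means)
    noise = (2.0 * sse / (n - m)) if literal_denominator \
        else 2.0 * np.sqrt(sse / (n - m))
    denom = (r_max - r_min) + noise
    val = 0.0 if denom == 0 else (r_max - r_min) / denom
    return TDIResult(tdi=float(val), r_max=float(r_max), r_min=float(r_min),
                     sse=float(sse), n_trials=n, n_tilts=m)


def tdi_map(trials: pd.DataFrame, rate_col: str = "rate_hz") -> pd.DataFrame:
    """TDI per (slant, distance) combination from a per-trial table."""
    rows = []
    slanted = trials[trials["slant"] > 0]
    for (slant, dist), g in slanted.groupby(["slant", "distance_cm"]):
        by_tilt = {t: gg[rate_col].to_numpy() for t, gg in g.groupby("tilt")}
        try:
            res = tdi(by_tilt)
            rows.append((slant, dist, res.tdi, res.n_trials))
        except ValueError:
            rows.append((slant, dist, np.nan, len(g)))
    return pd.DataFrame(rows, columns=["slant", "distance_cm", "tdi", "n"])


# ---------------------------------------------------------------------------
# Bingham orientation fit

@dataclass
class BinghamFit:
    pref_tilt: float
    pref_slant: float
    lambda1: float            # <= lambda2 <= 0
    lambda2: float
    axis_rotation: float      # degrees, orientation of the minor axis
    amplitude: float
    offset: float
    fit_r: float
    converged: bool = True
    isotropic: bool = False   # lambda1 ~ lambda2: axis unidentifiable


def _bingham_frame(pref_tilt: float, pref_slant: float, psi_deg: float
                   ) -> np.ndarray:
    """Orthonormal frame M whose third column is the preferred normal and
    whose first two columns span its tangent plane, rotated by psi."""
    n = pose_to_normal(pref_tilt, pref_slant)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(n[2]) > 0.999999:
        e1 = np.array([1.0, 0.0, 0.0])
    else:
        e1 = np.cross(ref, n)
        e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    psi = np.deg2rad(psi_deg)
    u1 = np.cos(psi) * e1 + np.sin(psi) * e2
    u2 = -np.sin(psi) * e1 + np.cos(psi) * e2
    return np.column_stack([u1, u2, n])


def bingham_predict(normals: np.ndarray, pref_tilt: float, pref_slant: float,
                    lambda1: float, lambda2: float, psi_deg: float,
                    amplitude: float, offset: float) -> np.ndarray:
    """Bingham-function rate: offset + amplitude * exp(n^T M Z M^T n) with
    Z = diag(lambda1, lambda2, 0); maximal (= offset + amplitude) at the
    preferred orientation."""
    M = _bingham_frame(pref_tilt, pref_slant, psi_deg)
    proj = normals @ M
    q = lambda1 * proj[:, 0] ** 2 + lambda2 * proj[:, 1] ** 2
    return offset + amplitude * np.exp(q)


def fit_bingham(orientations, rates, n_restarts: int = 8,
                lam_bound: float = 20.0, rng=None) -> BinghamFit:
    """Least-squares Bingham fit of one orientation tuning curve.

    ``orientations``: [(tilt, slant)] with frontoparallel tilt NaN;
    ``rates``: matching mean rates.  Multi-start: restarts seeded at the
    empirical peak and at 45-deg-spaced tilts; lambdas bounded in
    [-lam_bound, 0]; ties broken by lowest residual then lowest |lambda1|.
    The fitted preferred orientation may lie beyond the sampled slant range.
    """
    rates = np.asarray(rates, dtype=float)
    normals = np.array([pose_to_normal(t, s) for t, s in orientations])
    peak = int(np.nanargmax(rates))
    pk_tilt, pk_slant = orientations[peak]
    if not np.isfinite(pk_tilt):
        pk_tilt, pk_slant = 0.0, 1.0
    rmin, rmax = float(np.nanmin(rates)), float(np.nanmax(rates))
    amp0 = max(rmax - rmin, 1e-3)

    def residuals(p):
        tilt, slant, l1, l2, psi, amp, off = p
        return bingham_predict(normals, tilt, slant, -abs(l1), -abs(l2),
                               psi, amp, off) - rates

    starts = [(pk_tilt, pk_slant)] + [((pk_tilt + k * 45.0) % 360.0, 45.0)
                                      for k in range(max(n_restarts, 1))]
    best = None
    for t0, s0 in starts:
        try:
            res = optimize.least_squares(
                residuals, x0=[t0, s0, 2.0, 1.0, 0.0, amp0, rmin],
                bounds=([-360.0, 0.0, 0.0, 0.0, -180.0, 0.0, -np.inf],
                        [720.0, 90.0, lam_bound, lam_bound, 180.0, np.inf, np.inf]),
                max_nfev=400)
        except Exception:
            continue
        key = (res.cost, abs(res.x[2]))
        if best is None or key < best[0]:
            best = (key, res)
    if best is None:
        return BinghamFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                          np.nan, np.nan, converged=False)
    res = best[1]
    tilt, slant, l1, l2, psi, amp, off = res.x
    l1, l2 = -abs(l1), -abs(l2)
    if l1 > l2:          # enforce lambda1 <= lambda2; swap rotates axis 90 deg
        l1, l2 = l2, l1
        psi = float(wrap_diff(psi + 90.0))
    tilt = float(tilt) % 360.0
    pred = bingham_predict(normals, tilt, slant, l1, l2, psi, amp, off)
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(pred, rates)[0, 1] if np.std(pred) > 0 else 0.0
    iso = bool(abs(l1 - l2) < 1e-3)
    return BinghamFit(pref_tilt=tilt, pref_slant=float(slant), lambda1=float(l1),
                      lambda2=float(l2),
                      axis_rotation=float("nan") if iso else float(wrap_diff(psi)),
                      amplitude=float(amp), offset=float(off), fit_r=float(r),
                      converged=bool(res.success), isotropic=iso)


# ---------------------------------------------------------------------------
# Von Mises direction tuning fit

@dataclass
class VonMisesTuningFit:
    pref: float
    kappa: float
    amplitude: float
    baseline: float
    hwhh: float               # degrees; 180 with capped flag at low kappa
    hwhh_capped: bool
    fit_r: float
    pref_identifiable: bool = True


def vm_hwhh(kappa: float) -> tuple[float, bool]:
    """Half-width at half-height of exp(kappa(cos x - 1)): solves
    exp(kappa(cos w - 1)) = 1/2 -> w = arccos(1 + ln(1/2)/kappa), defined
    for kappa >= ln(2)/2; below that the curve never falls to half."""
    if kappa < np.log(2.0) / 2.0:
        return 180.0, True
    return float(np.rad2deg(np.arccos(1.0 + np.log(0.5) / kappa))), False


def fit_von_mises(directions_deg, rates, rng=None) -> VonMisesTuningFit:
    """Nonlinear least-squares fit of rate = baseline +
    amplitude * exp(kappa (cos(theta - pref) - 1)) to an 8-point curve."""
    th = np.asarray(directions_deg, dtype=float)
    r = np.asarray(rates, dtype=float)
    if len(th) != len(r) or len(th) < 4:
        raise ValueError("need matched direction/rate arrays (>= 4 points)")

    def model(p):
        pref, kappa, amp, base = p
        return base + amp * np.exp(kappa * (np.cos(np.deg2rad(th - pref)) - 1.0))

    def residuals(p):
        return model(p) - r

    amp0 = max(r.max() - r.min(), 1e-6)
    best = None
    for pref0 in th:
        res = optimize.least_squares(
            residuals, x0=[pref0, 2.0, amp0, r.min()],
            bounds=([-360.0, 0.0, 0.0, -np.inf], [720.0, 100.0, np.inf, np.inf]),
            max_nfev=200)
        if best is None or res.cost < best.cost:
            best = res
    pref, kappa, amp, base = best.x
    pred = model(best.x)
    with np.errstate(invalid="ignore"):
        fr = np.corrcoef(pred, r)[0, 1] if np.std(pred) > 0 else 0.0
    hw, capped = vm_hwhh(kappa)
    ident = amp > 1e-6 * max(abs(base), 1.0)
    return VonMisesTuningFit(pref=float(pref % 360.0) if ident else float("nan"),
                             kappa=float(kappa), amplitude=float(amp),
                             baseline=float(base), hwhh=hw, hwhh_capped=capped,
                             fit_r=float(fr), pref_identifiable=bool(ident))


# ---------------------------------------------------------------------------
# Significance gates

@dataclass
class TuningGates:
    orientation_tuned: dict         # distance -> bool (Holm over distances)
    orientation_p: dict
    distance_tuned: bool
    orientation_any: bool
    choice_tuned: bool | None
    saccade_tuned: bool | None
    slant_tuned: bool | None
    distance_tuned_linear: bool | None
    excluded: bool = False
    reason: str = ""


def _holm(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Bonferroni-Holm rejection decisions."""
    from statsmodels.stats.multitest import multipletests
    ok = np.isfinite(pvals)
    rej = np.zeros(len(pvals), dtype=bool)
    if ok.any():
        rej[ok] = multipletests(pvals[ok], alpha=alpha, method="holm")[0]
    return rej


def _oneway_by_label(values: np.ndarray, labels: np.ndarray) -> float:
    groups = [values[labels == u] for u in np.unique(labels)]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        return np.nan
    return float(stats.f_oneway(*groups).pvalue)


def _orientation_labels(trials: pd.DataFrame) -> np.ndarray:
    slant = trials["slant"].to_numpy(dtype=float)
    tilt = trials["tilt"].to_numpy(dtype=float)
    lab = np.where(slant == 0, "fp", [f"{t:.0f}_{s:.0f}" for t, s in zip(tilt, slant)])
    return lab


def tuning_gates(plane_rates: pd.DataFrame, z_fp: pd.DataFrame | None = None,
                 saccade_rates: pd.DataFrame | None = None,
                 alpha: float = 0.05, min_blocks: int = 5,
                 n_blocks: int | None = None) -> TuningGates:
    """Significance gates for one neuron.

    ``plane_rates``: per-trial window rates with tilt/slant/distance_cm.
    ``z_fp``: z-scored frontoparallel responses with a ``choice`` column.
    ``saccade_rates``: baseline-subtracted rates with a ``direction`` column.
    Requires at least ``min_blocks`` complete blocks (inferred from the
    minimum per-pose trial count unless ``n_blocks`` is given).
    """
    if n_blocks is None:
        cnt = plane_rates.groupby(["tilt", "slant", "distance_cm"],
                                  dropna=False).size()
        n_blocks = int(cnt.min()) if len(cnt) else 0
    if n_blocks < min_blocks:
        return TuningGates({}, {}, False, False, None, None, None, None,
                           excluded=True,
                           reason=f"{n_blocks} complete blocks < {min_blocks}")

    rates = plane_rates["rate_hz"].to_numpy(dtype=float)
    labels = _orientation_labels(plane_rates)
    dists = plane_rates["distance_cm"].to_numpy(dtype=float)
    uniq_d = np.unique(dists)

    ori_p = np.array([_oneway_by_label(rates[dists == d], labels[dists == d])
                      for d in uniq_d])
    rej = _holm(ori_p, alpha)
    orientation_tuned = {float(d): bool(r) for d, r in zip(uniq_d, rej)}
    orientation_p = {float(d): float(p) for d, p in zip(uniq_d, ori_p)}

    # two-way orientation x distance ANOVA (distance main effect)
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    df2 = pd.DataFrame({"rate": rates, "ori": labels, "dist": dists.astype(str)})
    try:
        aov = sm.stats.anova_lm(ols("rate ~ C(ori) + C(dist)", data=df2).fit(),
                                typ=2)
        distance_tuned = bool(aov.loc["C(dist)", "PR(>F)"] < alpha)
    except Exception:
        distance_tuned = False

    # four-way linearized model on slanted trials: slant, distance, tilt cos/sin
    slanted = plane_rates[plane_rates["slant"] > 0].copy()
    slant_tuned = distance_tuned_lin = None
    if len(slanted) > 20:
        t = np.deg2rad(slanted["tilt"].to_numpy(dtype=float))
        df4 = pd.DataFrame({
            "rate": slanted["rate_hz"].to_numpy(dtype=float),
            "slant": slanted["slant"].astype(str).to_numpy(),
            "dist": slanted["distance_cm"].astype(str).to_numpy(),
            "tc": np.cos(t), "ts": np.sin(t)})
        try:
            aov4 = sm.stats.anova_lm(
                ols("rate ~ C(slant) + C(dist) + tc + ts", data=df4).fit(), typ=2)
            slant_tuned = bool(aov4.loc["C(slant)", "PR(>F)"] < alpha)
            distance_tuned_lin = bool(aov4.loc["C(dist)", "PR(>F)"] < alpha)
        except Exception:
            pass

    choice_tuned = None
    if z_fp is not None and len(z_fp) > 0:
        p = _oneway_by_label(z_fp["z"].to_numpy(dtype=float),
                             z_fp["choice"].to_numpy())
        choice_tuned = bool(np.isfinite(p) and p < alpha)

    saccade_tuned = None
    if saccade_rates is not None and len(saccade_rates) > 0:
        p = _oneway_by_label(saccade_rates["rate_hz"].to_numpy(dtype=float),
                             saccade_rates["direction"].to_numpy())
        saccade_tuned = bool(np.isfinite(p) and p < alpha)

    return TuningGates(orientation_tuned=orientation_tuned,
                       orientation_p=orientation_p,
                       distance_tuned=distance_tuned,
                       orientation_any=bool(rej.any()),
                       choice_tuned=choice_tuned, saccade_tuned=saccade_tuned,
                       slant_tuned=slant_tuned,
                       distance_tuned_linear=distance_tuned_lin)
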