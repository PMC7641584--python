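"""Behavioral tilt sensitivity from reported-tilt error distributions.

Performance is quantified per condition by fitting a von Mises density to
the distribution of tilt report errors (DeltaTilt = reported - presented):

    VM(DeltaTilt) = exp(kappa * cos(DeltaTilt - mu)) / (2 pi I0(kappa))

mu measures accuracy (0 = unbiased) and kappa sensitivity.  With the 45 deg
report grid the density is discretized onto the eight possible errors
{0, +-45, +-90, +-135, 180} (density at bin centers, renormalized), and the
multinomial likelihood of the observed error counts is maximized over
(mu, kappa).  kappa is bounded above at 18, the largest concentration that
the 45 deg sampling interval can resolve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .circstats import wrap_diff

KAPPA_MAX = 18.0
ERROR_BINS = np.array([-135.0, -90.0, -45.0, 0.0, 45.0, 90.0, 135.0, 180.0])


class UndefinedTiltError(ValueError):
    """Raised when a tilt error is requested for a frontoparallel trial."""


def tilt_error(reported: float, presented: float) -> float:
    """Signed circular report error in (-180, 180]."""
    if not np.isfinite(presented):
        raise UndefinedTiltError("tilt error undefined on frontoparallel trials")
    return float(wrap_diff(reported, presented))


@dataclass
class ErrorDistribution:
    """Counts of tilt report errors over the eight 45-deg bins."""

    counts: np.ndarray                      # length 8, order ERROR_BINS
    condition: tuple | None = None          # (slant, distance) or None = pooled

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (8,) or (self.counts < 0).any():
            raise ValueError("counts must be 8 nonnegative integers")

    @property
    def n_trials(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_errors(cls, errors, condition=None) -> "ErrorDistribution":
        e = wrap_diff(np.asarray(errors, dtype=float))
        idx = np.searchsorted(ERROR_BINS, np.round(e / 45.0) * 45.0)
        counts = np.bincount(idx, minlength=8)
        return cls(counts, condition)


@dataclass
class SensitivityFit:
    mu: float
    kappa: float
    loglik: float
    converged: bool
    capped: bool = False          # kappa pinned at the 18 upper bound
    mu_identifiable: bool = True


def discretized_vm_probs(mu: float, kappa: float) -> np.ndarray:
    """Von Mises density at the 8 error-bin centers, renormalized to sum 1."""
    w = kappa * (np.cos(np.deg2rad(ERROR_BINS - mu)) - 1.0)
    p = np.exp(w - w.max())
    return p / p.sum()


def _negloglik(params, counts):
    mu, kappa = params
    p = discretized_vm_probs(mu, kappa)
    return -float(np.sum(counts * np.log(np.maximum(p, 1e-300))))


def fit_sensitivity(dist: ErrorDistribution, n_floor: int = 8,
                    method: str = "mle") -> SensitivityFit:
    """Maximum-likelihood (mu, kappa) of the discretized von Mises model.

    ``method='lsq'`` instead minimizes squared error between observed bin
    proportions and model probabilities (sensitivity-analysis mode).
    """
    counts = dist.counts
    n = dist.n_trials
    if n < n_floor:
        raise ValueError(f"need at least {n_floor} trials, got {n}")
    if (counts > 0).sum() == 1 and n < 2 * n_floor and counts[3] != n:
        raise ValueError("all mass in a single off-center bin with too few trials")

    if method == "lsq":
        obs = counts / n

        def obj(params):
            return float(np.sum((discretized_vm_probs(*params) - obs) ** 2))
    else:
        def obj(params):
            return _negloglik(params, counts)

    best = None
    for mu0 in (0.0, 45.0, -45.0, 90.0, -90.0, 135.0, -135.0, 180.0):
        res = optimize.minimize(
            obj, x0=[mu0, 2.0], method="L-BFGS-B",
            bounds=[(-180.0, 180.0), (1e-6, KAPPA_MAX)])
        if best is None or res.fun < best.fun:
            best = res
    mu = float(wrap_diff(best.x[0]))
    kappa = float(best.x[1])
    capped = kappa >= KAPPA_MAX - 1e-6
    mu_ident = kappa > 1e-3
    return SensitivityFit(mu=mu if mu_ident else float("nan"), kappa=kappa,
                          loglik=-float(best.fun) if method == "mle" else float("nan"),
                          converged=bool(best.success), capped=capped,
                          mu_identifiable=mu_ident)


def sensitivity_map(trials: pd.DataFrame, n_floor: int = 8) -> pd.DataFrame:
    """Per-session von Mises sensitivity per (slant, distance), pooled over
    tilts, plus across-session mean and SEM per cell.

    ``trials`` needs columns: session, tilt, slant, distance_cm, choice.
    Frontoparallel trials (slant 0) are skipped (tilt error undefined).
    Returns one row per (session, slant, distance) with mu, kappa, n,
    capped flag; cells with too few trials yield NaN kappa.
    """
    req = {"session", "tilt", "slant", "distance_cm", "choice"}
    if not req.issubset(trials.columns):
        raise ValueError(f"trials missing columns {req - set(trials.columns)}")
    rows = []
    slanted = trials[trials["slant"] > 0]
    for (sess, slant, dist), g in slanted.groupby(["session", "slant", "distance_cm"]):
        errors = wrap_diff(g["choice"].to_numpy(), g["tilt"].to_numpy())
        try:
            fit = fit_sensitivity(
                ErrorDistribution.from_errors(errors, (slant, dist)),
                n_floor=n_floor)
            rows.append((sess, slant, dist, fit.mu, fit.kappa, len(g), fit.capped))
        except ValueError:
            rows.append((sess, slant, dist, np.nan, np.nan, len(g), False))
    out = pd.DataFrame(rows, columns=["session", "slant", "distance_cm", "mu",
                                      "kappa", "n", "capped"])
    n_sessions = out["session"].nunique()
    summ = out.groupby(["slant", "distance_cm"])["kappa"].agg(["mean", "sem"])
    summ = summ.rename(columns={"mean": "kappa_mean", "sem": "kappa_sem"}).reset_index()
    if n_sessions < 2:
        summ["kappa_sem"] = np.nan
    out.attrs["summary"] = summ
    return out


def linearize_tilt(trials: pd.DataFrame) -> pd.DataFrame:
    """Add cos/sin tilt regressors for linear-model tests of tilt effects
    (tilt is circular, so it enters ANOVA-style models via its components)."""
    out = trials.copy()
    t = np.deg2rad(out["tilt"].to_numpy(dtype=float))
    out["tilt_cos"] = np.cos(t)
    out["tilt_sin"] = np.sin(t)
    return out
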