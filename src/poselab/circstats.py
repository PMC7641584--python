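"""Minimal circular statistics used across the package.

Angles are in degrees throughout, matching the task's tilt/choice/saccade
conventions.  Differences live on (-180, 180].
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def wrap_diff(a, b=0.0):
    """Signed circular difference a - b mapped to (-180, 180]."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.where(d > 180.0, d - 360.0, d)


def circ_mean(angles_deg, axis=None):
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    m = np.angle(np.exp(1j * a).mean(axis=axis))
    return np.rad2deg(m)


def circ_r(angles_deg, axis=None):
    """Mean resultant length in [0, 1]."""
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    return np.abs(np.exp(1j * a).mean(axis=axis))


def circ_var(angles_deg, axis=None):
    """Circular variance 1 - R in [0, 1]."""
    return 1.0 - circ_r(angles_deg, axis=axis)


def circ_median(angles_deg) -> float:
    """Circular median: the direction minimizing mean absolute angular
    deviation; ties broken toward the circular mean."""
    a = np.asarray(angles_deg, dtype=float) % 360.0
    cands = np.concatenate([a, (a + 180.0) % 360.0])
    dev = np.abs(wrap_diff(a[None, :], cands[:, None])).mean(axis=1)
    best = cands[np.isclose(dev, dev.min())]
    if len(best) == 1:
        m = best[0]
    else:
        mu = circ_mean(a)
        m = best[np.argmin(np.abs(wrap_diff(best, mu)))]
    return float(wrap_diff(m))


def circ_median_test(angles_deg, md: float = 0.0) -> float:
    """Test whether the population circular median equals ``md``.

    Sign-test form: under H0 the probability that an angle falls in the
    half-circle clockwise of ``md`` is 1/2.  Angles exactly on the diameter
    through ``md`` are dropped.  Returns the two-sided p-value.
    """
    d = wrap_diff(np.asarray(angles_deg, dtype=float), md)
    d = d[(np.abs(d) > 1e-9) & (np.abs(np.abs(d) - 180.0) > 1e-9)]
    n = len(d)
    if n == 0:
        return 1.0
    k = int(np.sum(d > 0))
    return float(stats.binomtest(k, n, 0.5).pvalue)


def concentration_difference_test(angles_a, angles_b):
    """Two-sample test for a difference in angular concentration.

    Wallraff's nonparametric procedure: angular deviations of each sample
    from its own circular median are compared with a two-sided
    Mann-Whitney U test.  Returns (statistic, p-value).
    """
    a = np.asarray(angles_a, dtype=float)
    b = np.asarray(angles_b, dtype=float)
    da = np.abs(wrap_diff(a, circ_median(a)))
    db = np.abs(wrap_diff(b, circ_median(b)))
    res = stats.mannwhitneyu(da, db, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def von_mises_pdf(theta_deg, mu_deg, kappa):
    """Von Mises density over angle in degrees (normalized over radians)."""
    from scipy.special import i0e
    t = np.deg2rad(np.asarray(theta_deg, dtype=float) - mu_deg)
    # i0e avoids overflow at large kappa: exp(k cos - k) / (2 pi i0e(k))
    return np.exp(kappa * (np.cos(t) - 1.0)) / (2.0 * np.pi * i0e(kappa))
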