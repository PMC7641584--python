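"""Separable orientation x distance tuning model and the Tolerance index.

The multiplicatively separable model of a 33 x 4 (orientations x distances)
response matrix is

    R(theta, D) = DC + g * H(theta) * F(D),

with DC an offset, g the gain (first singular value), and H, F unit-norm
orientation and distance profiles (first singular-vector pair of R - DC).
Fitting minimizes the Euclidean (Frobenius) error norm: for fixed DC the
optimal g, H, F are the truncated rank-1 SVD, and DC itself is found by a
bounded 1-D search.  The Tolerance index is the mean Pearson correlation
between the observed and model orientation tuning curves at each distance:
near 1, the orientation tuning shape is tolerant to distance; near 0 it
changes substantially with distance (as for low-level feature selectivity).

The additively separable alternative R = DC + H(theta) + F(D) is a ridge-
regularized linear system with sum-to-zero effect constraints and one more
effective free parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class DegenerateMatrixError(ValueError):
    """Raised when a tuning matrix has no variance to fit."""


@dataclass
class SeparableFit:
    dc: float
    gain: float
    h: np.ndarray             # unit-norm orientation profile (33,)
    f: np.ndarray             # unit-norm distance profile (4,)
    tolerance: float
    residual_norm: float
    n_excluded_distances: int = 0

    def predict(self) -> np.ndarray:
        return self.dc + self.gain * np.outer(self.h, self.f)


@dataclass
class AdditiveFit:
    dc: float
    h_add: np.ndarray
    f_add: np.ndarray
    ridge: float
    residual_norm: float

    def predict(self) -> np.ndarray:
        return self.dc + self.h_add[:, None] + self.f_add[None, :]


def _rank1(resid: np.ndarray):
    """Best rank-1 approximation (gain, h, f) of a matrix, gauge-fixed:
    unit-norm h and f, gain >= 0, and f nonnegative at its largest-magnitude
    entry."""
    U, s, Vt = np.linalg.svd(resid, full_matrices=False)
    g = float(s[0])
    h = U[:, 0]
    f = Vt[0, :]
    k = int(np.argmax(np.abs(f)))
    if f[k] < 0:
        f = -f
        h = -h
    return g, h, f


def _objective(dc: float, means: np.ndarray) -> float:
    g, h, f = _rank1(means - dc)
    return float(np.linalg.norm(means - dc - g * np.outer(h, f)))


def fit_separable(means: np.ndarray, window: tuple | None = None,
                  dc_tol: float = 1e-8) -> SeparableFit:
    """Fit R = DC + g H(theta) F(D) by SVD inside a bounded search over DC.

    DC is searched on [0, max(means)] with a bounded scalar minimizer
    (the rank-1 residual objective is well behaved in DC); the inner step
    is the truncated SVD of means - DC.
    """
    from scipy import optimize

    M = np.asarray(means, dtype=float)
    if np.isnan(M).any():
        raise ValueError("tuning matrix contains missing cells")
    if np.allclose(M, M.flat[0]):
        raise DegenerateMatrixError("zero-variance matrix: neuron untuned")
    hi = float(M.max())
    # the objective can be multimodal in DC: locate the basin on a coarse
    # grid, then refine with a bounded scalar search inside it
    grid = np.linspace(0.0, hi, 101)
    objs = np.array([_objective(d, M) for d in grid])
    k = int(np.argmin(objs))
    lo_b = grid[max(k - 1, 0)]
    hi_b = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(_objective, args=(M,), bounds=(lo_b, hi_b),
                                   method="bounded",
                                   options={"xatol": dc_tol})
    dc = float(res.x)
    if objs[0] <= res.fun:          # boundary DC = 0
        dc = 0.0
    g, h, f = _rank1(M - dc)
    pred = dc + g * np.outer(h, f)
    fit = SeparableFit(dc=dc, gain=g, h=h, f=f, tolerance=np.nan,
                       residual_norm=float(np.linalg.norm(M - pred)))
    fit.tolerance, fit.n_excluded_distances = tolerance_index(M, fit)
    return fit


def tolerance_index(means: np.ndarray, fit: SeparableFit,
                    against_h: bool = False) -> tuple[float, int]:
    """Mean per-distance Pearson r between observed and model orientation
    tuning curves.  Distances where either the observed column or the model
    column has zero variance (e.g. F(D) = 0) are excluded and counted.

    ``against_h=True`` correlates against the H profile directly instead of
    the per-distance prediction (identical except sign when F(D) < 0).
    """
    M = np.asarray(means, dtype=float)
    pred = fit.predict()
    rs = []
    excluded = 0
    for j in range(M.shape[1]):
        target = fit.h if against_h else pred[:, j]
        if np.std(M[:, j]) == 0 or np.std(target) == 0:
            excluded += 1
            continue
        rs.append(float(np.corrcoef(M[:, j], target)[0, 1]))
    if not rs:
        raise DegenerateMatrixError("all distances degenerate")
    return float(np.mean(rs)), excluded


def fit_additive(means: np.ndarray, ridge_grid=None) -> AdditiveFit:
    """Fit R = DC + H(theta) + F(D) with sum-to-zero effects and a ridge
    weight chosen to minimize the Euclidean error norm over a log grid."""
    M = np.asarray(means, dtype=float)
    n_o, n_d = M.shape
    if ridge_grid is None:
        ridge_grid = np.concatenate([[0.0], np.logspace(-6, 2, 9)])
    # design: intercept + orientation effects (drop last, sum-to-zero) +
    # distance effects (drop last, sum-to-zero)
    rows = []
    y = []
    for i in range(n_o):
        for j in range(n_d):
            x = np.zeros(1 + (n_o - 1) + (n_d - 1))
            x[0] = 1.0
            if i < n_o - 1:
                x[1 + i] = 1.0
            else:
                x[1:n_o] = -1.0
            if j < n_d - 1:
                x[n_o + j] = 1.0
            else:
                x[n_o:] = -1.0
            rows.append(x)
            y.append(M[i, j])
    X = np.array(rows)
    y = np.array(y)
    best = None
    for lam in ridge_grid:
        A = X.T @ X + lam * np.eye(X.shape[1])
        beta = np.linalg.solve(A, X.T @ y)
        resid = float(np.linalg.norm(y - X @ beta))
        if best is None or resid < best[0]:
            best = (resid, lam, beta)
    resid, lam, beta = best
    dc = float(beta[0])
    h = np.append(beta[1:n_o], -beta[1:n_o].sum())
    f = np.append(beta[n_o:], -beta[n_o:].sum())
    return AdditiveFit(dc=dc, h_add=h, f_add=f, ridge=float(lam),
                       residual_norm=resid)


@dataclass
class ModelComparison:
    winner: str               # "multiplicative" | "additive" | "tie"
    residual_mult: float
    residual_add: float
    p_value: float


def compare_models(means: np.ndarray, sep: SeparableFit, add: AdditiveFit,
                   n_permutations: int = 10_000, seed: int = 0
                   ) -> ModelComparison:
    """Compare the two models on identical data.

    Winner by residual norm; significance from a cell-wise paired sign-flip
    permutation test on the difference of squared residuals.
    """
    M = np.asarray(means, dtype=float)
    e_mult = (M - sep.predict()).ravel() ** 2
    e_add = (M - add.predict()).ravel() ** 2
    d = e_add - e_mult                  # > 0 where multiplicative is better
    obs = float(d.mean())
    if np.allclose(d, 0.0):
        return ModelComparison("tie", sep.residual_norm, add.residual_norm, 1.0)
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, len(d)))
    null = (signs * d).mean(axis=1)
    p = float((np.abs(null) >= abs(obs)).mean())
    winner = "multiplicative" if sep.residual_norm < add.residual_norm else (
        "additive" if add.residual_norm < sep.residual_norm else "tie")
    return ModelComparison(winner, sep.residual_norm, add.residual_norm, p)
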