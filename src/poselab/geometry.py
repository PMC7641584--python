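"""Spherical geometry of 3D orientation preferences.

A plane's orientation (tilt T, slant S) maps to its unit surface normal

    n = (cos T sin S, sin T sin S, cos S),

so slant is the polar angle from the line of sight and tilt the azimuth.
The clustering of a neuron's per-distance preferred orientations is
summarized by the principal orientation (leading eigenvector of the normals'
second-moment matrix); rotating all normals so the principal orientation
sits at the north pole yields a standardized frame in which deviations are
read off as a direction (delta_psi) and an angle (delta_angle, 0-90 deg).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circstats import wrap_diff


def pose_to_normal(tilt_deg: float, slant_deg: float) -> np.ndarray:
    """Unit normal of a plane at (tilt, slant); frontoparallel maps to the
    pole (0, 0, 1) whether or not the nominal tilt is defined."""
    s = np.deg2rad(slant_deg)
    if slant_deg < 0 or slant_deg > 90:
        raise ValueError(f"slant {slant_deg} outside [0, 90]")
    if slant_deg == 0 or not np.isfinite(tilt_deg):
        if slant_deg != 0 and not np.isfinite(tilt_deg):
            raise ValueError("tilt undefined for slanted pose")
        return np.array([0.0, 0.0, 1.0])
    t = np.deg2rad(tilt_deg)
    return np.array([np.cos(t) * np.sin(s), np.sin(t) * np.sin(s), np.cos(s)])


def normal_to_pose(n: np.ndarray) -> tuple[float, float]:
    """Inverse map: unit normal -> (tilt, slant) in degrees; tilt is NaN at
    the pole."""
    n = np.asarray(n, dtype=float)
    slant = float(np.rad2deg(np.arccos(np.clip(n[2], -1.0, 1.0))))
    if slant < 1e-9:
        return (float("nan"), 0.0)
    tilt = float(np.rad2deg(np.arctan2(n[1], n[0])) % 360.0)
    return (tilt, slant)


@dataclass
class PrincipalOrientation:
    tp: float          # tilt of principal orientation, degrees
    sp: float          # slant of principal orientation, degrees
    eigenvalue_gap: float
    n_preferences: int
    degenerate: bool = False

    @property
    def normal(self) -> np.ndarray:
        if np.isnan(self.tp):
            return np.array([0.0, 0.0, 1.0])
        return pose_to_normal(self.tp, self.sp)


def principal_orientation(normals) -> PrincipalOrientation:
    """Leading eigenvector of the second-moment (scatter) matrix sum n n^T.

    The sign is fixed so z >= 0 (all slants are <= 90 deg, so preferences
    live in the upper hemisphere); if z ~ 0 the sign is fixed by x >= 0.
    Tied leading eigenvalues are flagged degenerate with a deterministic
    tie-break (smallest eigen-index).
    """
    N = np.atleast_2d(np.asarray(normals, dtype=float))
    if N.shape[0] < 1:
        raise ValueError("need at least one normal")
    S = N.T @ N
    w, V = np.linalg.eigh(S)          # ascending
    v = V[:, -1]
    gap = float(w[-1] - w[-2]) if len(w) > 1 else float(w[-1])
    degenerate = bool(np.isclose(w[-1], w[-2], rtol=1e-9, atol=1e-12))
    if v[2] < 0 or (abs(v[2]) < 1e-12 and v[0] < 0):
        v = -v
    tilt, slant = normal_to_pose(v / np.linalg.norm(v))
    return PrincipalOrientation(tp=tilt, sp=slant, eigenvalue_gap=gap,
                                n_preferences=N.shape[0], degenerate=degenerate)


def _rot_tilt(tp_deg: float) -> np.ndarray:
    t = np.deg2rad(tp_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_slant(sp_deg: float) -> np.ndarray:
    s = np.deg2rad(sp_deg)
    c, sn = np.cos(s), np.sin(s)
    return np.array([[c, 0.0, sn], [0.0, 1.0, 0.0], [-sn, 0.0, c]])


def pole_rotation(principal: PrincipalOrientation) -> np.ndarray:
    """Composite rotation taking the principal normal to the north pole
    while preserving all pairwise angles."""
    tp = 0.0 if np.isnan(principal.tp) else principal.tp
    sp = principal.sp
    return _rot_tilt(tp) @ _rot_slant(-sp) @ _rot_tilt(-tp)


def rotate_to_pole(normals, principal: PrincipalOrientation) -> np.ndarray:
    """Rotate normals into the pole-aligned frame of ``principal``."""
    R = pole_rotation(principal)
    N = np.atleast_2d(np.asarray(normals, dtype=float))
    return N @ R.T


@dataclass
class Deviation:
    delta_psi: float    # direction of deviation, degrees in (-180, 180]
    delta_angle: float  # angular deviation from the pole, degrees in [0, 90]


def deviations(rotated_normals) -> list[Deviation]:
    """Per-normal deviation from the pole in the standardized frame."""
    N = np.atleast_2d(np.asarray(rotated_normals, dtype=float))
    out = []
    for n in N:
        ang = float(np.rad2deg(np.arccos(np.clip(n[2], -1.0, 1.0))))
        psi = float(wrap_diff(np.rad2deg(np.arctan2(n[1], n[0])))) if ang > 1e-9 else 0.0
        out.append(Deviation(delta_psi=psi, delta_angle=ang))
    return out


def deviation_cdf(delta_angles, grid=None):
    """Empirical CDF of angular deviations on a fixed degree grid."""
    d = np.sort(np.asarray(delta_angles, dtype=float))
    if grid is None:
        grid = np.linspace(0.0, 90.0, 181)
    cdf = np.searchsorted(d, grid, side="right") / max(len(d), 1)
    return grid, cdf


def equal_area_project(normal) -> np.ndarray:
    """Lambert azimuthal equal-area projection about the north pole.

    The pole maps to the origin; a point on the equator maps to radius
    sqrt(2) (unit-sphere convention).  Lower-hemisphere input is reflected
    through the equator first (flagged by the caller if it matters).
    """
    n = np.asarray(normal, dtype=float)
    z = n[..., 2]
    n = np.where(z[..., None] < 0, n * np.array([1.0, 1.0, -1.0]), n)
    z = np.abs(z)
    r = np.sqrt(np.clip(2.0 * (1.0 - z), 0.0, 4.0))
    az = np.arctan2(n[..., 1], n[..., 0])
    return np.stack([r * np.cos(az), r * np.sin(az)], axis=-1)
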