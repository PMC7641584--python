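"""Task design: the surface-pose stimulus grid, block structure, and reward rule.

The discrimination task shows a planar surface at a combination of tilt
(direction the plane is oriented in depth, 0-360 deg), slant (amount of depth
variation, 0-90 deg), and viewing distance, and the subject reports the
nearest side of the plane by a saccade to one of eight targets on a 45 deg
polar grid.  A frontoparallel plane (slant 0) has no depth variation, so its
tilt is undefined and any report is rewarded with probability 1/8.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel tilt value for frontoparallel poses (slant = 0, tilt undefined).
FRONTOPARALLEL_TILT = float("nan")

CHOICE_DIRECTIONS = tuple(float(a) for a in range(0, 360, 45))


class InvalidDesignError(ValueError):
    """Raised when a stimulus grid violates the task's domain bounds."""


class InvalidChoiceError(ValueError):
    """Raised when a report direction is not on the 45 deg choice grid."""


@dataclass(frozen=True)
class SurfacePose:
    """One stimulus condition: tilt and slant of a plane plus its distance.

    ``tilt`` is stored modulo 360 and is NaN (undefined) whenever
    ``slant == 0``: two frontoparallel poses at the same distance compare
    equal regardless of the nominal tilt they were constructed with.
    """

    tilt: float
    slant: float
    distance: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.slant <= 90.0):
            raise InvalidDesignError(f"slant {self.slant} outside [0, 90]")
        if self.distance <= 0:
            raise InvalidDesignError(f"distance {self.distance} must be positive")
        if self.slant == 0.0:
            object.__setattr__(self, "tilt", FRONTOPARALLEL_TILT)
        else:
            if not np.isfinite(self.tilt):
                raise InvalidDesignError("tilt undefined for slanted pose")
            object.__setattr__(self, "tilt", float(self.tilt) % 360.0)

    @property
    def frontoparallel(self) -> bool:
        return self.slant == 0.0

    def __eq__(self, other) -> bool:
        if not isinstance(other, SurfacePose):
            return NotImplemented
        if self.slant != other.slant or self.distance != other.distance:
            return False
        if self.frontoparallel:
            return True
        return self.tilt == other.tilt

    def __hash__(self) -> int:
        tilt_key = -1.0 if self.frontoparallel else self.tilt
        return hash((tilt_key, self.slant, self.distance))


@dataclass(frozen=True)
class DesignGrid:
    """The stimulus grid: tilts x slants x distances, plus fixation distance."""

    tilts: tuple = tuple(float(a) for a in range(0, 360, 45))
    slants: tuple = (0.0, 15.0, 30.0, 45.0, 60.0)
    distances: tuple = (37.0, 57.0, 97.0, 137.0)
    fixation_distance: float = 57.0

    def __post_init__(self) -> None:
        for name, vals, lo, hi in (
            ("tilts", self.tilts, 0.0, 360.0),
            ("slants", self.slants, 0.0, 90.0),
        ):
            if len(vals) == 0:
                raise InvalidDesignError(f"{name} empty")
            if list(vals) != sorted(vals):
                raise InvalidDesignError(f"{name} must be sorted")
            if any(v < lo or v >= hi + (1e-9 if name == "slants" else 0.0) for v in vals):
                if name == "tilts" and any(v < 0 or v >= 360 for v in vals):
                    raise InvalidDesignError("tilt outside [0, 360)")
                if name == "slants" and any(v < 0 or v > 90 for v in vals):
                    raise InvalidDesignError("slant outside [0, 90]")
        if len(self.distances) == 0:
            raise InvalidDesignError("distances empty")

    @property
    def n_unique_orientations(self) -> int:
        nonzero = sum(1 for s in self.slants if s > 0)
        has_zero = any(s == 0 for s in self.slants)
        return len(self.tilts) * nonzero + (1 if has_zero else 0)


def build_pose_grid(grid: DesignGrid) -> list[SurfacePose]:
    """Enumerate every unique pose: orientations crossed with distances.

    Frontoparallel appears once per distance.  Ordering is slant-major, then
    tilt, then distance, and is deterministic.
    """
    poses: list[SurfacePose] = []
    for slant in grid.slants:
        if slant == 0.0:
            for d in grid.distances:
                poses.append(SurfacePose(FRONTOPARALLEL_TILT, 0.0, d))
        else:
            for tilt in grid.tilts:
                for d in grid.distances:
                    poses.append(SurfacePose(tilt, slant, d))
    return poses


def orientation_index(grid: DesignGrid) -> list[tuple[float, float]]:
    """Deterministic (tilt, slant) order of the unique orientations.

    The frontoparallel orientation is listed first (tilt NaN), then slanted
    orientations slant-major, tilt-minor.  This ordering defines the row
    order of every orientations-by-distances tuning matrix in the package.
    """
    out: list[tuple[float, float]] = []
    for slant in grid.slants:
        if slant == 0.0:
            out.append((FRONTOPARALLEL_TILT, 0.0))
        else:
            out.extend((tilt, slant) for tilt in grid.tilts)
    return out


@dataclass
class BlockPlan:
    """One block of trials in seeded pseudorandom order."""

    plane_trials: pd.DataFrame
    saccade_trials: pd.DataFrame
    rng_seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([self.plane_trials, self.saccade_trials], ignore_index=True)


def build_block(grid: DesignGrid, seed: int, n_fp_repeats: int = 8,
                n_saccade_repeats: int = 4) -> BlockPlan:
    """Build one block: every slanted pose once + frontoparallel repeats,
    per distance, plus saccade trials, each list shuffled with ``seed``.

    For the default grid this yields (8 tilts x 4 slants + 8 frontoparallel)
    x 4 distances = 160 plane trials and 8 directions x 4 repeats = 32
    saccade trials.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for d in grid.distances:
        for slant in grid.slants:
            if slant == 0.0:
                for _ in range(n_fp_repeats):
                    rows.append(("plane", np.nan, 0.0, d, np.nan))
            else:
                for tilt in grid.tilts:
                    rows.append(("plane", tilt, slant, d, np.nan))
    plane = pd.DataFrame(rows, columns=["kind", "tilt", "slant", "distance_cm",
                                        "saccade_dir"])
    plane = plane.iloc[rng.permutation(len(plane))].reset_index(drop=True)

    srows = [("saccade", np.nan, np.nan, np.nan, float(d))
             for d in CHOICE_DIRECTIONS for _ in range(n_saccade_repeats)]
    sacc = pd.DataFrame(srows, columns=plane.columns)
    sacc = sacc.iloc[rng.permutation(len(sacc))].reset_index(drop=True)

    plane.insert(0, "trial_id", np.arange(len(plane)))
    sacc.insert(0, "trial_id", np.arange(len(plane), len(plane) + len(sacc)))
    return BlockPlan(plane, sacc, rng_seed=seed)


def reward_rule(pose: SurfacePose, choice: float) -> float:
    """Reward probability for a report.

    Slanted poses pay 1 for the correct tilt and 0 otherwise; frontoparallel
    poses are tilt-ambiguous and pay with probability 1/8 for any report.
    """
    if float(choice) % 360.0 not in CHOICE_DIRECTIONS:
        raise InvalidChoiceError(f"choice {choice} not on the 45 deg grid")
    if pose.frontoparallel:
        return 0.125
    return 1.0 if float(choice) % 360.0 == pose.tilt else 0.0


def grid_to_json(grid: DesignGrid) -> str:
    return json.dumps({
        "tilts": list(grid.tilts), "slants": list(grid.slants),
        "distances": list(grid.distances),
        "fixation_distance": grid.fixation_distance,
    })


def grid_from_json(text: str) -> DesignGrid:
    d = json.loads(text)
    return DesignGrid(tuple(d["tilts"]), tuple(d["slants"]),
                      tuple(d["distances"]), d["fixation_distance"])
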