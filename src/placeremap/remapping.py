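"""Place-field stability across light/dark/light sessions.

Two statistics quantify how far a unit's place field moves when visual input
is removed and whether it returns afterwards:

* the L1DL2 angle — the angle at the dark-session field centroid (D) between
  the vectors pointing to the two light-session centroids,
  ``arccos( (D->L1 . D->L2) / (|D->L1| |D->L2|) )`` in degrees.  A large
  angle means the two light fields sit on the same side of D close together
  relative to the dark displacement (little net remap); a small angle with a
  large |D - L1| means a genuine dark shift away and back.
* pairwise Euclidean distances between the three centroids (L1-D, L1-L2,
  D-L2) in cm.

A unit whose dark centroid coincides with a light centroid has no defined
angle; such units are reported as "no remap" rather than forced to a number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import InputError, UndefinedMetricError

__all__ = [
    "ComTriplet",
    "RemapResult",
    "RemapSummary",
    "l1dl2_angle",
    "com_distance",
    "remap_summary",
]

Point = tuple[float, float]


@dataclass(frozen=True)
class ComTriplet:
    """Field centre of mass in each of the three sessions, for one unit."""

    unit_id: str
    com_l1: Point
    com_d: Point
    com_l2: Point


@dataclass(frozen=True)
class RemapResult:
    """Per-unit remapping geometry; ``angle`` is None when D coincides with a
    light centroid (no defined angle)."""

    unit_id: str
    angle: float | None
    d_l1d: float
    d_l1l2: float
    d_dl2: float


@dataclass(frozen=True)
class RemapSummary:
    per_unit: tuple[RemapResult, ...]
    excluded: tuple[tuple[str, str], ...]  # (unit_id, reason)
    mean_angle: float | None
    sem_angle: float | None
    mean_d_l1d: float
    sem_d_l1d: float | None
    mean_d_l1l2: float
    sem_d_l1l2: float | None
    mean_d_dl2: float
    sem_d_dl2: float | None
    n: int


def com_distance(a: Point, b: Point) -> float:
    """Euclidean distance (cm) between two field centroids."""
    if not all(math.isfinite(v) for v in (*a, *b)):
        raise InputError("centroid coordinates must be finite")
    return math.hypot(b[0] - a[0], b[1] - a[1])


def l1dl2_angle(com_l1: Point, com_d: Point, com_l2: Point) -> float:
    """Angle (degrees) at the dark centroid between D->L1 and D->L2.

    The cosine is clamped to [-1, 1] to absorb floating error in the
    collinear cases; the result lies in [0, 180] and is symmetric under
    swapping the two light centroids.
    """
    v1 = np.asarray(com_l1, dtype=float) - np.asarray(com_d, dtype=float)
    v2 = np.asarray(com_l2, dtype=float) - np.asarray(com_d, dtype=float)
    n1 = float(np.hypot(*v1))
    n2 = float(np.hypot(*v2))
    if n1 == 0.0 or n2 == 0.0:
        raise UndefinedMetricError(
            "dark centroid coincides with a light centroid; angle undefined"
        )
    cosang = float(np.dot(v1, v2) / (n1 * n2))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def _mean_sem(values: list[float]) -> tuple[float | None, float | None]:
    if not values:
        return None, None
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else None
    return mean, sem


def remap_summary(triplets: list[ComTriplet]) -> RemapSummary:
    """Per-unit remapping geometry plus cohort mean ± SEM.

    Units whose dark centroid coincides exactly with a light centroid
    contribute their distances but are excluded from the angle aggregate
    (reported in ``excluded`` with reason ``"no remap"``).
    """
    if not triplets:
        raise InputError("remap_summary needs at least one COM triplet")

    per_unit: list[RemapResult] = []
    excluded: list[tuple[str, str]] = []
    angles: list[float] = []
    for trip in triplets:
        d_l1d = com_distance(trip.com_l1, trip.com_d)
        d_l1l2 = com_distance(trip.com_l1, trip.com_l2)
        d_dl2 = com_distance(trip.com_d, trip.com_l2)
        try:
            angle = l1dl2_angle(trip.com_l1, trip.com_d, trip.com_l2)
            angles.append(angle)
        except UndefinedMetricError:
            angle = None
            excluded.append((trip.unit_id, "no remap"))
        per_unit.append(RemapResult(trip.unit_id, angle, d_l1d, d_l1l2, d_dl2))

    mean_angle, sem_angle = _mean_sem(angles)
    mean_d_l1d, sem_d_l1d = _mean_sem([r.d_l1d for r in per_unit])
    mean_d_l1l2, sem_d_l1l2 = _mean_sem([r.d_l1l2 for r in per_unit])
    mean_d_dl2, sem_d_dl2 = _mean_sem([r.d_dl2 for r in per_unit])
    return RemapSummary(
        per_unit=tuple(per_unit),
        excluded=tuple(excluded),
        mean_angle=mean_angle,
        sem_angle=sem_angle,
        mean_d_l1d=mean_d_l1d,
        sem_d_l1d=sem_d_l1d,
        mean_d_l1l2=mean_d_l1l2,
        sem_d_l1l2=sem_d_l1l2,
        mean_d_dl2=mean_d_dl2,
        sem_d_dl2=sem_d_dl2,
        n=len(per_unit),
    )
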