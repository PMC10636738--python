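"""Active-site water occupancy.

Counts water oxygens inside a probe sphere whose center is recomputed per
frame as the midpoint between the anomeric carbon (C1) and the centroid
of the general acid/base carboxylate group, and reports the fraction of
frames with at least one water inside (the occupancy that gates the
hydrolytic second step).  The sphere is a closed ball (a water exactly at
the radius counts), radius 2 Å by default.

An optional dual-distance mode instead requires a water within the radius
of both anchors simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ProbeSphere", "OccupancyResult", "count_waters_in_sphere", "occupancy_fraction"]

#: residue-name dialects commonly used for water
WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "SOL"})


@dataclass(frozen=True)
class ProbeSphere:
    """Probe sphere anchored to the active site.

    ``c1_index`` is the anomeric carbon; ``carboxylate_indices`` the
    atoms of the acid/base carboxylate group (centroid taken over the
    two oxygens and the carboxyl carbon by default — configurable by
    simply passing other indices).
    """

    c1_index: int
    carboxylate_indices: tuple[int, ...]
    radius: float = 2.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("probe radius must be positive")
        if len(self.carboxylate_indices) == 0:
            raise ValueError("carboxylate group needs at least one atom")
        object.__setattr__(
            self, "carboxylate_indices", tuple(int(i) for i in self.carboxylate_indices)
        )

    def center(self, frame: np.ndarray) -> np.ndarray:
        frame = np.asarray(frame, dtype=float)
        c1 = frame[self.c1_index]
        carb = frame[list(self.carboxylate_indices)].mean(axis=0)
        return 0.5 * (c1 + carb)


@dataclass(frozen=True)
class OccupancyResult:
    counts: np.ndarray  # per-frame water counts
    fraction: float  # frames with count >= 1 / total frames
    histogram: dict[int, int] = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return int(self.counts.size)


def count_waters_in_sphere(
    frame: np.ndarray,
    sphere: ProbeSphere,
    water_oxygen_indices,
    dual_distance: bool = False,
) -> int:
    """Water oxygens within the probe sphere of one frame (closed ball).

    With ``dual_distance=True`` a water counts when it is within the
    radius of both the C1 atom and the carboxylate centroid, rather than
    of the single midpoint-centered sphere.
    """
    frame = np.asarray(frame, dtype=float)
    widx = np.asarray(list(water_oxygen_indices), dtype=int)
    if widx.size == 0:
        return 0
    waters = frame[widx]
    if dual_distance:
        c1 = frame[sphere.c1_index]
        carb = frame[list(sphere.carboxylate_indices)].mean(axis=0)
        ok = (np.linalg.norm(waters - c1, axis=1) <= sphere.radius) & (
            np.linalg.norm(waters - carb, axis=1) <= sphere.radius
        )
    else:
        center = sphere.center(frame)
        ok = np.linalg.norm(waters - center, axis=1) <= sphere.radius
    return int(np.count_nonzero(ok))


def occupancy_fraction(
    trajectory,
    sphere: ProbeSphere,
    water_oxygen_indices,
    dual_distance: bool = False,
) -> OccupancyResult:
    """Occupancy statistics over a trajectory of frames.

    Fraction of frames with at least one water in the sphere, plus the
    full count histogram (which sums to the number of frames).
    """
    counts = []
    for frame in trajectory:
        counts.append(
            count_waters_in_sphere(frame, sphere, water_oxygen_indices, dual_distance)
        )
    if not counts:
        raise ValueError("no valid frames: occupancy undefined")
    counts = np.asarray(counts, dtype=int)
    values, freqs = np.unique(counts, return_counts=True)
    return OccupancyResult(
        counts=counts,
        fraction=float(np.mean(counts >= 1)),
        histogram={int(v): int(f) for v, f in zip(values, freqs)},
    )
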