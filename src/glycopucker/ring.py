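"""Cremer–Pople puckering coordinates for six-membered rings.

The out-of-plane deformation of a six-membered ring is described by three
generalized coordinates: a total puckering amplitude ``Q`` (Å) and two
angles ``(theta, phi)`` locating the conformation on a sphere whose poles
are the two chair forms.  Intermediate quantities are the two puckering
amplitudes ``q2`` (degenerate pair, with phase ``phi2``) and ``q3``
(alternating mode), with ``Q**2 == q2**2 + q3**2``.

Ring atoms are taken in the order j = 1..6 = O5, C1, C2, C3, C4, C5 — the
standard carbohydrate convention, which puts the 4C1 chair of a
beta-D-pyranose at the north pole (theta = 0).

All angles crossing this module's boundary are degrees; distances are Å.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "RingAtomSet",
    "PuckerCoordinates",
    "RingGeometryError",
    "DEFAULT_RING_LABELS",
    "PLANARITY_THRESHOLD",
    "compute_cremer_pople",
    "build_ideal_ring",
    "geodesic_distance",
]

#: Canonical atom names in ring order for a pyranose.
DEFAULT_RING_LABELS = ("O5", "C1", "C2", "C3", "C4", "C5")

#: Below this total amplitude (Å) the angular coordinates are reported as
#: undefined: near the center of the puckering sphere (theta, phi) are
#: numerically meaningless.
PLANARITY_THRESHOLD = 0.1


class RingGeometryError(ValueError):
    """Raised for structurally invalid ring atom sets."""


@dataclass(frozen=True)
class RingAtomSet:
    """Six ring atoms in fixed ring order (O5, C1, C2, C3, C4, C5).

    Parameters
    ----------
    labels
        Atom names in ring order.
    coords
        ``(6, 3)`` Cartesian coordinates in Å.
    """

    labels: tuple[str, ...]
    coords: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if len(self.labels) != 6:
            raise RingGeometryError(
                f"a six-membered ring needs 6 atoms, got {len(self.labels)}"
            )
        if coords.shape != (6, 3):
            raise RingGeometryError(
                f"coords must have shape (6, 3), got {coords.shape}"
            )
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "labels", tuple(self.labels))

    def validate_bonds(self, lo: float = 0.8, hi: float = 2.0) -> None:
        """Check consecutive ring atoms are within plausible bonded distance."""
        for j in range(6):
            d = float(np.linalg.norm(self.coords[(j + 1) % 6] - self.coords[j]))
            if not lo <= d <= hi:
                raise RingGeometryError(
                    f"ring bond {self.labels[j]}-{self.labels[(j + 1) % 6]} "
                    f"has length {d:.3f} Å, outside [{lo}, {hi}] Å"
                )


@dataclass(frozen=True)
class PuckerCoordinates:
    """Cremer–Pople coordinates (Q, theta, phi) with intermediates.

    ``theta`` and ``phi`` are NaN when the ring is too close to planar for
    the angular coordinates to be defined (``Q`` below the planarity
    threshold used at computation time).
    """

    Q: float
    theta: float
    phi: float
    q2: float
    q3: float
    phi2: float = field(default=math.nan)

    @property
    def is_angular_defined(self) -> bool:
        return not (math.isnan(self.theta) or math.isnan(self.phi))


def _ring_coords(ring: RingAtomSet | np.ndarray) -> np.ndarray:
    if isinstance(ring, RingAtomSet):
        return ring.coords
    coords = np.asarray(ring, dtype=float)
    if coords.shape != (6, 3):
        raise RingGeometryError(f"expected 6 ring atoms, got shape {coords.shape}")
    return coords


def compute_cremer_pople(
    ring: RingAtomSet | np.ndarray,
    planarity_threshold: float = PLANARITY_THRESHOLD,
) -> PuckerCoordinates:
    """Compute Cremer–Pople puckering coordinates of a six-membered ring.

    The six positions are centered on their geometric mean; the mean plane
    is defined through the two in-plane vectors

        R' = sum_j R_j sin(2*pi*(j-1)/6),   R'' = sum_j R_j cos(2*pi*(j-1)/6)

    with unit normal ``n = R' x R'' / |R' x R''|``.  From the out-of-plane
    displacements ``z_j = R_j . n``:

        q2 cos(phi2) =  sqrt(1/3) * sum_j z_j cos(4*pi*(j-1)/6)
        q2 sin(phi2) = -sqrt(1/3) * sum_j z_j sin(4*pi*(j-1)/6)
        q3           =  sqrt(1/6) * sum_j z_j * (-1)**(j-1)
        Q            =  sqrt(q2**2 + q3**2)
        theta        =  atan2(q2, q3)  in [0, 180] deg,   phi = phi2

    Angular coordinates are returned as NaN when ``Q < planarity_threshold``.
    """
    coords = _ring_coords(ring)
    centered = coords - coords.mean(axis=0)

    j = np.arange(6)
    b = 2.0 * math.pi * j / 6.0
    r_prime = (centered * np.sin(b)[:, None]).sum(axis=0)
    r_dprime = (centered * np.cos(b)[:, None]).sum(axis=0)
    normal = np.cross(r_prime, r_dprime)
    norm = np.linalg.norm(normal)
    if norm < 1e-12:
        raise RingGeometryError("degenerate ring: mean plane undefined")
    normal /= norm
    z = centered @ normal

    a = 2.0 * b  # 4*pi*(j-1)/6
    q2cos = math.sqrt(1.0 / 3.0) * float(np.sum(z * np.cos(a)))
    q2sin = -math.sqrt(1.0 / 3.0) * float(np.sum(z * np.sin(a)))
    q3 = math.sqrt(1.0 / 6.0) * float(np.sum(z * (-1.0) ** j))
    q2 = math.hypot(q2cos, q2sin)
    big_q = math.hypot(q2, q3)

    if big_q < planarity_threshold:
        theta = phi = phi2 = math.nan
    else:
        theta = math.degrees(math.atan2(q2, q3))
        phi2 = math.degrees(math.atan2(q2sin, q2cos)) % 360.0
        phi = phi2
    return PuckerCoordinates(Q=big_q, theta=theta, phi=phi, q2=q2, q3=q3, phi2=phi2)


def _hexagon_template(bond_length: float) -> np.ndarray:
    """Regular hexagon in the xy-plane, numbered clockwise seen from +z.

    Clockwise numbering makes the mean-plane normal of the Cremer–Pople
    construction point along +z, so that positive z displacements of
    odd-j atoms (O5, C2, C4) give theta = 0 (the 4C1 pole).
    """
    j = np.arange(6)
    ang = -2.0 * math.pi * j / 6.0
    r = bond_length  # circumradius equals side length for a regular hexagon
    xyz = np.zeros((6, 3))
    xyz[:, 0] = r * np.cos(ang)
    xyz[:, 1] = r * np.sin(ang)
    return xyz


def displacement_pattern(Q: float, theta: float, phi: float) -> np.ndarray:
    """Out-of-plane displacements z_j for target (Q, theta, phi), degrees in."""
    th = math.radians(theta)
    ph = math.radians(phi)
    j = np.arange(6)
    a = 4.0 * math.pi * j / 6.0
    return (
        math.sqrt(1.0 / 3.0) * Q * math.sin(th) * np.cos(ph + a)
        + math.sqrt(1.0 / 6.0) * Q * math.cos(th) * (-1.0) ** j
    )


def build_ideal_ring(
    Q: float,
    theta: float,
    phi: float,
    bond_length: float = 1.52,
    labels: Sequence[str] = DEFAULT_RING_LABELS,
) -> RingAtomSet:
    """Build an idealized ring with prescribed Cremer–Pople coordinates.

    A planar regular hexagon template (side ``bond_length``) is displaced
    along its normal by the closed-form pattern z_j(Q, theta, phi).  The
    construction is an exact inverse: ``compute_cremer_pople`` on the
    result recovers (Q, theta, phi) to machine precision.
    """
    if Q < 0:
        raise ValueError(f"puckering amplitude Q must be >= 0, got {Q}")
    if bond_length <= 0:
        raise ValueError("bond_length must be positive")
    xyz = _hexagon_template(bond_length)
    xyz[:, 2] = displacement_pattern(Q, theta, phi)
    return RingAtomSet(labels=tuple(labels), coords=xyz)


def geodesic_distance(theta1: float, phi1: float, theta2: float, phi2: float) -> float:
    """Great-circle distance (degrees) between two puckering-sphere points."""
    t1, p1, t2, p2 = map(math.radians, (theta1, phi1, theta2, phi2))
    c = math.cos(t1) * math.cos(t2) + math.sin(t1) * math.sin(t2) * math.cos(p1 - p2)
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))
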