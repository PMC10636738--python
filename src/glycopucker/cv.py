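"""Reaction collective variables for the glycosidase two-step mechanism.

Both catalytic steps are followed with a single distance-combination CV
(units Å), built from a named map of active-site atoms:

* cyclization (glycosidic bond cleavage with acid protonation of the
  leaving-group oxygen and anchimeric attack of the 2-acetamido oxygen):

      CV1 = (d(Ocarb_D175, H_D175) - d(O1, H_D175)) + (d(C1, O1) - d(C1, O_NHAc))

* ring opening (deprotonation of the nucleophilic water by the acid/base
  aspartate and attack of the water oxygen on the anomeric carbon):

      CV2 = (d(O_w, H_w) - d(Ocarb_D175, H_w)) + (d(C1, O_NHAc) - d(C1, O_w))

Sign convention: reactant-like frames are negative, product-like positive,
so the free-energy profiles read left to right along the reaction.

Atom roles are always supplied explicitly — protonation states are
mechanism-critical and are never guessed from geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np

from .ring import PuckerCoordinates, compute_cremer_pople

__all__ = [
    "ActiveSiteMap",
    "CVResult",
    "MissingRoleError",
    "distance",
    "evaluate_cyclization_cv",
    "evaluate_ring_opening_cv",
    "cv_series",
    "pucker_series",
    "CYCLIZATION_ROLES",
    "RING_OPENING_ROLES",
]


class MissingRoleError(KeyError):
    """An evaluated CV references an atom role absent from the map."""


@dataclass(frozen=True)
class ActiveSiteMap:
    """Named atom indices (0-based) binding CV formulas to a structure.

    Roles: anomeric carbon ``C1``; glycosidic oxygen ``O1``; endocyclic
    oxygen ``O5``; 2-acetamido carbonyl oxygen ``O_NHAc``; the acid/base
    aspartate's transferable proton ``H_D175`` and the carboxylate oxygen
    holding/receiving it ``Ocarb_D175``; nucleophilic water oxygen ``O_w``
    and its transferring proton ``H_w``.  Unused roles may be None.
    """

    C1: int | None = None
    O1: int | None = None
    O5: int | None = None
    O_NHAc: int | None = None
    H_D175: int | None = None
    Ocarb_D175: int | None = None
    O_w: int | None = None
    H_w: int | None = None

    def __post_init__(self) -> None:
        idx = [v for v in self.as_dict().values() if v is not None]
        if len(set(idx)) != len(idx):
            raise ValueError("active-site map indices must be distinct")

    def as_dict(self) -> dict[str, int | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def require(self, roles: tuple[str, ...]) -> dict[str, int]:
        resolved = {}
        for role in roles:
            v = getattr(self, role)
            if v is None:
                raise MissingRoleError(
                    f"role '{role}' is required by this CV but missing from the map"
                )
            resolved[role] = v
        return resolved


CYCLIZATION_ROLES = ("Ocarb_D175", "H_D175", "O1", "C1", "O_NHAc")
RING_OPENING_ROLES = ("O_w", "H_w", "Ocarb_D175", "C1", "O_NHAc")


@dataclass(frozen=True)
class CVResult:
    """A CV value (Å) with its retained component distances."""

    value: float
    components: dict[str, float] = field(default_factory=dict)


def distance(frame: np.ndarray, i: int, j: int) -> float:
    """Euclidean distance (Å) between atoms i and j of a (n, 3) frame."""
    frame = np.asarray(frame, dtype=float)
    n = frame.shape[0]
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"atom index out of range for frame with {n} atoms")
    return float(np.linalg.norm(frame[i] - frame[j]))


def evaluate_cyclization_cv(frame: np.ndarray, site: ActiveSiteMap) -> CVResult:
    """CV for the first catalytic step (Michaelis complex -> oxazolinium)."""
    r = site.require(CYCLIZATION_ROLES)
    comp = {
        "d_Ocarb_H": distance(frame, r["Ocarb_D175"], r["H_D175"]),
        "d_O1_H": distance(frame, r["O1"], r["H_D175"]),
        "d_C1_O1": distance(frame, r["C1"], r["O1"]),
        "d_C1_ONHAc": distance(frame, r["C1"], r["O_NHAc"]),
    }
    value = (comp["d_Ocarb_H"] - comp["d_O1_H"]) + (comp["d_C1_O1"] - comp["d_C1_ONHAc"])
    return CVResult(value=value, components=comp)


def evaluate_ring_opening_cv(frame: np.ndarray, site: ActiveSiteMap) -> CVResult:
    """CV for the second catalytic step (oxazolinium hydrolysis)."""
    r = site.require(RING_OPENING_ROLES)
    comp = {
        "d_Ow_Hw": distance(frame, r["O_w"], r["H_w"]),
        "d_Ocarb_Hw": distance(frame, r["Ocarb_D175"], r["H_w"]),
        "d_C1_ONHAc": distance(frame, r["C1"], r["O_NHAc"]),
        "d_C1_Ow": distance(frame, r["C1"], r["O_w"]),
    }
    value = (comp["d_Ow_Hw"] - comp["d_Ocarb_Hw"]) + (comp["d_C1_ONHAc"] - comp["d_C1_Ow"])
    return CVResult(value=value, components=comp)


_CV_EVALUATORS = {
    "cyclization": evaluate_cyclization_cv,
    "ring-opening": evaluate_ring_opening_cv,
}


def cv_series(trajectory, site: ActiveSiteMap, step: str = "cyclization"):
    """Evaluate a reaction CV on every frame; frame order preserved.

    Frames that cannot be evaluated yield None (gap marker) rather than
    being dropped, so the series stays aligned with other per-frame
    observables.
    """
    try:
        evaluate = _CV_EVALUATORS[step]
    except KeyError:
        raise ValueError(f"unknown CV step '{step}'; choose from {sorted(_CV_EVALUATORS)}")
    out: list[CVResult | None] = []
    for frame in trajectory:
        try:
            out.append(evaluate(np.asarray(frame, dtype=float), site))
        except (IndexError, MissingRoleError):
            out.append(None)
    return out


def pucker_series(trajectory, ring_indices) -> list[PuckerCoordinates | None]:
    """Cremer–Pople coordinates of the selected ring for every frame.

    ``ring_indices`` are six 0-based atom indices in ring order
    (O5, C1, C2, C3, C4, C5).  Frames where the ring cannot be extracted
    yield None gap markers; frame order is preserved.
    """
    ring_indices = list(ring_indices)
    if len(ring_indices) != 6:
        raise ValueError("ring selection must name exactly 6 atoms")
    out: list[PuckerCoordinates | None] = []
    for frame in trajectory:
        frame = np.asarray(frame, dtype=float)
        try:
            coords = frame[ring_indices]
            p = compute_cremer_pople(coords)
            out.append(p)
        except (IndexError, ValueError):
            out.append(None)
    return out
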