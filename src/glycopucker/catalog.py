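"""The 38 canonical pyranose conformers and classification against them.

Canonical six-membered-ring shapes: 2 chairs (C), 6 boats (B), 6 twist-boats
(S, "skew"), 12 envelopes (E) and 12 half-chairs (H).  Labels use the
carbohydrate convention in plain ASCII — superscripts written before the
family letter, subscripts after, ring oxygen written "O": the 4C1 chair is
"4C1", the boat with C1 and C4 above the reference plane is "1,4B", the
twist-boat with C1 above and C3 below is "1S3", the envelope with C4 above
is "4E".

Reference (theta, phi) positions are not taken from a literature table:
each conformer's idealized geometry is constructed from its definition
(the named atoms displaced above/below the plane of the remaining ones on
a regular hexagon template) and run through ``compute_cremer_pople``.  The
catalog is therefore self-consistent with this package's phi convention by
construction.  Chairs land at theta = 0/180, boats and twist-boats exactly
on the equator every 30 deg in phi, envelopes exactly on the tropics
(theta = 54.74/125.26 deg) and half-chairs close to them (50.77/129.23 deg:
the geometric four-atom-coplanar half-chair is not quite the canonical
lattice point).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .ring import (
    DEFAULT_RING_LABELS,
    PuckerCoordinates,
    compute_cremer_pople,
    geodesic_distance,
    _hexagon_template,
)

__all__ = [
    "ConformerEntry",
    "ConformerCatalog",
    "ConformerAssignment",
    "CONFORMER_DEFINITIONS",
    "generate_conformer_catalog",
    "load_catalog",
    "classify_conformation",
]

# label -> (atoms above the reference plane, atoms below, family)
CONFORMER_DEFINITIONS: dict[str, tuple[tuple[str, ...], tuple[str, ...], str]] = {
    # chairs: alternating displacement; named by the out-of-plane para pair C1/C4
    "4C1": (("O5", "C2", "C4"), ("C1", "C3", "C5"), "chair"),
    "1C4": (("C1", "C3", "C5"), ("O5", "C2", "C4"), "chair"),
    # boats: a para pair displaced to the same side
    "1,4B": (("C1", "C4"), (), "boat"),
    "B1,4": ((), ("C1", "C4"), "boat"),
    "2,5B": (("C2", "C5"), (), "boat"),
    "B2,5": ((), ("C2", "C5"), "boat"),
    "O,3B": (("O5", "C3"), (), "boat"),
    "B3,O": ((), ("O5", "C3"), "boat"),
    # twist-boats: a meta pair displaced to opposite sides
    "1S3": (("C1",), ("C3",), "twist-boat"),
    "3S1": (("C3",), ("C1",), "twist-boat"),
    "1S5": (("C1",), ("C5",), "twist-boat"),
    "5S1": (("C5",), ("C1",), "twist-boat"),
    "2SO": (("C2",), ("O5",), "twist-boat"),
    "OS2": (("O5",), ("C2",), "twist-boat"),
    # envelopes: a single atom out of the plane of the other five
    "OE": (("O5",), (), "envelope"),
    "EO": ((), ("O5",), "envelope"),
    "1E": (("C1",), (), "envelope"),
    "E1": ((), ("C1",), "envelope"),
    "2E": (("C2",), (), "envelope"),
    "E2": ((), ("C2",), "envelope"),
    "3E": (("C3",), (), "envelope"),
    "E3": ((), ("C3",), "envelope"),
    "4E": (("C4",), (), "envelope"),
    "E4": ((), ("C4",), "envelope"),
    "5E": (("C5",), (), "envelope"),
    "E5": ((), ("C5",), "envelope"),
    # half-chairs: an adjacent pair displaced to opposite sides
    "OH1": (("O5",), ("C1",), "half-chair"),
    "1HO": (("C1",), ("O5",), "half-chair"),
    "1H2": (("C1",), ("C2",), "half-chair"),
    "2H1": (("C2",), ("C1",), "half-chair"),
    "2H3": (("C2",), ("C3",), "half-chair"),
    "3H2": (("C3",), ("C2",), "half-chair"),
    "3H4": (("C3",), ("C4",), "half-chair"),
    "4H3": (("C4",), ("C3",), "half-chair"),
    "4H5": (("C4",), ("C5",), "half-chair"),
    "5H4": (("C5",), ("C4",), "half-chair"),
    "5HO": (("C5",), ("O5",), "half-chair"),
    "OH5": (("O5",), ("C5",), "half-chair"),
}


@dataclass(frozen=True)
class ConformerEntry:
    label: str
    theta_ref: float
    phi_ref: float
    family: str


@dataclass(frozen=True)
class ConformerCatalog:
    """The 38 canonical conformers with their reference sphere positions."""

    entries: tuple[ConformerEntry, ...]

    def __post_init__(self) -> None:
        labels = [e.label for e in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError("catalog labels must be unique")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, label: str) -> ConformerEntry:
        for e in self.entries:
            if e.label == label:
                return e
        raise KeyError(label)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(e.label for e in self.entries)


@dataclass(frozen=True)
class ConformerAssignment:
    """Nearest-conformer assignment on the puckering sphere.

    ``label`` is a single catalog label, or a composite "A/B" when the two
    nearest references are closer than the tie tolerance (the blended
    assignments seen for conformations intermediate between a boat and the
    adjacent twist-boat).
    """

    label: str
    distance_deg: float
    runner_up: str
    runner_up_distance_deg: float


def ideal_conformer_ring(label: str, displacement: float = 0.275):
    """Idealized geometry of a canonical conformer on the hexagon template.

    The named atoms are displaced ``displacement`` Å above/below the plane
    of the remaining atoms; the amplitude sets Q but not (theta, phi).
    """
    up, down, _family = CONFORMER_DEFINITIONS[label]
    idx = {name: i for i, name in enumerate(DEFAULT_RING_LABELS)}
    xyz = _hexagon_template(1.52)
    for name in up:
        xyz[idx[name], 2] = displacement
    for name in down:
        xyz[idx[name], 2] = -displacement
    return xyz


def generate_conformer_catalog(Q_ref: float = 0.55) -> ConformerCatalog:
    """Generate the 38-entry catalog by geometric construction.

    Each conformer's ideal geometry is built and its Cremer–Pople angles
    computed; the displacement amplitude is scaled per family so the
    resulting total amplitude is close to ``Q_ref`` (the angles themselves
    are amplitude-independent to first order).
    """
    if Q_ref <= 0:
        raise ValueError("Q_ref must be positive")
    entries = []
    for label, (_up, _down, family) in CONFORMER_DEFINITIONS.items():
        # per-family scale so Q of the constructed ring is ~Q_ref
        n_displaced = len(_up) + len(_down)
        scale = {6: 0.41, 2: 1.3, 1: 2.1}[n_displaced]
        p = compute_cremer_pople(
            ideal_conformer_ring(label, displacement=scale * Q_ref / 2.0),
            planarity_threshold=0.0,
        )
        phi = 0.0 if family == "chair" else round(p.phi, 9) % 360.0
        if phi >= 360.0 - 1e-9:
            phi = 0.0
        entries.append(
            ConformerEntry(
                label=label,
                theta_ref=round(p.theta, 9),
                phi_ref=phi,
                family=family,
            )
        )
    return ConformerCatalog(entries=tuple(entries))


def load_catalog() -> ConformerCatalog:
    """Load the frozen reference catalog shipped with the package."""
    text = (
        resources.files("glycopucker.data")
        .joinpath("conformer_catalog.tsv")
        .read_text()
    )
    entries = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        label, theta, phi, family = line.split("\t")
        entries.append(ConformerEntry(label, float(theta), float(phi), family))
    return ConformerCatalog(entries=tuple(entries))


def classify_conformation(
    p: PuckerCoordinates,
    catalog: ConformerCatalog | None = None,
    tie_tol: float = 10.0,
) -> ConformerAssignment:
    """Assign the nearest canonical conformer by geodesic distance.

    Parameters
    ----------
    p
        Puckering coordinates with defined (theta, phi).
    catalog
        Reference catalog; the frozen shipped catalog by default.
    tie_tol
        Composite "A/B" label emitted when the two nearest references are
        within this many degrees of each other (degrees of geodesic arc).
    """
    if not p.is_angular_defined:
        raise ValueError(
            "cannot classify a near-planar ring: theta/phi undefined "
            f"(Q = {p.Q:.4f} Å below the planarity threshold)"
        )
    if catalog is None:
        catalog = load_catalog()
    dists = sorted(
        (
            (geodesic_distance(p.theta, p.phi, e.theta_ref, e.phi_ref), e.label)
            for e in catalog
        ),
        key=lambda t: (t[0], t[1]),
    )
    (d1, l1), (d2, l2) = dists[0], dists[1]
    if abs(d2 - d1) < tie_tol:
        first, second = sorted([l1, l2])
        label = f"{first}/{second}"
    else:
        label = l1
    return ConformerAssignment(
        label=label, distance_deg=d1, runner_up=l2, runner_up_distance_deg=d2
    )
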