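"""Synthetic inputs with known ground truth.

Everything the analysis pipeline consumes can be generated here with the
truth recorded alongside: ring trajectories following prescribed paths on
the puckering sphere, model free-energy landscapes with designed basins
and saddles, 1D reaction profiles with exact barrier/reaction free
energy, water trajectories with a prescribed per-frame sphere-occupancy
probability, and toy active-site frames realizing printed transition-
state distances.  All generators are seed-deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .catalog import ConformerCatalog, load_catalog
from .cv import ActiveSiteMap
from .fes import FreeEnergySurface, make_pucker_axes
from .metad import ModelPotential
from .ring import build_ideal_ring
from .solvation import ProbeSphere

__all__ = [
    "PuckerPathSpec",
    "FELSpec",
    "Basin",
    "ReactionProfileSpec",
    "make_ring_trajectory",
    "make_fel",
    "make_reaction_profile",
    "make_water_trajectory",
    "make_toy_active_site",
    "harmonic_well",
    "TS1_DISTANCES",
    "TS2_DISTANCES",
]

# Transition-state geometries of the two catalytic steps (Å): proton of the
# acid/base residue nearly transferred to the glycosidic oxygen at TS1;
# water proton in flight and C1-O_w bond forming at TS2.
TS1_DISTANCES = {"d_Ocarb_H": 1.53, "d_O1_H": 1.07, "d_C1_O1": 2.3, "d_C1_ONHAc": 2.2}
TS2_DISTANCES = {"d_Ow_Hw": 1.16, "d_Ocarb_Hw": 1.29, "d_C1_ONHAc": 2.56, "d_C1_Ow": 2.14}


# ---------------------------------------------------------------------------
# ring trajectories on the puckering sphere


@dataclass(frozen=True)
class PuckerPathSpec:
    """Waypoints (theta, phi, Q) traversed geodesically with optional noise."""

    waypoints: tuple[tuple[float, float, float], ...]
    frames_per_segment: int = 50
    noise_sigma: float = 0.0
    seed: int = 0
    bond_length: float = 1.52

    def __post_init__(self) -> None:
        if len(self.waypoints) == 0:
            raise ValueError("at least one waypoint required")
        for th, ph, q in self.waypoints:
            if not (0.0 <= th <= 180.0) or q < 0:
                raise ValueError(f"waypoint out of domain: theta={th}, Q={q}")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


def _sph_to_vec(theta: float, phi: float) -> np.ndarray:
    t, p = math.radians(theta), math.radians(phi)
    return np.array([math.sin(t) * math.cos(p), math.sin(t) * math.sin(p), math.cos(t)])


def _vec_to_sph(v: np.ndarray) -> tuple[float, float]:
    theta = math.degrees(math.acos(max(-1.0, min(1.0, v[2] / np.linalg.norm(v)))))
    phi = math.degrees(math.atan2(v[1], v[0])) % 360.0
    return theta, phi


def _slerp(v0: np.ndarray, v1: np.ndarray, f: float) -> np.ndarray:
    dot = float(np.clip(np.dot(v0, v1), -1.0, 1.0))
    omega = math.acos(dot)
    if omega < 1e-12:
        return v0
    return (math.sin((1 - f) * omega) * v0 + math.sin(f * omega) * v1) / math.sin(omega)


def make_ring_trajectory(spec: PuckerPathSpec):
    """Cartesian ring trajectory along a puckering-sphere path.

    Returns ``(coords, truth)`` where ``coords`` has shape (n_frames, 6, 3)
    (atom order O5, C1, C2, C3, C4, C5) and ``truth`` is a list of ground-
    truth ``(Q, theta, phi)`` per frame (noise-free targets).  Waypoints
    are interpolated along great circles with Q varied linearly; i.i.d.
    Gaussian noise of width ``noise_sigma`` Å is added to every Cartesian
    component.
    """
    rng = np.random.default_rng(spec.seed)
    targets: list[tuple[float, float, float]] = []
    wps = spec.waypoints
    if len(wps) == 1:
        th, ph, q = wps[0]
        targets = [(q, th, ph)] * spec.frames_per_segment
    else:
        for (th0, ph0, q0), (th1, ph1, q1) in zip(wps[:-1], wps[1:]):
            v0, v1 = _sph_to_vec(th0, ph0), _sph_to_vec(th1, ph1)
            for k in range(spec.frames_per_segment):
                f = k / (spec.frames_per_segment - 1) if spec.frames_per_segment > 1 else 0.0
                th, ph = _vec_to_sph(_slerp(v0, v1, f))
                targets.append((q0 + f * (q1 - q0), th, ph))
    coords = np.empty((len(targets), 6, 3))
    for i, (q, th, ph) in enumerate(targets):
        ring = build_ideal_ring(q, th, ph, bond_length=spec.bond_length)
        coords[i] = ring.coords
    if spec.noise_sigma > 0:
        coords = coords + rng.normal(0.0, spec.noise_sigma, size=coords.shape)
    return coords, targets


# ---------------------------------------------------------------------------
# model free-energy landscapes on the puckering sphere


@dataclass(frozen=True)
class Basin:
    """A basin placed at a conformer label or an explicit (theta, phi)."""

    center: str | tuple[float, float]
    energy: float = 0.0
    width: float = 15.0  # deg, for the Gaussian-well construction


@dataclass(frozen=True)
class FELSpec:
    """Designed landscape: Gaussian wells, or a valley through a saddle.

    With ``saddle`` set (exactly two basins required) the surface is built
    as a valley along the geodesic polyline basin-saddle-basin whose
    on-path profile passes exactly through the designed energies, rising
    transversally toward ``base_level`` — minima and saddle energies are
    then exact by construction.  Without a saddle the surface is a sum of
    inverted geodesic Gaussians on a constant base.
    """

    basins: tuple[Basin, ...]
    saddle: tuple[str | tuple[float, float], float] | None = None
    base_level: float = 12.0
    grid_step: float = 1.0
    transverse_width: float = 25.0

    def __post_init__(self) -> None:
        if len(self.basins) == 0:
            raise ValueError("at least one basin required")
        if self.saddle is not None and len(self.basins) != 2:
            raise ValueError("the valley construction needs exactly two basins")


def _resolve_center(center, catalog: ConformerCatalog) -> tuple[float, float]:
    if isinstance(center, str):
        if "/" in center:  # midpoint of a composite label like "1,4B/1S3"
            la, lb = center.split("/")
            ea, eb = catalog[la], catalog[lb]
            v = _slerp(
                _sph_to_vec(ea.theta_ref, ea.phi_ref),
                _sph_to_vec(eb.theta_ref, eb.phi_ref),
                0.5,
            )
            return _vec_to_sph(v)
        e = catalog[center]
        return e.theta_ref, e.phi_ref
    return float(center[0]), float(center[1])


def _geodesic_grid(phi_axis, theta_axis, theta0, phi0):
    pp, tt = np.meshgrid(np.radians(phi_axis), np.radians(theta_axis), indexing="ij")
    t0, p0 = math.radians(theta0), math.radians(phi0)
    cosd = np.cos(tt) * math.cos(t0) + np.sin(tt) * math.sin(t0) * np.cos(pp - p0)
    return np.degrees(np.arccos(np.clip(cosd, -1.0, 1.0)))


def make_fel(spec: FELSpec, catalog: ConformerCatalog | None = None):
    """Build a designed puckering free-energy surface.

    Returns ``(fes, truth)`` where ``truth`` records the designed minima
    and saddle (positions in (theta, phi) degrees and energies kcal/mol).
    """
    if catalog is None:
        catalog = load_catalog()
    phi_axis, theta_axis = make_pucker_axes(spec.grid_step)
    centers = [_resolve_center(b.center, catalog) for b in spec.basins]

    if spec.saddle is None:
        values = np.full((len(phi_axis), len(theta_axis)), spec.base_level)
        for (th0, ph0), b in zip(centers, spec.basins):
            d = _geodesic_grid(phi_axis, theta_axis, th0, ph0)
            values -= (spec.base_level - b.energy) * np.exp(-0.5 * (d / b.width) ** 2)
        truth = {
            "minima": [
                {"theta": th, "phi": ph, "energy": b.energy}
                for (th, ph), b in zip(centers, spec.basins)
            ],
            "saddle": None,
        }
    else:
        s_center, s_energy = spec.saddle
        ths, phs = _resolve_center(s_center, catalog)
        (tha, pha), (thb, phb) = centers
        ea, eb = spec.basins[0].energy, spec.basins[1].energy
        # sample the polyline A -> S -> B densely along great circles
        va, vs, vb = _sph_to_vec(tha, pha), _sph_to_vec(ths, phs), _sph_to_vec(thb, phb)
        n_samp = 240
        seg1 = [_slerp(va, vs, f) for f in np.linspace(0, 1, n_samp)]
        seg2 = [_slerp(vs, vb, f) for f in np.linspace(0, 1, n_samp)[1:]]
        pts = np.array(seg1 + seg2)
        arc1 = math.degrees(math.acos(np.clip(np.dot(va, vs), -1, 1)))
        arc2 = math.degrees(math.acos(np.clip(np.dot(vs, vb), -1, 1)))
        u1 = np.linspace(0, 1, n_samp)
        u2 = np.linspace(0, 1, n_samp)[1:]
        # on-path profile: cosine ramps through (ea -> s_energy -> eb)
        f1 = ea + (s_energy - ea) * 0.5 * (1 - np.cos(math.pi * u1))
        f2 = s_energy + (eb - s_energy) * 0.5 * (1 - np.cos(math.pi * u2))
        f_path = np.concatenate([f1, f2])

        pp, tt = np.meshgrid(np.radians(phi_axis), np.radians(theta_axis), indexing="ij")
        grid_vecs = np.stack(
            [np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp), np.cos(tt)], axis=-1
        )
        # nearest path sample per grid point
        dots = np.clip(np.einsum("ijk,lk->ijl", grid_vecs, pts), -1.0, 1.0)
        nearest = np.argmax(dots, axis=-1)
        d_perp = np.degrees(np.arccos(np.take_along_axis(dots, nearest[..., None], -1)[..., 0]))
        q = (d_perp / spec.transverse_width) ** 2
        values = f_path[nearest] + (spec.base_level - f_path[nearest]) * q / (1.0 + q)
        truth = {
            "minima": [
                {"theta": tha, "phi": pha, "energy": ea},
                {"theta": thb, "phi": phb, "energy": eb},
            ],
            "saddle": {"theta": ths, "phi": phs, "energy": s_energy},
            "barrier_from_first": s_energy - ea,
            "arc_lengths": (arc1, arc2),
        }
    fes = FreeEnergySurface(
        axes=(phi_axis, theta_axis),
        values=values,
        periodic=(True, False),
        axis_names=("phi", "theta"),
    )
    return fes.normalized(), truth


# ---------------------------------------------------------------------------
# 1D reaction profiles


@dataclass(frozen=True)
class ReactionProfileSpec:
    """Double well with exact barrier and reaction free energy (kcal/mol).

    The reactant well sits at ``well_positions[0]`` with energy 0, the
    transition state at their midpoint with energy ``barrier``, and the
    product well at ``well_positions[1]`` with energy ``reaction_dg``
    (negative = exothermic).
    """

    barrier: float
    reaction_dg: float = 0.0
    well_positions: tuple[float, float] = (-1.0, 1.0)
    wall_k: float = 25.0
    margin: float = 0.8

    def __post_init__(self) -> None:
        if self.barrier < max(0.0, self.reaction_dg) or self.barrier <= self.reaction_dg:
            raise ValueError(
                f"infeasible profile: barrier {self.barrier} must exceed "
                f"max(0, reaction_dg={self.reaction_dg})"
            )
        if not self.well_positions[0] < self.well_positions[1]:
            raise ValueError("well positions must be increasing")


def make_reaction_profile(spec: ReactionProfileSpec) -> ModelPotential:
    """Analytic double-well ModelPotential realizing the spec exactly.

    Piecewise cosine ramps between the stationary points (C1-smooth, zero
    slope at wells and barrier top) with harmonic confining walls outside
    the wells.
    """
    xa, xb = spec.well_positions
    xts = 0.5 * (xa + xb)
    ea, ets, eb = 0.0, spec.barrier, spec.reaction_dg
    kw = spec.wall_k

    def energy(x):
        x = np.asarray(x, dtype=float)
        x = x[..., 0] if x.ndim and x.shape[-1] == 1 else x
        out = np.empty_like(x, dtype=float)
        left = x < xa
        seg1 = (x >= xa) & (x < xts)
        seg2 = (x >= xts) & (x <= xb)
        right = x > xb
        out[left] = ea + kw * (x[left] - xa) ** 2
        u = (x[seg1] - xa) / (xts - xa)
        out[seg1] = ea + (ets - ea) * 0.5 * (1 - np.cos(np.pi * u))
        u = (x[seg2] - xts) / (xb - xts)
        out[seg2] = ets + (eb - ets) * 0.5 * (1 - np.cos(np.pi * u))
        out[right] = eb + kw * (x[right] - xb) ** 2
        return out

    def gradient(x):
        x = np.asarray(x, dtype=float)
        xv = float(x[0] if x.ndim else x)
        if xv < xa:
            g = 2 * kw * (xv - xa)
        elif xv < xts:
            u = (xv - xa) / (xts - xa)
            g = (ets - ea) * 0.5 * np.pi * np.sin(np.pi * u) / (xts - xa)
        elif xv <= xb:
            u = (xv - xts) / (xb - xts)
            g = (eb - ets) * 0.5 * np.pi * np.sin(np.pi * u) / (xb - xts)
        else:
            g = 2 * kw * (xv - xb)
        return np.array([g])

    return ModelPotential(
        energy=energy,
        gradient=gradient,
        bounds=((xa - spec.margin, xb + spec.margin),),
        periods=(None,),
        name=f"double_well(barrier={spec.barrier}, dG={spec.reaction_dg})",
    )


def harmonic_well(k: float = 10.0, center: float = 0.0, half_width: float = 2.0) -> ModelPotential:
    """1D harmonic potential, mainly for sampler validation (equipartition)."""

    def energy(x):
        x = np.asarray(x, dtype=float)
        x = x[..., 0] if x.ndim and x.shape[-1] == 1 else x
        return 0.5 * k * (x - center) ** 2

    def gradient(x):
        return np.array([k * (float(np.asarray(x).ravel()[0]) - center)])

    return ModelPotential(
        energy=energy,
        gradient=gradient,
        bounds=((center - half_width, center + half_width),),
        name=f"harmonic(k={k})",
    )


# ---------------------------------------------------------------------------
# water trajectories


def make_water_trajectory(
    p_occupancy: float,
    n_frames: int,
    seed: int = 0,
    radius: float = 2.0,
    n_background_waters: int = 3,
):
    """Frames with a water in the active-site probe sphere with probability p.

    Anchors are fixed: the anomeric carbon at the origin and a three-atom
    carboxylate group centered 3 Å away; the probe sphere sits at their
    midpoint.  Per frame, with probability ``p_occupancy`` one water
    oxygen is placed uniformly inside the sphere, otherwise all waters
    stay outside.  Background waters bob around 8-12 Å away.

    Returns ``(frames, sphere, water_indices, truth)`` with ``truth`` the
    per-frame ground-truth occupancy indicator.
    """
    if not 0.0 <= p_occupancy <= 1.0:
        raise ValueError("p_occupancy must be in [0, 1]")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    c1 = np.zeros(3)
    carb = np.array(
        [[3.0, 0.0, 0.0], [3.6, 1.0, 0.0], [3.6, -1.0, 0.0]]
    )  # CG, OD1, OD2 of the aspartate
    center = 0.5 * (c1 + carb.mean(axis=0))
    n_atoms = 4 + 1 + n_background_waters  # C1, 3 carboxylate, probe water, background
    frames = np.empty((n_frames, n_atoms, 3))
    truth = rng.random(n_frames) < p_occupancy
    for i in range(n_frames):
        frames[i, 0] = c1
        frames[i, 1:4] = carb
        if truth[i]:
            while True:  # uniform in the ball by rejection
                u = rng.uniform(-1, 1, size=3)
                if np.dot(u, u) <= 1.0:
                    break
            frames[i, 4] = center + radius * u
        else:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            frames[i, 4] = center + direction * (radius + 2.0 + rng.uniform(0, 3))
        for w in range(n_background_waters):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            frames[i, 5 + w] = center + direction * rng.uniform(8.0, 12.0)
    sphere = ProbeSphere(c1_index=0, carboxylate_indices=(1, 2, 3), radius=radius)
    water_indices = list(range(4, n_atoms))
    return frames, sphere, water_indices, truth.astype(bool)


# ---------------------------------------------------------------------------
# toy active-site frames


_TOY_KEYS_TS1 = ("d_C1_O1", "d_O1_H", "d_Ocarb_H", "d_C1_ONHAc")
_TOY_KEYS_TS2 = ("d_C1_Ow", "d_Ow_Hw", "d_Ocarb_Hw", "d_C1_ONHAc")


def make_toy_active_site(distance_spec: dict[str, float]):
    """A frame realizing the given role-pair distances exactly.

    Accepts the component keys of either reaction CV
    (``d_C1_O1, d_O1_H, d_Ocarb_H, d_C1_ONHAc`` for cyclization;
    ``d_C1_Ow, d_Ow_Hw, d_Ocarb_Hw, d_C1_ONHAc`` for ring opening).
    Atoms are chain-placed along the x axis with the acetamido oxygen on
    y, so every positive distance specification is realizable; the spec'd
    pairwise distances are reproduced to machine precision.

    Returns ``(frame, site_map)``.
    """
    for key, val in distance_spec.items():
        if key not in set(_TOY_KEYS_TS1) | set(_TOY_KEYS_TS2):
            raise KeyError(f"unknown distance key '{key}'")
        if val < 0:
            raise ValueError(f"distance {key} must be >= 0, got {val}")
    is_ts1 = "d_C1_O1" in distance_spec or "d_O1_H" in distance_spec
    is_ts2 = "d_C1_Ow" in distance_spec or "d_Ow_Hw" in distance_spec
    if is_ts1 and is_ts2:
        raise ValueError("mixing cyclization and ring-opening keys is ambiguous")
    coords: list[np.ndarray] = []
    roles: dict[str, int] = {}

    def add(role: str, xyz) -> None:
        roles[role] = len(coords)
        coords.append(np.asarray(xyz, dtype=float))

    add("C1", (0.0, 0.0, 0.0))
    add("O_NHAc", (0.0, distance_spec.get("d_C1_ONHAc", 2.0), 0.0))
    if is_ts1:
        x = distance_spec.get("d_C1_O1", 1.4)
        add("O1", (x, 0, 0))
        x += distance_spec.get("d_O1_H", 1.0)
        add("H_D175", (x, 0, 0))
        x += distance_spec.get("d_Ocarb_H", 1.5)
        add("Ocarb_D175", (x, 0, 0))
    else:
        x = distance_spec.get("d_C1_Ow", 3.0)
        add("O_w", (x, 0, 0))
        x += distance_spec.get("d_Ow_Hw", 1.0)
        add("H_w", (x, 0, 0))
        x += distance_spec.get("d_Ocarb_Hw", 1.5)
        add("Ocarb_D175", (x, 0, 0))
    frame = np.vstack(coords)
    return frame, ActiveSiteMap(**roles)
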