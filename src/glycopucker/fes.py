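"""Analysis of gridded free-energy surfaces.

Surfaces live on a regular grid over either a single reaction CV (Å) or
the puckering angles (phi in [0, 360) periodic, theta in [0, 180]).  The
operations are topographic: locate minima, compute minimax barriers and
minimum-energy paths between them (Dijkstra with max-cost composition on
the 8-connected grid), assign conformational itineraries by classifying
path points against the canonical conformer catalog, and export the
Mercator representation with isolines.

Sphere topology is respected: phi wraps, and the theta = 0 / 180 rows are
each treated as a single logical point (the chairs are points on the
puckering sphere, not circles).
"""

from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .catalog import ConformerCatalog, classify_conformation, load_catalog
from .ring import PuckerCoordinates, geodesic_distance

__all__ = [
    "FreeEnergySurface",
    "StationaryPoint",
    "ItineraryPath",
    "find_minima",
    "minimax_barrier",
    "minimum_energy_path",
    "assign_itinerary",
    "region_energy",
    "export_mercator",
    "make_pucker_axes",
]


@dataclass(frozen=True)
class FreeEnergySurface:
    """Gridded free energy in kcal/mol.

    ``axes`` are strictly increasing 1D arrays (one per dimension);
    ``values`` has shape ``(len(axes[0]), ...)``.  For puckering surfaces
    the axis order is (phi, theta).
    """

    axes: tuple[np.ndarray, ...]
    values: np.ndarray
    periodic: tuple[bool, ...]
    axis_names: tuple[str, ...] = ("cv1",)

    def __post_init__(self) -> None:
        axes = tuple(np.asarray(a, dtype=float) for a in self.axes)
        values = np.asarray(self.values, dtype=float)
        if values.shape != tuple(len(a) for a in axes):
            raise ValueError("values shape does not match axes")
        if not np.all(np.isfinite(values)):
            raise ValueError("free energy must be finite everywhere")
        for a in axes:
            if np.any(np.diff(a) <= 0):
                raise ValueError("axes must be strictly increasing")
        object.__setattr__(self, "axes", axes)
        object.__setattr__(self, "values", values)

    @property
    def ndim(self) -> int:
        return len(self.axes)

    @property
    def is_pucker_surface(self) -> bool:
        return self.ndim == 2 and self.axis_names[:2] == ("phi", "theta")

    def normalized(self) -> "FreeEnergySurface":
        """Shift so the global minimum is exactly zero."""
        return FreeEnergySurface(
            axes=self.axes,
            values=self.values - self.values.min(),
            periodic=self.periodic,
            axis_names=self.axis_names,
        )

    def point(self, idx: tuple[int, ...]) -> tuple[float, ...]:
        return tuple(float(self.axes[d][i]) for d, i in enumerate(idx))

    def energy(self, idx: tuple[int, ...]) -> float:
        return float(self.values[idx])


@dataclass(frozen=True)
class StationaryPoint:
    kind: str  # "minimum" | "saddle"
    index: tuple[int, ...]
    location: tuple[float, ...]
    energy: float
    basin_id: int = -1


@dataclass(frozen=True)
class ItineraryPath:
    """Grid path between two minima with its saddle marked."""

    indices: tuple[tuple[int, ...], ...]
    points: tuple[tuple[float, ...], ...]
    energies: tuple[float, ...]
    saddle_position: int  # index into the path of its highest point

    @property
    def saddle_energy(self) -> float:
        return self.energies[self.saddle_position]


def make_pucker_axes(step: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Default (phi, theta) grid: phi in [0, 360) and theta in [0, 180]."""
    phi = np.arange(0.0, 360.0, step)
    theta = np.arange(0.0, 180.0 + 0.5 * step, step)
    return phi, theta


def _pole_rows(fes: FreeEnergySurface) -> set[int]:
    """theta-axis indices collapsed to a single logical point (the chairs)."""
    if not fes.is_pucker_surface:
        return set()
    theta = fes.axes[1]
    rows = set()
    if abs(theta[0]) < 1e-9:
        rows.add(0)
    if abs(theta[-1] - 180.0) < 1e-9:
        rows.add(len(theta) - 1)
    return rows


def _neighbors(fes: FreeEnergySurface, idx: tuple[int, ...]):
    """8-connected neighbors with periodic wrap and pole identification."""
    shape = fes.values.shape
    if fes.ndim == 1:
        (i,) = idx
        for di in (-1, 1):
            j = i + di
            if fes.periodic[0]:
                yield (j % shape[0],)
            elif 0 <= j < shape[0]:
                yield (j,)
        return
    poles = _pole_rows(fes)
    i, j = idx
    if j in poles:
        # a pole is one logical point: its neighbors are every cell in the
        # adjacent theta row (and it connects to all phi of its own row,
        # which all carry the same logical energy)
        jn = j + 1 if j == 0 else j - 1
        for ii in range(shape[0]):
            yield (ii, jn)
        return
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            ii, jj = i + di, j + dj
            if fes.periodic[0]:
                ii %= shape[0]
            elif not 0 <= ii < shape[0]:
                continue
            if not 0 <= jj < shape[1]:
                continue
            yield (ii, jj)


def find_minima(fes: FreeEnergySurface, depth_tol: float = 0.5) -> list[StationaryPoint]:
    """All grid-local minima deeper than ``depth_tol``.

    Minima are found by topographic persistence: cells are flooded in
    order of increasing energy (8-connectivity, periodic wrap and pole
    identification respected) and components are merged union-find style.
    A basin survives when the saddle level at which it merges into a
    deeper basin lies more than ``depth_tol`` above its own minimum;
    shallower basins are grid noise and are absorbed.  The global minimum
    always survives.  Results are sorted by energy.
    """
    v = fes.values
    if np.allclose(v, v.flat[0]):
        warnings.warn("flat surface: no minima")
        return []
    poles = _pole_rows(fes)

    def node_of(idx: tuple[int, ...]) -> tuple[int, ...]:
        # collapse each pole row to a single representative node
        if fes.ndim == 2 and idx[1] in poles:
            return (0, idx[1])
        return idx

    cells = [node_of(idx) for idx in np.ndindex(v.shape)]
    order = sorted(set(cells), key=lambda idx: (float(v[idx]), idx))

    parent: dict[tuple[int, ...], tuple[int, ...]] = {}
    comp_min: dict[tuple[int, ...], tuple[float, tuple[int, ...]]] = {}

    def find(x):
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    survivors: list[tuple[float, tuple[int, ...]]] = []
    for idx in order:
        level = float(v[idx])
        roots = set()
        for n in _neighbors(fes, idx):
            n = node_of(n)
            if n in parent:
                roots.add(find(n))
        parent[idx] = idx
        if not roots:
            comp_min[idx] = (level, idx)
            continue
        # merge into the deepest neighboring component
        roots = sorted(roots, key=lambda r: comp_min[r])
        target = roots[0]
        parent[idx] = target
        for other in roots[1:]:
            death = level - comp_min[other][0]
            if death > depth_tol:
                survivors.append(comp_min[other])
            parent[other] = target
    # the last standing component holds the global minimum
    final_roots = {find(idx) for idx in parent}
    for root in final_roots:
        survivors.append(comp_min[root])
    survivors = sorted(set(survivors))
    return [
        StationaryPoint(
            kind="minimum",
            index=idx,
            location=fes.point(idx),
            energy=energy,
            basin_id=rank,
        )
        for rank, (energy, idx) in enumerate(survivors)
    ]


def _minimax(
    fes: FreeEnergySurface,
    start: tuple[int, ...],
    goals: tuple[tuple[int, ...], ...],
):
    """Dijkstra with max-cost composition from start to the nearest goal.

    Returns (minimax energy, goal reached, predecessor map).  The cost of
    a path is the maximum energy along it; ties are broken toward smaller
    accumulated energy so recovered paths hug the valley floor.
    """
    v = fes.values
    goal_set = set(goals)
    best: dict[tuple[int, ...], tuple[float, float]] = {}
    prev: dict[tuple[int, ...], tuple[int, ...] | None] = {start: None}
    h0 = (float(v[start]), 0.0)
    pq = [(h0[0], h0[1], start)]
    best[start] = h0
    while pq:
        cmax, csum, idx = heapq.heappop(pq)
        if best.get(idx, (math.inf, math.inf)) < (cmax, csum):
            continue
        if idx in goal_set:
            return cmax, idx, prev
        for n in _neighbors(fes, idx):
            ncost = (max(cmax, float(v[n])), csum + float(v[n]))
            if ncost < best.get(n, (math.inf, math.inf)):
                best[n] = ncost
                prev[n] = idx
                heapq.heappush(pq, (ncost[0], ncost[1], n))
    raise ValueError("grid is disconnected: no path between the given minima")


def minimax_barrier(
    fes: FreeEnergySurface,
    a: StationaryPoint | tuple[int, ...],
    b: StationaryPoint | tuple[int, ...],
) -> tuple[float, StationaryPoint]:
    """Lowest possible path maximum from minimum a to minimum b.

    Returns (barrier relative to a, saddle point).  The saddle is the
    arg-max cell on the optimal path; by the shared-saddle identity,
    barrier(a->b) - barrier(b->a) == E(a) - E(b).
    """
    ia = a.index if isinstance(a, StationaryPoint) else tuple(a)
    ib = b.index if isinstance(b, StationaryPoint) else tuple(b)
    if ia == ib:
        sp = StationaryPoint("saddle", ia, fes.point(ia), fes.energy(ia))
        return 0.0, sp
    cmax, _goal, prev = _minimax(fes, ia, (ib,))
    path = _walk_back(prev, ib)
    k = int(np.argmax([fes.energy(i) for i in path]))
    saddle = StationaryPoint(
        kind="saddle", index=path[k], location=fes.point(path[k]), energy=fes.energy(path[k])
    )
    return cmax - fes.energy(ia), saddle


def _walk_back(prev, end):
    path = [end]
    while prev[path[-1]] is not None:
        path.append(prev[path[-1]])
    path.reverse()
    return path


def _descend(fes: FreeEnergySurface, idx: tuple[int, ...]):
    """Discrete steepest descent to a local minimum."""
    path = [idx]
    while True:
        here = path[-1]
        nbrs = list(_neighbors(fes, here))
        down = min(nbrs, key=lambda n: fes.energy(n))
        if fes.energy(down) >= fes.energy(here):
            return path
        path.append(down)


def minimum_energy_path(
    fes: FreeEnergySurface,
    a: StationaryPoint | tuple[int, ...],
    b: StationaryPoint | tuple[int, ...],
) -> ItineraryPath:
    """Minimax-optimal path from a to b, relaxed by steepest descent.

    The saddle is located on the Dijkstra path; from it, steepest-descent
    segments run toward each side.  When a descent segment fails to reach
    the requested endpoint the Dijkstra path segment is used instead, so
    the returned path always connects a and b through the saddle.
    """
    ia = a.index if isinstance(a, StationaryPoint) else tuple(a)
    ib = b.index if isinstance(b, StationaryPoint) else tuple(b)
    _, _goal, prev = _minimax(fes, ia, (ib,))
    dijkstra = _walk_back(prev, ib)
    k = int(np.argmax([fes.energy(i) for i in dijkstra]))
    saddle = dijkstra[k]

    def _same_logical(i1, i2):
        if i1 == i2:
            return True
        poles = _pole_rows(fes)
        return fes.ndim == 2 and i1[1] in poles and i1[1] == i2[1]

    def _relaxed_side(seed, endpoint, fallback):
        if seed is None:
            return [saddle]
        seg = [saddle] + _descend(fes, seed)
        return seg if _same_logical(seg[-1], endpoint) else fallback

    left = _relaxed_side(
        dijkstra[k - 1] if k > 0 else None, ia, list(reversed(dijkstra[: k + 1]))
    )
    right = _relaxed_side(
        dijkstra[k + 1] if k < len(dijkstra) - 1 else None, ib, dijkstra[k:]
    )
    indices = list(reversed(left)) + right[1:]
    if not _same_logical(indices[0], ia):
        indices = [ia] + indices
    if not _same_logical(indices[-1], ib):
        indices = indices + [ib]
    energies = tuple(fes.energy(i) for i in indices)
    saddle_pos = int(np.argmax(energies))
    return ItineraryPath(
        indices=tuple(indices),
        points=tuple(fes.point(i) for i in indices),
        energies=energies,
        saddle_position=saddle_pos,
    )


def _as_pucker(point: tuple[float, ...]) -> PuckerCoordinates:
    phi, theta = point[0], point[1]
    return PuckerCoordinates(Q=0.55, theta=theta, phi=phi % 360.0, q2=0.0, q3=0.0)


def assign_itinerary(
    path: ItineraryPath,
    catalog: ConformerCatalog | None = None,
    tie_tol: float = 10.0,
    station_radius: float = 10.0,
) -> str:
    """Conformational itinerary string along a puckering-surface path.

    Every path point is classified against the catalog; points count as
    stations when the path actually visits a reference conformer (nearest
    distance below ``station_radius`` degrees) — the endpoints and the
    saddle always count.  Consecutive duplicate labels are collapsed and
    the saddle's label is bracketed as the transition state, yielding the
    grammar "1,4B/1S3 -> [4E]++ -> 4C1" (with the dagger rendered as ‡).

    Raises if the path does not lie on a (phi, theta) surface (itineraries
    are defined on the puckering sphere only).
    """
    if len(path.points) == 0 or len(path.points[0]) != 2:
        raise ValueError("itinerary assignment requires a (phi, theta) surface path")
    if catalog is None:
        catalog = load_catalog()
    stations: list[tuple[str, int]] = []  # (label, path position)
    for pos, point in enumerate(path.points):
        asg = classify_conformation(_as_pucker(point), catalog, tie_tol=tie_tol)
        is_endpoint = pos in (0, len(path.points) - 1)
        is_saddle = pos == path.saddle_position
        if is_endpoint or is_saddle or asg.distance_deg <= station_radius:
            stations.append((asg.label, pos))
    # collapse consecutive duplicates, remembering which group holds the saddle
    groups: list[tuple[str, bool]] = []
    for label, pos in stations:
        holds_saddle = pos == path.saddle_position
        if groups and groups[-1][0] == label:
            groups[-1] = (label, groups[-1][1] or holds_saddle)
        else:
            groups.append((label, holds_saddle))
    if len(groups) == 1:
        warnings.warn("single-basin path: no transition state to mark")
        return groups[0][0]
    parts = [f"[{label}]‡" if holds_saddle else label for label, holds_saddle in groups]
    return " → ".join(parts)


def region_energy(
    fes: FreeEnergySurface,
    label: str,
    catalog: ConformerCatalog | None = None,
    radius_deg: float = 5.0,
) -> float:
    """Lowest free energy within a geodesic radius of a conformer's position.

    Reported relative to the surface's global minimum.
    """
    if not fes.is_pucker_surface:
        raise ValueError("region_energy requires a (phi, theta) puckering surface")
    if catalog is None:
        catalog = load_catalog()
    entry = catalog[label]
    phi, theta = fes.axes
    pp, tt = np.meshgrid(phi, theta, indexing="ij")
    cosd = np.cos(np.radians(tt)) * math.cos(math.radians(entry.theta_ref)) + np.sin(
        np.radians(tt)
    ) * math.sin(math.radians(entry.theta_ref)) * np.cos(
        np.radians(pp) - math.radians(entry.phi_ref)
    )
    mask = np.degrees(np.arccos(np.clip(cosd, -1, 1))) <= radius_deg
    if not mask.any():
        raise ValueError(
            f"no grid cells within {radius_deg} deg of {label}; radius too small for grid"
        )
    return float(fes.values[mask].min() - fes.values.min())


def export_mercator(
    fes: FreeEnergySurface,
    isoline_step: float = 1.0,
    png_path: str | None = None,
    data_path: str | None = None,
    path: ItineraryPath | None = None,
):
    """Mercator contour representation of a puckering free-energy surface.

    phi on the abscissa [0, 360), theta on the ordinate plotted top-to-
    bottom so the 4C1 pole is at the top.  Contour levels are multiples of
    ``isoline_step`` (default 1 kcal/mol).  Returns the contour levels;
    optionally writes a PNG and a tab-separated ``phi theta F`` table.
    """
    if fes.ndim != 2:
        raise ValueError("Mercator export requires a 2D (phi, theta) surface")
    vmax = float(fes.values.max())
    levels = np.arange(0.0, vmax + isoline_step, isoline_step)
    if len(levels) < 2:
        levels = np.array([0.0, isoline_step])
    if data_path is not None:
        phi, theta = fes.axes
        with open(data_path, "w") as fh:
            fh.write(f"# {fes.axis_names[0]}\t{fes.axis_names[1]}\tF_kcal_per_mol\n")
            for i, p in enumerate(phi):
                for j, t in enumerate(theta):
                    fh.write(f"{p:.6g}\t{t:.6g}\t{fes.values[i, j]:.9g}\n")
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4))
        phi, theta = fes.axes
        cs = ax.contourf(phi, theta, fes.values.T, levels=levels, cmap="viridis")
        ax.contour(phi, theta, fes.values.T, levels=levels, colors="k", linewidths=0.4)
        if path is not None:
            pts = np.array(path.points)
            ax.plot(pts[:, 0], pts[:, 1], "r.-", ms=3, lw=1)
        ax.set_xlabel("phi (deg)")
        ax.set_ylabel("theta (deg)")
        ax.set_ylim(fes.axes[1][-1], fes.axes[1][0])  # 4C1 pole on top
        fig.colorbar(cs, ax=ax, label="F (kcal/mol)")
        fig.tight_layout()
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
    return levels
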