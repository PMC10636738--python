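"""Readers and writers: structures/trajectories (PDB, XYZ), HILLS-style
metadynamics logs, FES grid text, tab-separated reports and JSON sidecars.

Structure and trajectory parsing is delegated to MDAnalysis; this module
adds ring/role selection resolution and keeps all user-facing indices
1-based (internal indices are 0-based).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .metad import Hill, HillsLog
from .fes import FreeEnergySurface
from .ring import DEFAULT_RING_LABELS

__all__ = [
    "TrajectoryHandle",
    "read_structure",
    "resolve_ring_indices",
    "write_ring_trajectory",
    "read_hills",
    "write_hills",
    "read_fes",
    "write_fes",
    "write_pucker_report",
    "write_manifest",
]


@dataclass
class TrajectoryHandle:
    """A loaded multi-frame structure with atom metadata."""

    source: str
    atom_names: tuple[str, ...]
    resnames: tuple[str, ...]
    resids: tuple[int, ...]
    frames: np.ndarray  # (n_frames, n_atoms, 3), Å

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.frames.shape[1])

    def __iter__(self):
        return iter(self.frames)


def read_structure(path: str | Path) -> TrajectoryHandle:
    """Read a (multi-model) PDB or (multi-frame) XYZ file.

    Coordinates are Å; the atom count must be constant across frames
    (MDAnalysis enforces this).
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"structure file not found: {path}")
    u = mda.Universe(str(path))
    frames = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
    try:
        resnames = tuple(str(r) for r in u.atoms.resnames)
        resids = tuple(int(r) for r in u.atoms.resids)
    except Exception:  # XYZ files carry no residue metadata
        resnames = tuple("UNK" for _ in range(len(u.atoms)))
        resids = tuple(1 for _ in range(len(u.atoms)))
    return TrajectoryHandle(
        source=str(path),
        atom_names=tuple(str(n) for n in u.atoms.names),
        resnames=resnames,
        resids=resids,
        frames=frames,
    )


def resolve_ring_indices(
    handle: TrajectoryHandle,
    ring_atoms=DEFAULT_RING_LABELS,
    resname: str | None = None,
    resid: int | None = None,
) -> list[int]:
    """Resolve the six ring atoms (in ring order) to 0-based indices.

    Raises naming the first missing atom; ambiguous selections (an atom
    name matching several times within the selection) also raise.
    """
    indices = []
    for name in ring_atoms:
        matches = [
            i
            for i in range(handle.n_atoms)
            if handle.atom_names[i] == name
            and (resname is None or handle.resnames[i] == resname)
            and (resid is None or handle.resids[i] == resid)
        ]
        if not matches:
            where = f" in residue {resname or ''}{resid or ''}".rstrip()
            raise KeyError(f"ring atom '{name}' not found{where} in {handle.source}")
        if len(matches) > 1:
            raise KeyError(
                f"ring atom '{name}' is ambiguous ({len(matches)} matches); "
                "narrow the selection with a residue name/id"
            )
        indices.append(matches[0])
    return indices


def write_ring_trajectory(
    path: str | Path,
    coords: np.ndarray,
    atom_names=DEFAULT_RING_LABELS,
    resname: str = "NAG",
) -> None:
    """Write ring frames as multi-model PDB or multi-frame XYZ (by suffix)."""
    import MDAnalysis as mda

    path = Path(path)
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n_atoms = coords.shape[1]
    u = mda.Universe.empty(n_atoms, n_residues=1, atom_resindex=[0] * n_atoms, trajectory=True)
    u.add_TopologyAttr("names", list(atom_names))
    u.add_TopologyAttr("resnames", [resname])
    u.add_TopologyAttr("resids", [1])
    u.add_TopologyAttr("elements", [n.strip("0123456789") or "C" for n in atom_names])
    u.load_new(coords, order="fac")
    with mda.Writer(str(path), n_atoms, multiframe=True) as w:
        for _ in u.trajectory:
            w.write(u.atoms)


# ---------------------------------------------------------------------------
# HILLS-style logs
#
# Dialect: a header line `#! FIELDS time <cv names...> <sigma_...> height
# biasf`, optional `#! SET periodic_<cv> <period|none>` lines, then one
# whitespace-separated row per hill.  Floats are written with repr
# precision so write -> read roundtrips bit-exactly.


def write_hills(log: HillsLog, path: str | Path) -> None:
    path = Path(path)
    names = list(log.cv_names)
    cols = ["time", *names, *[f"sigma_{n}" for n in names], "height", "biasf"]
    lines = ["#! FIELDS " + " ".join(cols)]
    for name, period in zip(names, log.periods):
        lines.append(f"#! SET periodic_{name} {period if period is not None else 'none'}")
    for h in log.hills:
        row = [repr(h.time), *[repr(c) for c in h.center], *[repr(s) for s in h.sigma]]
        row += [repr(h.height), repr(log.bias_factor)]
        lines.append(" ".join(row))
    path.write_text("\n".join(lines) + "\n")


def read_hills(path: str | Path) -> HillsLog:
    path = Path(path)
    names: list[str] = []
    periods: list[float | None] = []
    hills: list[Hill] = []
    bias_factor = math.inf
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#! FIELDS"):
                cols = line.split()[2:]
                ndim = (len(cols) - 3) // 2
                names = cols[1 : 1 + ndim]
                periods = [None] * ndim
                continue
            if line.startswith("#! SET periodic_"):
                key, val = line.split()[2:]
                cv = key.removeprefix("periodic_")
                if cv in names:
                    periods[names.index(cv)] = None if val == "none" else float(val)
                continue
            if line.startswith("#"):
                continue
            parts = line.split()
            ndim = len(names) or (len(parts) - 3) // 2
            if len(parts) != 2 * ndim + 3:
                raise ValueError(f"{path}:{lineno}: malformed hill line ({len(parts)} fields)")
            try:
                time = int(float(parts[0]))
                center = tuple(float(x) for x in parts[1 : 1 + ndim])
                sigma = tuple(float(x) for x in parts[1 + ndim : 1 + 2 * ndim])
                height = float(parts[1 + 2 * ndim])
                bias_factor = float(parts[2 + 2 * ndim])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed hill line: {exc}") from None
            hills.append(Hill(time=time, center=center, sigma=sigma, height=height))
    if not names:
        names = ["cv1"]
        periods = [None]
    return HillsLog(
        hills=hills,
        cv_names=tuple(names),
        periods=tuple(periods),
        bias_factor=bias_factor,
    )


# ---------------------------------------------------------------------------
# FES grids


def write_fes(fes: FreeEnergySurface, path: str | Path) -> None:
    """Grid text: axis declarations in the header, then `dim1 [dim2] F` rows."""
    path = Path(path)
    with open(path, "w") as fh:
        for d in range(fes.ndim):
            a = fes.axes[d]
            fh.write(
                f"# axis {fes.axis_names[d]} n={len(a)} min={float(a[0])!r} "
                f"max={float(a[-1])!r} periodic={int(fes.periodic[d])}\n"
            )
        fh.write("# columns: " + " ".join(fes.axis_names) + " F_kcal_per_mol\n")
        if fes.ndim == 1:
            for x, v in zip(fes.axes[0], fes.values):
                fh.write(f"{float(x)!r} {float(v)!r}\n")
        else:
            for i, x in enumerate(fes.axes[0]):
                for j, y in enumerate(fes.axes[1]):
                    fh.write(f"{float(x)!r} {float(y)!r} {float(fes.values[i, j])!r}\n")


def read_fes(path: str | Path) -> FreeEnergySurface:
    path = Path(path)
    axes_meta = []
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("# axis "):
                parts = dict(p.split("=") for p in line.split()[3:])
                name = line.split()[2]
                axes_meta.append(
                    (name, int(parts["n"]), float(parts["min"]), float(parts["max"]),
                     bool(int(parts["periodic"])))
                )
            elif not line or line.startswith("#"):
                continue
            else:
                rows.append([float(x) for x in line.split()])
    if not axes_meta:
        raise ValueError(f"{path}: missing axis declarations")
    data = np.asarray(rows)
    axes = tuple(np.linspace(lo, hi, n) for _name, n, lo, hi, _p in axes_meta)
    shape = tuple(len(a) for a in axes)
    values = data[:, -1].reshape(shape)
    return FreeEnergySurface(
        axes=axes,
        values=values,
        periodic=tuple(p for *_x, p in axes_meta),
        axis_names=tuple(name for name, *_x in axes_meta),
    )


# ---------------------------------------------------------------------------
# reports and manifests


def write_pucker_report(path: str | Path, series, assignments=None) -> None:
    """Per-frame puckering report (frame indices 1-based in the report)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# frame indices are 1-based; angles deg, amplitudes Å\n")
        header = "frame\tQ\ttheta\tphi"
        if assignments is not None:
            header += "\tlabel\tdistance_deg"
        fh.write(header + "\n")
        for i, p in enumerate(series, start=1):
            if p is None:
                row = f"{i}\tNA\tNA\tNA"
                if assignments is not None:
                    row += "\tNA\tNA"
            else:
                row = f"{i}\t{p.Q:.6f}\t{p.theta:.4f}\t{p.phi:.4f}"
                if assignments is not None:
                    a = assignments[i - 1]
                    row += (
                        f"\t{a.label}\t{a.distance_deg:.4f}" if a is not None else "\tNA\tNA"
                    )
            fh.write(row + "\n")


def write_manifest(path: str | Path, **entries) -> None:
    """JSON run manifest (inputs, parameters, package version)."""
    from . import __version__

    payload = {"package": "glycopucker", "version": __version__, **entries}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
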