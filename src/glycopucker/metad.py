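"""Desk-scale metadynamics in collective-variable space.

Overdamped Langevin dynamics on analytic model potentials in one or two
CV dimensions, with Gaussian hill deposition (standard or well-tempered)
and free-energy reconstruction from the accumulated bias.  The engine
works entirely in CV space: its purpose is to exercise and validate the
reconstruction and landscape-analysis machinery on potentials whose
minima and saddles are known in closed form, not to emulate atomistic
forces.

Units: energies kcal/mol, temperature expressed as k_B*T in kcal/mol
(0.596 kcal/mol is ~300 K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Hill",
    "HillsLog",
    "LangevinParams",
    "WellTemperedParams",
    "ModelPotential",
    "bias_energy",
    "run_metadynamics",
    "reconstruct_fes",
]

KT_ROOM = 0.596  # k_B * 300 K in kcal/mol


@dataclass(frozen=True)
class Hill:
    """One deposited Gaussian: V(s) = height * exp(-sum_d dx_d^2 / (2 sigma_d^2))."""

    time: int
    center: tuple[float, ...]
    sigma: tuple[float, ...]
    height: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        object.__setattr__(self, "sigma", tuple(float(s) for s in self.sigma))
        if len(self.center) != len(self.sigma):
            raise ValueError("center and sigma dimensionality differ")
        if any(s <= 0 for s in self.sigma):
            raise ValueError("hill sigma must be positive")
        if self.height < 0:
            raise ValueError("hill height must be non-negative")


@dataclass
class HillsLog:
    """A sequence of hills plus the metadata needed to reuse them.

    ``periods`` holds, per CV dimension, the period length for periodic
    dimensions and None otherwise.  ``bias_factor`` is the well-tempered
    gamma used during deposition (inf for standard metadynamics).
    """

    hills: list[Hill] = field(default_factory=list)
    cv_names: tuple[str, ...] = ("cv1",)
    periods: tuple[float | None, ...] = (None,)
    bias_factor: float = math.inf

    def __len__(self) -> int:
        return len(self.hills)

    def __iter__(self):
        return iter(self.hills)

    @property
    def ndim(self) -> int:
        return len(self.cv_names)


@dataclass(frozen=True)
class LangevinParams:
    """Overdamped Langevin parameters.

    temperature is k_B*T in kcal/mol; friction in 1/time units fixes the
    mobility mu = 1/friction; the displacement per step is
    -mu * grad(U) * dt + sqrt(2 * kT * mu * dt) * xi.
    """

    temperature: float = KT_ROOM
    friction: float = 1.0
    timestep: float = 1e-3
    n_steps: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature <= 0 or self.friction <= 0 or self.timestep <= 0:
            raise ValueError("temperature, friction and timestep must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")


@dataclass(frozen=True)
class WellTemperedParams:
    """Bias factor gamma > 1; gamma = inf recovers standard metadynamics."""

    bias_factor: float = math.inf

    def __post_init__(self) -> None:
        if not self.bias_factor > 1:
            raise ValueError("bias factor gamma must be > 1 (inf for standard)")


@dataclass
class ModelPotential:
    """Closed-form potential over 1-2 CVs.

    ``energy`` maps an array of shape (..., ndim) (or scalar-like for 1D)
    to kcal/mol; ``gradient`` is optional (central differences otherwise).
    ``bounds`` is ((lo, hi), ...) per dimension; ``periods`` per-dimension
    period length or None (non-periodic dimensions reflect at the bounds).
    """

    energy: Callable[[np.ndarray], np.ndarray]
    bounds: tuple[tuple[float, float], ...]
    periods: tuple[float | None, ...] | None = None
    gradient: Callable[[np.ndarray], np.ndarray] | None = None
    name: str = "model"

    def __post_init__(self) -> None:
        if self.periods is None:
            self.periods = tuple(None for _ in self.bounds)
        if len(self.periods) != len(self.bounds):
            raise ValueError("periods and bounds dimensionality differ")

    @property
    def ndim(self) -> int:
        return len(self.bounds)

    def grad(self, s: np.ndarray, h: float = 1e-5) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        if self.gradient is not None:
            return np.asarray(self.gradient(s), dtype=float)
        g = np.empty_like(s)
        for d in range(s.size):
            sp, sm = s.copy(), s.copy()
            sp[d] += h
            sm[d] -= h
            g[d] = (float(self.energy(sp)) - float(self.energy(sm))) / (2 * h)
        return g


def _min_image(delta: np.ndarray, periods: Sequence[float | None]) -> np.ndarray:
    delta = np.array(delta, dtype=float, copy=True)
    for d, period in enumerate(periods):
        if period is not None:
            delta[..., d] -= period * np.round(delta[..., d] / period)
    return delta


def bias_energy(
    hills: HillsLog | Sequence[Hill],
    s,
    periods: Sequence[float | None] | None = None,
) -> float | np.ndarray:
    """Sum of deposited Gaussians at point(s) ``s``.

    ``s`` may be a single CV point (shape (ndim,)) or an array of points
    (..., ndim).  Periodic dimensions use the minimum-image convention.
    """
    if isinstance(hills, HillsLog):
        if periods is None:
            periods = hills.periods
        hill_seq = hills.hills
    else:
        hill_seq = list(hills)
    s = np.atleast_2d(np.asarray(s, dtype=float))
    if hill_seq and s.shape[-1] != len(hill_seq[0].center):
        raise ValueError(
            f"CV point dimensionality {s.shape[-1]} does not match hills "
            f"({len(hill_seq[0].center)})"
        )
    if periods is None:
        periods = tuple(None for _ in range(s.shape[-1]))
    v = np.zeros(s.shape[:-1])
    for hill in hill_seq:
        delta = _min_image(s - np.asarray(hill.center), periods)
        v += hill.height * np.exp(-0.5 * np.sum((delta / np.asarray(hill.sigma)) ** 2, axis=-1))
    return float(v[0]) if v.size == 1 else v


class _GridBias:
    """Accumulated bias on a regular grid with linear interpolation.

    Depositing a hill adds its Gaussian to the grid once (vectorized); the
    per-step bias force is then O(1) in the number of hills.
    """

    def __init__(self, bounds, periods, n_per_dim=601):
        self.bounds = bounds
        self.periods = periods
        self.axes = [np.linspace(lo, hi, n_per_dim) for lo, hi in bounds]
        shape = tuple(len(a) for a in self.axes)
        self.values = np.zeros(shape)
        if len(bounds) == 1:
            self.mesh = self.axes[0][:, None]
        else:
            g = np.meshgrid(*self.axes, indexing="ij")
            self.mesh = np.stack(g, axis=-1)

    def deposit(self, hill: Hill) -> None:
        delta = _min_image(self.mesh - np.asarray(hill.center), self.periods)
        self.values += hill.height * np.exp(
            -0.5 * np.sum((delta / np.asarray(hill.sigma)) ** 2, axis=-1)
        )

    def _locate(self, x: float, d: int) -> tuple[int, float]:
        a = self.axes[d]
        step = a[1] - a[0]
        u = (x - a[0]) / step
        i = int(np.clip(np.floor(u), 0, len(a) - 2))
        return i, u - i

    def value_and_grad(self, s: np.ndarray) -> tuple[float, np.ndarray]:
        if len(self.axes) == 1:
            i, f = self._locate(float(s[0]), 0)
            v0, v1 = self.values[i], self.values[i + 1]
            step = self.axes[0][1] - self.axes[0][0]
            return float(v0 + f * (v1 - v0)), np.array([(v1 - v0) / step])
        (i, fx), (j, fy) = self._locate(float(s[0]), 0), self._locate(float(s[1]), 1)
        v = self.values
        v00, v10, v01, v11 = v[i, j], v[i + 1, j], v[i, j + 1], v[i + 1, j + 1]
        dx = self.axes[0][1] - self.axes[0][0]
        dy = self.axes[1][1] - self.axes[1][0]
        val = (
            v00 * (1 - fx) * (1 - fy)
            + v10 * fx * (1 - fy)
            + v01 * (1 - fx) * fy
            + v11 * fx * fy
        )
        gx = ((v10 - v00) * (1 - fy) + (v11 - v01) * fy) / dx
        gy = ((v01 - v00) * (1 - fx) + (v11 - v10) * fx) / dy
        return float(val), np.array([gx, gy])


def _apply_boundaries(s: np.ndarray, bounds, periods) -> np.ndarray:
    for d, ((lo, hi), period) in enumerate(zip(bounds, periods)):
        if period is not None:
            s[d] = lo + (s[d] - lo) % period
        else:
            # reflect at the walls (possibly repeatedly for large kicks)
            while s[d] < lo or s[d] > hi:
                if s[d] < lo:
                    s[d] = 2 * lo - s[d]
                if s[d] > hi:
                    s[d] = 2 * hi - s[d]
    return s


def run_metadynamics(
    potential: ModelPotential,
    lp: LangevinParams,
    pace: int = 500,
    hill_height: float = 0.2,
    hill_sigma: float | Sequence[float] = 0.1,
    wt: WellTemperedParams | None = None,
    s0: Sequence[float] | None = None,
    cv_names: tuple[str, ...] | None = None,
    traj_stride: int = 10,
) -> tuple[np.ndarray, HillsLog]:
    """Biased overdamped Langevin run; returns (CV trajectory, hills log).

    A hill is deposited every ``pace`` steps at the current point; with
    well-tempered parameters the height is scaled by
    exp(-V_bias / ((gamma - 1) k_B T)).  Identical inputs and seed give
    bit-identical output.  The trajectory is sampled every ``traj_stride``
    steps (the initial point included).
    """
    if pace < 1:
        raise ValueError("pace must be >= 1")
    ndim = potential.ndim
    sigma = np.broadcast_to(np.asarray(hill_sigma, dtype=float), (ndim,)).copy()
    gamma = wt.bias_factor if wt is not None else math.inf
    rng = np.random.default_rng(lp.seed)
    mu = 1.0 / lp.friction
    dt = lp.timestep
    noise_amp = math.sqrt(2.0 * lp.temperature * mu * dt)

    if s0 is None:
        s = np.array([0.5 * (lo + hi) for lo, hi in potential.bounds])
    else:
        s = np.asarray(s0, dtype=float).copy()
    names = cv_names or tuple(f"cv{d + 1}" for d in range(ndim))
    log = HillsLog(cv_names=names, periods=tuple(potential.periods), bias_factor=gamma)
    bias = _GridBias(potential.bounds, potential.periods, n_per_dim=601 if ndim == 1 else 161)

    traj = []
    for step in range(lp.n_steps):
        if step % traj_stride == 0:
            traj.append(s.copy())
        vb, gb = bias.value_and_grad(s)
        g = potential.grad(s) + gb
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(
                f"non-finite force at s={s} (step {step}); "
                "check potential domain and timestep"
            )
        s = s - mu * g * dt + noise_amp * rng.standard_normal(ndim)
        s = _apply_boundaries(s, potential.bounds, potential.periods)
        if (step + 1) % pace == 0:
            vb, _ = bias.value_and_grad(s)
            h = hill_height
            if math.isfinite(gamma):
                h *= math.exp(-vb / ((gamma - 1.0) * lp.temperature))
            hill = Hill(time=step + 1, center=tuple(s), sigma=tuple(sigma), height=h)
            log.hills.append(hill)
            bias.deposit(hill)
    if lp.n_steps > 0:
        traj.append(s.copy())
    return np.asarray(traj), log


def reconstruct_fes(
    hills: HillsLog,
    axes: Sequence[np.ndarray],
    wt: WellTemperedParams | None = None,
    average_tail: float = 0.0,
):
    """Free-energy estimate on a grid from a hills log.

    Standard metadynamics: F(s) = -V_bias(s).  Well-tempered: the bias
    converges to -(1 - 1/gamma) F, so F(s) = -(gamma/(gamma-1)) V_bias(s).
    The surface is shifted so its minimum is 0.

    ``average_tail`` in (0, 1] switches on tail averaging: the (shifted)
    estimate is averaged over deposition checkpoints spanning the last
    fraction of the run, damping the oscillation of the instantaneous
    bias around the converged profile.  Returns a ``FreeEnergySurface``
    (see :mod:`glycopucker.fes`).
    """
    from .fes import FreeEnergySurface

    axes = [np.asarray(a, dtype=float) for a in axes]
    gamma = wt.bias_factor if wt is not None else hills.bias_factor
    if len(axes) == 1:
        pts = axes[0][:, None]
    else:
        g = np.meshgrid(*axes, indexing="ij")
        pts = np.stack(g, axis=-1)
    shape = tuple(len(a) for a in axes)
    scale = gamma / (gamma - 1.0) if math.isfinite(gamma) else 1.0
    if len(hills) == 0:
        import warnings

        warnings.warn("empty hills log: returning a flat zero surface")
        values = np.zeros(shape)
    elif not 0.0 < average_tail <= 1.0:
        values = -scale * np.atleast_1d(np.asarray(bias_energy(hills, pts), dtype=float))
    else:
        n = len(hills)
        start = max(1, int(round(n * (1.0 - average_tail))))
        checkpoints = np.unique(np.linspace(start, n, min(40, n - start + 1), dtype=int))
        v = np.atleast_1d(np.asarray(bias_energy(hills.hills[:start], pts, hills.periods)))
        acc = np.zeros(v.shape)
        prev = start
        n_chk = 0
        for chk in checkpoints:
            if chk > prev:
                v = v + np.atleast_1d(
                    np.asarray(bias_energy(hills.hills[prev:chk], pts, hills.periods))
                )
                prev = chk
            est = -scale * v
            acc += est - est.min()
            n_chk += 1
        values = acc / n_chk
    fes = FreeEnergySurface(
        axes=tuple(axes),
        values=values.reshape(shape),
        periodic=tuple(p is not None for p in hills.periods),
        axis_names=hills.cv_names,
    )
    return fes.normalized()
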