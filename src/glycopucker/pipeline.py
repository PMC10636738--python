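"""End-to-end recovery pipelines shared by the analysis scripts and tests.

Each function generates its inputs with the synthetic-data module, runs
the full method (sampling, reconstruction, landscape analysis) and
returns the measured quantities next to the generator's ground truth.
"""

from __future__ import annotations

import numpy as np

from .fes import (
    assign_itinerary,
    find_minima,
    minimax_barrier,
    minimum_energy_path,
)
from .metad import KT_ROOM, LangevinParams, WellTemperedParams, reconstruct_fes, run_metadynamics
from .solvation import occupancy_fraction
from .synthetic import (
    Basin,
    FELSpec,
    ReactionProfileSpec,
    make_fel,
    make_reaction_profile,
    make_water_trajectory,
)

__all__ = [
    "recover_reaction_profile",
    "designed_fel_itinerary",
    "water_occupancy_recovery",
]


def recover_reaction_profile(
    barrier: float,
    reaction_dg: float,
    seed: int,
    n_steps: int = 1_200_000,
    pace: int = 250,
    hill_height: float = 0.12,
    hill_sigma: float = 0.07,
) -> dict:
    """Metadynamics recovery of a designed double-well reaction profile.

    Builds the exact analytic profile, runs well-tempered metadynamics
    from the reactant well, reconstructs the free energy with tail
    averaging, and measures the forward barrier and reaction free energy
    from the reconstructed surface's minima.  The well-tempered bias
    factor is sized to the designed energy range
    (gamma = 1 + (range + 8 kcal/mol) / kT).
    """
    pot = make_reaction_profile(ReactionProfileSpec(barrier=barrier, reaction_dg=reaction_dg))
    gamma = 1.0 + (barrier - min(0.0, reaction_dg) + 8.0) / KT_ROOM
    lp = LangevinParams(n_steps=n_steps, seed=seed)
    wt = WellTemperedParams(bias_factor=gamma)
    _traj, log = run_metadynamics(
        pot, lp, pace=pace, hill_height=hill_height, hill_sigma=hill_sigma, wt=wt,
        s0=[pot.bounds[0][0] + 0.8],
    )
    axes = [np.linspace(pot.bounds[0][0], pot.bounds[0][1], 401)]
    fes = reconstruct_fes(log, axes, wt=wt, average_tail=0.5)
    minima = find_minima(fes, depth_tol=1.0)
    xts = 0.5 * sum(pot.bounds[0]) / 1.0  # wells are symmetric about the midpoint
    reactant = min(
        (m for m in minima if m.location[0] < xts), key=lambda m: m.energy, default=None
    )
    product = min(
        (m for m in minima if m.location[0] >= xts), key=lambda m: m.energy, default=None
    )
    if reactant is None or product is None:
        raise RuntimeError("metadynamics run did not resolve both basins")
    b_fwd, saddle = minimax_barrier(fes, reactant, product)
    return {
        "barrier_true": barrier,
        "barrier": float(b_fwd),
        "reaction_dg_true": reaction_dg,
        "reaction_dg": float(product.energy - reactant.energy),
        "saddle_position": saddle.location[0],
        "n_hills": len(log),
        "fes": fes,
        "hills": log,
    }


def designed_fel_itinerary(
    saddle_energy: float = 5.0,
    chair_offset: float = 0.5,
    tie_tol: float = 10.0,
) -> dict:
    """Itinerary recovery on a designed puckering landscape.

    The landscape has a basin at the boat/twist-boat midpoint (the
    preactivated Michaelis conformation), a basin at the 4C1 chair
    ``chair_offset`` kcal/mol higher, and a designed saddle at the 4E
    envelope.  Returns the forward and reverse itinerary strings and the
    measured barrier.
    """
    spec = FELSpec(
        basins=(Basin("1,4B/1S3", energy=0.0), Basin("4C1", energy=chair_offset)),
        saddle=("4E", saddle_energy),
    )
    fes, truth = make_fel(spec)
    minima = find_minima(fes, depth_tol=0.5)
    if len(minima) != 2:
        raise RuntimeError(f"expected 2 minima on the designed surface, found {len(minima)}")
    boat_min, chair_min = minima[0], minima[1]
    barrier, saddle = minimax_barrier(fes, boat_min, chair_min)
    fwd = assign_itinerary(minimum_energy_path(fes, boat_min, chair_min), tie_tol=tie_tol)
    rev = assign_itinerary(minimum_energy_path(fes, chair_min, boat_min), tie_tol=tie_tol)
    return {
        "fes": fes,
        "truth": truth,
        "minima": minima,
        "barrier": float(barrier),
        "saddle": saddle,
        "itinerary_forward": fwd,
        "itinerary_reverse": rev,
    }


def water_occupancy_recovery(
    p_occupancy: float = 0.75, n_frames: int = 10_000, seed: int = 0
) -> dict:
    """Estimate sphere occupancy on a synthetic water trajectory.

    The estimator sees only the frames; the generator's per-frame truth
    is returned alongside for comparison.
    """
    frames, sphere, water_idx, truth = make_water_trajectory(
        p_occupancy, n_frames, seed=seed
    )
    result = occupancy_fraction(frames, sphere, water_idx)
    return {
        "p_true": p_occupancy,
        "fraction": result.fraction,
        "truth_fraction": float(truth.mean()),
        "histogram": result.histogram,
        "n_frames": n_frames,
    }
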