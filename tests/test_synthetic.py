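"""Generators: seed determinism and ground-truth fidelity."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from glycopucker.catalog import load_catalog
from glycopucker.cv import pucker_series
from glycopucker.fes import find_minima
from glycopucker.ring import compute_cremer_pople
from glycopucker.synthetic import (
    Basin,
    FELSpec,
    PuckerPathSpec,
    ReactionProfileSpec,
    make_fel,
    make_reaction_profile,
    make_ring_trajectory,
    make_toy_active_site,
    make_water_trajectory,
)


def test_single_waypoint_constant_trajectory():
    spec = PuckerPathSpec(waypoints=((90.0, 240.0, 0.55),), frames_per_segment=5)
    coords, truth = make_ring_trajectory(spec)
    assert coords.shape == (5, 6, 3)
    assert np.allclose(coords, coords[0])
    for frame, (q, th, ph) in zip(coords, truth):
        p = compute_cremer_pople(frame)
        assert p.Q == pytest.approx(q, abs=1e-6)
        assert p.theta == pytest.approx(th, abs=1e-6)
        assert p.phi == pytest.approx(ph, abs=1e-6)


def test_path_through_envelope_theta_profile():
    """Boat -> envelope -> chair: recovered theta passes the 4E latitude."""
    cat = load_catalog()
    e4 = cat["4E"]
    spec = PuckerPathSpec(
        waypoints=((90.0, 240.0, 0.55), (e4.theta_ref, e4.phi_ref, 0.55), (0.0, 0.0, 0.55)),
        frames_per_segment=25,
    )
    coords, truth = make_ring_trajectory(spec)
    thetas = [compute_cremer_pople(f).theta for f in coords]
    assert thetas[0] == pytest.approx(90.0, abs=1e-6)
    assert thetas[24] == pytest.approx(e4.theta_ref, abs=1e-6)
    assert thetas[-1] == pytest.approx(0.0, abs=1.0)
    assert all(a >= b - 1e-9 for a, b in zip(thetas, thetas[1:]))  # monotone descent


def test_noisy_trajectory_recovery_error():
    spec = PuckerPathSpec(
        waypoints=((90.0, 225.0, 0.55), (0.0, 0.0, 0.55)),
        frames_per_segment=1000,
        noise_sigma=0.02,
        seed=5,
    )
    coords, truth = make_ring_trajectory(spec)
    series = pucker_series(coords, range(6))
    errs = [
        abs(p.theta - t)
        for p, (_q, t, _ph) in zip(series, truth)
        if p is not None and p.is_angular_defined
    ]
    assert len(errs) > 900
    assert np.mean(errs) < 3.0  # mean absolute theta error under thermal-scale noise


def test_generators_seed_deterministic():
    spec = PuckerPathSpec(waypoints=((90.0, 240.0, 0.55), (0.0, 0.0, 0.5)),
                          frames_per_segment=10, noise_sigma=0.05, seed=3)
    c1, _ = make_ring_trajectory(spec)
    c2, _ = make_ring_trajectory(spec)
    assert np.array_equal(c1, c2)
    f1, _, _, t1 = make_water_trajectory(0.4, 20, seed=8)
    f2, _, _, t2 = make_water_trajectory(0.4, 20, seed=8)
    assert np.array_equal(f1, f2) and np.array_equal(t1, t2)


def test_invalid_path_specs():
    with pytest.raises(ValueError):
        PuckerPathSpec(waypoints=())
    with pytest.raises(ValueError):
        PuckerPathSpec(waypoints=((200.0, 0.0, 0.5),))
    with pytest.raises(ValueError):
        PuckerPathSpec(waypoints=((90.0, 0.0, 0.5),), noise_sigma=-0.1)


def test_fel_single_basin_minimum_at_center():
    spec = FELSpec(basins=(Basin((90.0, 120.0), energy=0.0, width=15.0),))
    fes, truth = make_fel(spec)
    minima = find_minima(fes)
    assert len(minima) == 1
    phi, theta = minima[0].location
    assert phi == pytest.approx(120.0, abs=1.0)
    assert theta == pytest.approx(90.0, abs=1.0)


def test_fel_designed_barrier():
    spec = FELSpec(basins=(Basin("1,4B/1S3", 0.0), Basin("4C1", 0.5)), saddle=("4E", 5.0))
    fes, truth = make_fel(spec)
    from glycopucker.fes import minimax_barrier

    minima = find_minima(fes, depth_tol=0.5)
    barrier, _ = minimax_barrier(fes, minima[0], minima[1])
    assert barrier == pytest.approx(5.0, abs=0.1)
    assert truth["barrier_from_first"] == 5.0


def test_fel_requires_basins():
    with pytest.raises(ValueError):
        FELSpec(basins=())
    with pytest.raises(ValueError):
        FELSpec(basins=(Basin("4C1"),), saddle=("4E", 5.0))  # valley needs two


@pytest.mark.parametrize("barrier,dg", [(16.1, -10.0), (11.1, -6.8), (5.0, 0.0)])
def test_reaction_profile_stationary_values(barrier, dg):
    pot = make_reaction_profile(ReactionProfileSpec(barrier=barrier, reaction_dg=dg))
    # numerical minimization confirms the designed stationary energies
    res_a = minimize_scalar(lambda x: float(pot.energy(np.array(x))),
                            bounds=(-1.5, -0.5), method="bounded",
                            options={"xatol": 1e-10})
    res_b = minimize_scalar(lambda x: float(pot.energy(np.array(x))),
                            bounds=(0.5, 1.5), method="bounded", options={"xatol": 1e-10})
    res_ts = minimize_scalar(lambda x: -float(pot.energy(np.array(x))),
                             bounds=(-0.5, 0.5), method="bounded", options={"xatol": 1e-10})
    assert res_a.fun == pytest.approx(0.0, abs=1e-6)
    assert res_b.fun == pytest.approx(dg, abs=1e-6)
    assert -res_ts.fun == pytest.approx(barrier, abs=1e-6)


def test_reaction_profile_symmetric_wells_equal():
    pot = make_reaction_profile(ReactionProfileSpec(barrier=4.0, reaction_dg=0.0))
    assert float(pot.energy(np.array(-1.0))) == pytest.approx(
        float(pot.energy(np.array(1.0))), abs=1e-12
    )


def test_reaction_profile_infeasible_spec():
    with pytest.raises(ValueError, match="infeasible"):
        ReactionProfileSpec(barrier=3.0, reaction_dg=5.0)


def test_profile_gradient_matches_finite_difference():
    pot = make_reaction_profile(ReactionProfileSpec(barrier=11.1, reaction_dg=-6.8))
    for x in (-1.4, -0.7, 0.0, 0.4, 1.2, 1.6):
        g = float(pot.gradient(np.array([x]))[0])
        h = 1e-6
        fd = (float(pot.energy(np.array(x + h))) - float(pot.energy(np.array(x - h)))) / (2 * h)
        assert g == pytest.approx(fd, abs=1e-5)


def test_toy_active_site_distances_exact():
    from glycopucker.cv import distance
    from glycopucker.synthetic import TS1_DISTANCES

    frame, site = make_toy_active_site(TS1_DISTANCES)
    assert distance(frame, site.Ocarb_D175, site.H_D175) == pytest.approx(1.53, abs=1e-9)
    assert distance(frame, site.O1, site.H_D175) == pytest.approx(1.07, abs=1e-9)
    assert distance(frame, site.C1, site.O1) == pytest.approx(2.3, abs=1e-9)
    assert distance(frame, site.C1, site.O_NHAc) == pytest.approx(2.2, abs=1e-9)


def test_toy_active_site_rejects_bad_specs():
    with pytest.raises(KeyError):
        make_toy_active_site({"d_nonsense": 1.0})
    with pytest.raises(ValueError):
        make_toy_active_site({"d_C1_O1": -1.0})
    with pytest.raises(ValueError, match="ambiguous"):
        make_toy_active_site({"d_C1_O1": 1.4, "d_C1_Ow": 3.0})
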