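"""Reaction collective variables and per-frame series."""

import numpy as np
import pytest

from glycopucker.cv import (
    ActiveSiteMap,
    MissingRoleError,
    cv_series,
    distance,
    evaluate_cyclization_cv,
    evaluate_ring_opening_cv,
    pucker_series,
)
from glycopucker.ring import build_ideal_ring
from glycopucker.synthetic import TS1_DISTANCES, TS2_DISTANCES, make_toy_active_site
from .conftest import random_rotation


def test_distance_basics():
    frame = np.array([[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]])
    assert distance(frame, 0, 0) == 0.0
    assert distance(frame, 0, 1) == pytest.approx(5.0)
    assert distance(frame, 1, 0) == pytest.approx(5.0)
    with pytest.raises(IndexError):
        distance(frame, 0, 5)


def test_distance_rotation_invariant(rng):
    frame = rng.normal(size=(6, 3))
    d0 = distance(frame, 1, 4)
    rot = random_rotation(rng)
    assert distance(frame @ rot.T, 1, 4) == pytest.approx(d0, abs=1e-9)


def test_cyclization_cv_transition_state_geometry():
    """Proton nearly on the glycosidic oxygen, C1-O1 partially broken: CV = 0.56 Å."""
    frame, site = make_toy_active_site(TS1_DISTANCES)
    r = evaluate_cyclization_cv(frame, site)
    assert r.value == pytest.approx((1.53 - 1.07) + (2.3 - 2.2), abs=1e-9)
    assert r.value == pytest.approx(0.56, abs=1e-9)


def test_cyclization_cv_michaelis_like_frame():
    frame, site = make_toy_active_site(
        {"d_Ocarb_H": 1.0, "d_O1_H": 1.9, "d_C1_O1": 1.4, "d_C1_ONHAc": 3.0}
    )
    r = evaluate_cyclization_cv(frame, site)
    assert r.value == pytest.approx(-2.5, abs=1e-9)


def test_ring_opening_cv_transition_state_geometry():
    """Water proton in flight, C1-O_w forming: CV = 0.29 Å."""
    frame, site = make_toy_active_site(TS2_DISTANCES)
    r = evaluate_ring_opening_cv(frame, site)
    assert r.value == pytest.approx((1.16 - 1.29) + (2.56 - 2.14), abs=1e-9)
    assert r.value == pytest.approx(0.29, abs=1e-9)


def test_ring_opening_cv_intact_oxazolinium():
    frame, site = make_toy_active_site(
        {"d_Ow_Hw": 0.97, "d_Ocarb_Hw": 3.0, "d_C1_ONHAc": 1.5, "d_C1_Ow": 3.5}
    )
    r = evaluate_ring_opening_cv(frame, site)
    assert r.value == pytest.approx(-4.03, abs=1e-9)


@pytest.mark.parametrize(
    "spec,evaluate",
    [
        ({"d_Ocarb_H": 1.2, "d_O1_H": 1.2, "d_C1_O1": 2.0, "d_C1_ONHAc": 2.0},
         evaluate_cyclization_cv),
        ({"d_Ow_Hw": 1.1, "d_Ocarb_Hw": 1.1, "d_C1_ONHAc": 2.3, "d_C1_Ow": 2.3},
         evaluate_ring_opening_cv),
    ],
)
def test_balanced_frames_give_zero_cv(spec, evaluate):
    frame, site = make_toy_active_site(spec)
    assert evaluate(frame, site).value == pytest.approx(0.0, abs=1e-12)


def test_cv_equals_sum_of_components():
    frame, site = make_toy_active_site(TS1_DISTANCES)
    r = evaluate_cyclization_cv(frame, site)
    c = r.components
    assert r.value == (c["d_Ocarb_H"] - c["d_O1_H"]) + (c["d_C1_O1"] - c["d_C1_ONHAc"])


def test_cv_rigid_motion_invariance(rng):
    frame, site = make_toy_active_site(TS1_DISTANCES)
    v0 = evaluate_cyclization_cv(frame, site).value
    moved = frame @ random_rotation(rng).T + rng.uniform(-9, 9, 3)
    assert evaluate_cyclization_cv(moved, site).value == pytest.approx(v0, abs=1e-9)


def test_missing_role_raises():
    frame, site = make_toy_active_site(TS1_DISTANCES)
    with pytest.raises(MissingRoleError, match="O_w"):
        evaluate_ring_opening_cv(frame, site)


def test_carboxylate_oxygen_identity_matters():
    """Re-pointing Ocarb_D175 at a different atom changes the CV through the
    role assignment only — the sensitivity the explicit map exists to expose."""
    frame, site = make_toy_active_site(TS1_DISTANCES)
    with pytest.raises(ValueError):
        # an oxygen cannot play two roles: indices must be distinct
        ActiveSiteMap(C1=0, O1=1, Ocarb_D175=1)
    v0 = evaluate_cyclization_cv(frame, site).value
    # move the carboxylate oxygen: only the d(Ocarb,H) component responds
    frame2 = frame.copy()
    frame2[site.Ocarb_D175] += np.array([0.25, 0.0, 0.0])
    v1 = evaluate_cyclization_cv(frame2, site).value
    assert v1 != pytest.approx(v0, abs=1e-6)


def test_cv_series_preserves_order_with_gap_markers():
    frame, site = make_toy_active_site(TS1_DISTANCES)
    short = frame[:2]  # drops the mapped proton -> unevaluable
    series = cv_series([frame, short, frame], site, step="cyclization")
    assert series[0] is not None and series[2] is not None
    assert series[1] is None
    assert series[0].value == pytest.approx(0.56, abs=1e-9)


def test_cv_series_unknown_step():
    with pytest.raises(ValueError, match="unknown CV step"):
        cv_series([], ActiveSiteMap(), step="nope")


def test_pucker_series_rigid_chair():
    ring = build_ideal_ring(0.55, 0.0, 0.0)
    traj = np.repeat(ring.coords[None], 10, axis=0)
    series = pucker_series(traj, range(6))
    assert len(series) == 10
    for p in series:
        assert p.theta == pytest.approx(0.0, abs=1e-9)


def test_pucker_series_single_frame_matches_direct_computation():
    from glycopucker.ring import compute_cremer_pople

    ring = build_ideal_ring(0.5, 70.0, 100.0)
    series = pucker_series(ring.coords[None], range(6))
    direct = compute_cremer_pople(ring)
    assert series[0].theta == pytest.approx(direct.theta)
    assert series[0].phi == pytest.approx(direct.phi)


def test_pucker_series_gap_marker_for_missing_atoms():
    ring = build_ideal_ring(0.55, 90.0, 240.0)
    bad = ring.coords[:4]  # missing atoms
    series = pucker_series([ring.coords, bad], range(6))
    assert series[0] is not None
    assert series[1] is None
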