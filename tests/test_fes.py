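"""Landscape topography: minima, minimax barriers, paths, itineraries."""

import numpy as np
import pytest

from glycopucker.fes import (
    FreeEnergySurface,
    assign_itinerary,
    export_mercator,
    find_minima,
    make_pucker_axes,
    minimax_barrier,
    minimum_energy_path,
    region_energy,
)
from glycopucker.synthetic import Basin, FELSpec, make_fel


def gaussian_well_surface(centers, depths, widths, base=8.0, step=2.0):
    """Simple periodic (phi, theta) surface from inverted Gaussian wells."""
    phi, theta = make_pucker_axes(step)
    pp, tt = np.meshgrid(phi, theta, indexing="ij")
    v = np.full(pp.shape, base)
    for (p0, t0), d, w in zip(centers, depths, widths):
        dphi = np.minimum(np.abs(pp - p0), 360 - np.abs(pp - p0))
        v -= d * np.exp(-0.5 * ((dphi / w) ** 2 + ((tt - t0) / w) ** 2))
    return FreeEnergySurface(
        axes=(phi, theta), values=v - v.min(), periodic=(True, False),
        axis_names=("phi", "theta"),
    )


def double_well_1d(barrier=5.0):
    x = np.linspace(-1.5, 1.5, 301)
    v = barrier * (x**2 - 1.0) ** 2  # quartic: minima at ±1, saddle = barrier at 0
    return FreeEnergySurface(axes=(x,), values=v - v.min(), periodic=(False,))


def test_single_well_yields_one_minimum():
    fes = gaussian_well_surface([(120.0, 90.0)], [5.0], [20.0])
    minima = find_minima(fes)
    assert len(minima) == 1
    assert minima[0].location == (120.0, 90.0)
    assert minima[0].energy == pytest.approx(0.0)


def test_two_wells_found_within_one_cell():
    fes = gaussian_well_surface([(60.0, 60.0), (240.0, 120.0)], [6.0, 5.0], [18.0, 18.0])
    minima = find_minima(fes)
    assert len(minima) == 2
    locs = sorted(m.location for m in minima)
    assert abs(locs[0][0] - 60.0) <= 2.0 and abs(locs[0][1] - 60.0) <= 2.0
    assert abs(locs[1][0] - 240.0) <= 2.0 and abs(locs[1][1] - 120.0) <= 2.0


def test_minimum_detected_across_periodic_wrap():
    fes = gaussian_well_surface([(358.0, 90.0)], [5.0], [15.0])
    minima = find_minima(fes)
    assert len(minima) == 1
    assert minima[0].location[0] == 358.0


def test_flat_surface_warns_and_returns_empty():
    phi, theta = make_pucker_axes(5.0)
    fes = FreeEnergySurface(axes=(phi, theta), values=np.zeros((len(phi), len(theta))),
                            periodic=(True, False), axis_names=("phi", "theta"))
    with pytest.warns(UserWarning, match="flat"):
        assert find_minima(fes) == []


def test_minimax_barrier_on_quartic_double_well():
    fes = double_well_1d(barrier=5.0)
    minima = find_minima(fes, depth_tol=0.5)
    assert len(minima) == 2
    barrier, saddle = minimax_barrier(fes, minima[0], minima[1])
    assert barrier == pytest.approx(5.0, abs=0.05)
    assert abs(saddle.location[0]) < 0.02


def test_minimax_barrier_same_minimum_is_zero():
    fes = double_well_1d()
    minima = find_minima(fes, depth_tol=0.5)
    barrier, _ = minimax_barrier(fes, minima[0], minima[0])
    assert barrier == 0.0


def test_shared_saddle_identity():
    """barrier(a->b) - barrier(b->a) = E(a) - E(b)."""
    x = np.linspace(-1.5, 1.5, 301)
    v = 5.0 * (x**2 - 1) ** 2 + 1.2 * x  # tilted double well
    fes = FreeEnergySurface(axes=(x,), values=v - v.min(), periodic=(False,))
    a, b = find_minima(fes, depth_tol=0.5)[:2]
    fwd, s1 = minimax_barrier(fes, a, b)
    rev, s2 = minimax_barrier(fes, b, a)
    assert fwd - rev == pytest.approx(b.energy - a.energy, abs=1e-9)
    assert s1.energy == pytest.approx(s2.energy, abs=1e-9)


def test_barrier_invariant_under_constant_shift():
    fes = double_well_1d()
    minima = find_minima(fes, depth_tol=0.5)
    b0, _ = minimax_barrier(fes, minima[0], minima[1])
    shifted = FreeEnergySurface(axes=fes.axes, values=fes.values + 7.3,
                                periodic=fes.periodic, axis_names=fes.axis_names)
    b1, _ = minimax_barrier(shifted, minima[0], minima[1])
    assert b1 == pytest.approx(b0, abs=1e-9)


def test_outputs_invariant_under_periodic_translation():
    fes = gaussian_well_surface([(60.0, 60.0), (240.0, 120.0)], [6.0, 5.0], [18.0, 18.0])
    rolled = FreeEnergySurface(axes=fes.axes, values=np.roll(fes.values, 90, axis=0),
                               periodic=fes.periodic, axis_names=fes.axis_names)
    m0 = find_minima(fes)
    m1 = find_minima(rolled)
    b0, s0 = minimax_barrier(fes, m0[0], m0[1])
    b1, s1 = minimax_barrier(rolled, m1[0], m1[1])
    assert b1 == pytest.approx(b0, abs=1e-9)
    assert s1.energy == pytest.approx(s0.energy, abs=1e-9)
    assert sorted(m.energy for m in m1) == pytest.approx(
        sorted(m.energy for m in m0), abs=1e-9
    )


def test_mep_passes_through_saddle_and_endpoints():
    fes = double_well_1d()
    minima = find_minima(fes, depth_tol=0.5)
    path = minimum_energy_path(fes, minima[0], minima[1])
    assert path.indices[0] == minima[0].index
    assert path.indices[-1] == minima[1].index
    barrier, saddle = minimax_barrier(fes, minima[0], minima[1])
    assert path.saddle_energy == pytest.approx(saddle.energy, abs=1e-9)
    assert abs(path.points[path.saddle_position][0] - saddle.location[0]) < 0.02


def test_barrier_stable_under_grid_refinement():
    for n in (151, 301, 601):
        x = np.linspace(-1.5, 1.5, n)
        v = 5.0 * (x**2 - 1) ** 2
        fes = FreeEnergySurface(axes=(x,), values=v - v.min(), periodic=(False,))
        m = find_minima(fes, depth_tol=0.5)
        b, _ = minimax_barrier(fes, m[0], m[1])
        assert b == pytest.approx(5.0, abs=0.1)


@pytest.fixture(scope="module")
def designed_fel():
    spec = FELSpec(basins=(Basin("1,4B/1S3", energy=0.0), Basin("4C1", energy=0.5)),
                   saddle=("4E", 5.0))
    return make_fel(spec)


def test_designed_fel_itinerary_forward_and_reverse(designed_fel):
    fes, _truth = designed_fel
    minima = find_minima(fes, depth_tol=0.5)
    assert len(minima) == 2
    boat, chair = minima
    fwd = assign_itinerary(minimum_energy_path(fes, boat, chair))
    rev = assign_itinerary(minimum_energy_path(fes, chair, boat))
    assert fwd == "1,4B/1S3 → [4E]‡ → 4C1"
    assert rev == "4C1 → [4E]‡ → 1,4B/1S3"


def test_designed_fel_barrier_matches_construction(designed_fel):
    fes, truth = designed_fel
    minima = find_minima(fes, depth_tol=0.5)
    barrier, saddle = minimax_barrier(fes, minima[0], minima[1])
    assert barrier == pytest.approx(truth["saddle"]["energy"], abs=0.1)
    assert saddle.location[1] == pytest.approx(truth["saddle"]["theta"], abs=1.0)


def test_single_basin_path_has_no_ts_marker():
    fes = gaussian_well_surface([(120.0, 90.0)], [5.0], [20.0])
    m = find_minima(fes)[0]
    path = minimum_energy_path(fes, m, m)
    with pytest.warns(UserWarning, match="single-basin"):
        label = assign_itinerary(path)
    assert "‡" not in label


def test_itinerary_requires_pucker_surface():
    fes = double_well_1d()
    m = find_minima(fes, depth_tol=0.5)
    path = minimum_energy_path(fes, m[0], m[1])
    with pytest.raises(ValueError, match="phi, theta"):
        assign_itinerary(path)


def test_region_energy_at_global_minimum_is_zero(designed_fel):
    fes, _ = designed_fel
    # the global minimum sits midway between 1,4B and 1S3; both labels see it
    assert region_energy(fes, "1,4B", radius_deg=16.0) == pytest.approx(0.0, abs=1e-9)


def test_region_energy_recovers_designed_shelf():
    spec = FELSpec(basins=(Basin("1,4B/1S3", energy=0.0), Basin("4C1", energy=0.5)),
                   saddle=("4E", 4.5))
    fes, _ = make_fel(spec)
    assert region_energy(fes, "4E", radius_deg=3.0) == pytest.approx(4.5, abs=0.15)


def test_region_energy_whole_sphere_contains_global_minimum(designed_fel):
    fes, _ = designed_fel
    assert region_energy(fes, "1C4", radius_deg=200.0) == pytest.approx(0.0, abs=1e-12)


def test_region_energy_radius_too_small(designed_fel):
    fes, _ = designed_fel
    with pytest.raises(ValueError, match="radius"):
        region_energy(fes, "4E", radius_deg=0.01)


def test_mercator_levels_default_one_kcal(designed_fel, tmp_path):
    fes, _ = designed_fel
    levels = export_mercator(fes, isoline_step=1.0,
                             data_path=str(tmp_path / "fel.tsv"))
    assert np.allclose(np.diff(levels), 1.0)
    assert (tmp_path / "fel.tsv").exists()


def test_mercator_contour_count_on_gaussian_well():
    fes = gaussian_well_surface([(180.0, 90.0)], [5.0], [25.0], base=5.0)
    levels = export_mercator(fes, isoline_step=1.0)
    # a well of depth 5 crossed by unit isolines: closed contours at 1..4
    # plus the near-max level, all at integer multiples of the step
    assert np.allclose(levels % 1.0, 0.0)
    closed = [lv for lv in levels if 0.0 < lv < float(fes.values.max())]
    assert closed == [1.0, 2.0, 3.0, 4.0]


def test_mercator_rejects_1d():
    with pytest.raises(ValueError, match="2D"):
        export_mercator(double_well_1d())


def test_normalization_invariant():
    fes = gaussian_well_surface([(10.0, 40.0)], [3.0], [15.0])
    assert fes.normalized().values.min() == pytest.approx(0.0, abs=1e-12)
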