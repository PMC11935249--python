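import numpy as np
import pytest

from letimpt import (BeamConfig, Scenario, SpotSpacing, assemble_influence,
                     build_phantom, make_scenarios, place_spots)
from letimpt import physics
from letimpt.montecarlo import mc_beamlet_transport, spot_seed
from letimpt.pencilbeam import pb_beamlet_dose
from letimpt.planning import stv_wepl_and_lateral, spot_table


def test_make_scenarios_enumeration():
    scens = make_scenarios(5.0, 3.5)
    assert len(scens) == 9
    assert scens[0].is_nominal
    shifts = {s.setup_shift_mm for s in scens[1:7]}
    assert shifts == {(5.0, 0.0, 0.0), (-5.0, 0.0, 0.0), (0.0, 5.0, 0.0),
                      (0.0, -5.0, 0.0), (0.0, 0.0, 5.0), (0.0, 0.0, -5.0)}
    scales = sorted(s.range_scale for s in scens[7:])
    assert scales == [pytest.approx(0.965), pytest.approx(1.035)]
    # eight perturbed scenarios beyond the nominal
    assert sum(not s.is_nominal for s in scens) == 8


def test_make_scenarios_degenerate_and_errors():
    scens = make_scenarios(0.0, 0.0)
    assert len(scens) == 9
    assert all(s.setup_shift_mm == (0.0, 0.0, 0.0) and s.range_scale == 1.0
               for s in scens)
    with pytest.raises(ValueError):
        make_scenarios(-1.0, 0.0)


@pytest.fixture(scope="module")
def tiny_setup(tiny_phantom_config, tables):
    grid, density, ss = build_phantom(tiny_phantom_config)
    iso = ss.centroid("ctv")
    beams = [BeamConfig(270.0, tuple(iso)), BeamConfig(90.0, tuple(iso))]
    spots = place_spots(ss["stv"], beams, grid, density, tables)
    return grid, density, ss, beams, spots


def test_spot_coverage_contract(tiny_setup, tables):
    """Brute-force audit: every STV voxel has a spot within one lateral
    spacing and one layer spacing (in WEPL) of its position."""
    grid, density, ss, beams, spots = tiny_setup
    spacing = SpotSpacing()
    duv = spacing.lateral_spacing_mm
    for bi, beam in enumerate(beams):
        _, wepl, u, v = stv_wepl_and_lateral(ss["stv"], beam, grid, density)
        bspots = [s for s in spots if s.beam_index == bi]
        su = np.array([s.u_mm for s in bspots])
        sv = np.array([s.v_mm for s in bspots])
        sw = physics.range_from_energy(
            np.array([s.energy_mev for s in bspots]), tables) * 10.0
        layer_dw = np.diff(np.unique(np.round(sw, 6)))
        dw = layer_dw.min() if layer_dw.size else duv
        for i in range(len(wepl)):
            lat_ok = np.hypot(su - u[i], sv - v[i]) <= duv * 1.001
            dep_ok = np.abs(sw - wepl[i] * 10.0) <= dw * 1.001
            assert np.any(lat_ok & dep_ok), f"voxel {i} of beam {bi} uncovered"


def test_spot_count_decreases_with_spacing(tiny_setup, tables):
    grid, density, ss, beams, spots = tiny_setup
    wide = place_spots(ss["stv"], beams, grid, density, tables,
                       SpotSpacing(lateral_factor=3.0))
    assert len(wide) < len(spots)


def test_single_voxel_stv_minimal_coverage(tiny_setup, tables):
    grid, density, ss, beams, _ = tiny_setup
    lone = np.zeros(grid.dims, bool)
    lone[20, 20, 10] = True
    spots = place_spots(lone, beams[:1], grid, density, tables)
    assert len(spots) >= 1
    _, wepl, _, _ = stv_wepl_and_lateral(lone, beams[0], grid, density)
    peaks = physics.range_from_energy(
        np.array([s.energy_mev for s in spots]), tables)
    assert np.min(np.abs(peaks - wepl[0])) * 10.0 <= 4.0  # within one layer


def test_unreachable_stv_raises(tiny_setup, tables):
    grid, density, ss, beams, _ = tiny_setup
    with pytest.raises(ValueError, match="energy reach"):
        place_spots(ss["stv"], beams, grid, density, tables,
                    energy_limits_mev=(70.0, 80.0))


def test_assemble_counting_and_schema_contract(tiny_setup, tables):
    grid, density, ss, beams, spots = tiny_setup
    two = spots[:2]
    scens = make_scenarios(3.0, 2.0)[:3]
    inf_pb = assemble_influence("pb", two, beams, grid, density, scens, tables)
    inf_mc = assemble_influence("mc", two, beams, grid, density, scens, tables,
                                n_histories=500, seed=4)
    for inf in (inf_pb, inf_mc):
        assert len(inf.matrices) == 3
        for mat in inf.matrices.values():
            assert mat.shape == (grid.n_voxels, 2)
    # identical spot tables, differing only in engine tag and values
    assert spot_table(inf_pb.spots).equals(spot_table(inf_mc.spots))
    assert inf_pb.engine == "pb" and inf_mc.engine == "mc"
    assert inf_mc.dose_let is not None and inf_pb.dose_let is None
    with pytest.raises(ValueError):
        assemble_influence("nope", two, beams, grid, density, scens, tables)


def test_nominal_columns_reproduce_direct_engine_calls(tiny_setup, tables,
                                                       nominal):
    grid, density, ss, beams, spots = tiny_setup
    two = spots[:2]
    inf_pb = assemble_influence("pb", two, beams, grid, density, [nominal],
                                tables)
    inf_mc = assemble_influence("mc", two, beams, grid, density, [nominal],
                                tables, n_histories=500, seed=9)
    for j, spot in enumerate(two):
        direct = pb_beamlet_dose(spot, beams[spot.beam_index], grid, density,
                                 nominal, tables)
        col = inf_pb.nominal()[:, j].toarray().ravel()
        assert np.allclose(col[direct.indices], direct.values)
        sc = mc_beamlet_transport(spot, beams[spot.beam_index], grid, density,
                                  nominal, tables, 500, spot_seed(9, spot.id))
        col = inf_mc.nominal()[:, j].toarray().ravel()
        assert np.allclose(col[sc.indices], sc.values)


def test_spot_order_permutation_permutes_columns(tiny_setup, tables, nominal):
    """Per-spot seeding keyed by spot id makes assembly order-independent."""
    grid, density, ss, beams, spots = tiny_setup
    four = spots[:4]
    inf_a = assemble_influence("mc", four, beams, grid, density, [nominal],
                               tables, n_histories=300, seed=5)
    perm = [2, 0, 3, 1]
    inf_b = assemble_influence("mc", [four[i] for i in perm], beams, grid,
                               density, [nominal], tables, n_histories=300,
                               seed=5)
    a = inf_a.nominal().toarray()
    b = inf_b.nominal().toarray()
    for new_pos, old_pos in enumerate(perm):
        assert np.array_equal(b[:, new_pos], a[:, old_pos])


def test_scenario_subset_restriction(tiny_setup, tables):
    grid, density, ss, beams, spots = tiny_setup
    scens = make_scenarios(3.0, 2.0)[:2]
    subset = np.flatnonzero(ss["stv"].ravel())
    inf = assemble_influence("pb", spots[:3], beams, grid, density, scens,
                             tables, scenario_subset=subset)
    assert inf.row_subsets["nominal"] is None
    label = scens[1].label
    assert inf.matrices[label].shape == (subset.size, 3)
    rows = inf.rows_for(label, subset[:5])
    assert np.array_equal(rows, np.arange(5))


def test_uniform_weights_cover_stv(tiny_setup, tables, nominal):
    """Sanity property: unit weights give dose to >= 95% of STV voxels."""
    grid, density, ss, beams, spots = tiny_setup
    inf = assemble_influence("pb", spots, beams, grid, density, [nominal],
                             tables)
    dose = inf.nominal() @ np.ones(len(spots))
    stv_dose = dose[np.flatnonzero(ss["stv"].ravel())]
    assert np.mean(stv_dose > 0) >= 0.95
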