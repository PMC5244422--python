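"""Synthetic morphological-stage generation: rasterization, porosity control,
connectivity, determinism, and I/O."""

import numpy as np
import pytest

from ivs_hemoflow.geometry import (
    FLUID_LABELS,
    GridSpec,
    Label,
    MorphologicalStage,
    PackingError,
    ResolutionError,
    SpiralArterySpec,
    VillousSpec,
    build_stage,
    check_connectivity,
    load_stage_h5,
    make_2d_slice,
    porosity,
    save_stage_h5,
    save_stage_vtk,
)

GRID = GridSpec((3000.0, 40.0, 4400.0), (75, 1, 110))
ARTERY_U = SpiralArterySpec(opening="undilated", rng_seed=7)
ARTERY_D = SpiralArterySpec(opening="dilated", rng_seed=7)


def test_straight_tube_into_empty_cuboid():
    """Degenerate case: no coil, no villi -> porosity exactly 1, connected."""
    art = SpiralArterySpec(opening="undilated", n_turns=0.0, pitch_um=2400.0, rng_seed=0)
    st = build_stage(GRID, art, VillousSpec(target_porosity=1.0))
    assert porosity(st) == 1.0
    assert check_connectivity(st).connected


def test_porosity_lands_in_band_and_matches_recount(undilated_stage):
    st = undilated_stage
    assert abs(porosity(st) - 0.5) <= 0.02
    # independent brute-force recount oracle
    n_f = n_s = 0
    for idx in np.ndindex(st.labels.shape):
        v = st.labels[idx]
        if v in (int(Label.IVS_FLUID), int(Label.TOP_OUTLET)):
            n_f += 1
        elif v == int(Label.VILLOUS_SOLID):
            n_s += 1
    assert porosity(st) == pytest.approx(n_f / (n_f + n_s), abs=1e-12)


def test_build_is_deterministic_under_fixed_seeds(undilated_stage):
    st2 = build_stage(GRID, ARTERY_U, VillousSpec(target_porosity=0.5, rng_seed=12))
    assert np.array_equal(undilated_stage.labels, st2.labels)
    assert undilated_stage.provenance == st2.provenance


def test_every_voxel_has_exactly_one_valid_label(undilated_stage):
    valid = {int(Label.INLET), int(Label.ARTERY_LUMEN), int(Label.WALL),
             int(Label.OPENING), int(Label.IVS_FLUID), int(Label.VILLOUS_SOLID),
             int(Label.TOP_OUTLET)}
    assert set(np.unique(undilated_stage.labels)) <= valid


def test_connectivity_witness_path_is_valid(undilated_stage):
    rep = check_connectivity(undilated_stage)
    assert rep.connected
    path = rep.path_witness
    assert undilated_stage.labels[path[0]] == int(Label.INLET)
    assert undilated_stage.labels[path[-1]] == int(Label.TOP_OUTLET)
    steps = np.abs(np.diff(np.array(path), axis=0)).sum(axis=1)
    assert np.all(steps == 1)  # 6-connected chain


def test_sealed_plane_disconnects():
    art = SpiralArterySpec(opening="undilated", n_turns=0.0, pitch_um=2400.0, rng_seed=0)
    st = build_stage(GRID, art, VillousSpec(target_porosity=1.0))
    labels = st.labels.copy()
    labels[:, :, 70] = int(Label.VILLOUS_SOLID)  # solid plane sealing the IVS
    blocked = MorphologicalStage(grid=st.grid, labels=labels)
    assert not check_connectivity(blocked).connected


def test_opening_diameter_within_one_voxel(undilated_stage, dilated_stage):
    hx = GRID.spacing_um[0]
    assert abs(undilated_stage.provenance["realized_opening_diameter_um"] - 340.0) <= hx
    assert abs(dilated_stage.provenance["realized_opening_diameter_um"] - 600.0) <= hx


def test_dilated_differs_only_in_the_opening_region(undilated_stage, dilated_stage):
    """With matched seeds the voxel diff is confined to the funnel's z band."""
    diff = np.nonzero(undilated_stage.labels != dilated_stage.labels)
    assert len(diff[0]) > 0
    zs = GRID.centers_um(2)[diff[2]]
    z0 = GRID.extent_um[2] - 2000.0  # mouth plane
    assert zs.max() < z0
    assert zs.min() > z0 - ARTERY_D.funnel_length_um - GRID.spacing_um[2]


def test_2d_slice_same_grammar_and_porosity_contract():
    st = make_2d_slice(ARTERY_U, VillousSpec(target_porosity=0.6, rng_seed=3),
                       extent_um=(3000.0, 4400.0), shape=(75, 110))
    assert st.two_d
    assert abs(porosity(st) - 0.6) <= 0.02
    assert check_connectivity(st).connected


def test_unresolvable_lumen_raises():
    coarse = GridSpec((3000.0, 200.0, 4400.0), (15, 1, 22))
    with pytest.raises(ResolutionError):
        build_stage(coarse, ARTERY_U, VillousSpec(target_porosity=1.0))


def test_unreachable_porosity_raises_packing_error():
    # clearance zone + minimum obstacle size make near-total occlusion
    # unreachable within the draw budget
    with pytest.raises(PackingError):
        build_stage(GRID, ARTERY_U, VillousSpec(target_porosity=0.04, rng_seed=1))


def test_h5_roundtrip_and_vtk_export(tmp_path, undilated_stage):
    h5 = tmp_path / "stage.h5"
    save_stage_h5(undilated_stage, h5)
    back = load_stage_h5(h5)
    assert np.array_equal(back.labels, undilated_stage.labels)
    assert back.grid == undilated_stage.grid
    assert len(back.wall_primitives) == len(undilated_stage.wall_primitives)
    vtk = tmp_path / "stage.vtk"
    save_stage_vtk(undilated_stage, vtk)
    head = vtk.read_text().splitlines()[:5]
    assert head[0].startswith("# vtk DataFile")
    assert (tmp_path / "stage.vtk.json").exists()


def test_wall_distance_accurate_near_the_surface():
    """The swept-ball channel surface is exact to O(step^2/r) near the wall,
    where wall-shear probing uses it."""
    from ivs_hemoflow.geometry import straight_tube_stage

    tb = straight_tube_stage(radius_mm=0.17, length_mm=2.0, n_across=14)
    c = tb.grid.extent_um[0] / 2000.0
    pts = np.array([[c + 0.10, c, 1.0], [c + 0.15, c, 1.0]])
    d = tb.wall_distance(pts)
    assert d[0] == pytest.approx(0.07, abs=3e-3)
    assert d[1] == pytest.approx(0.02, abs=1e-3)
    _, normals = tb.nearest_wall(pts, step_mm=0.005)
    assert normals[0] @ np.array([1.0, 0, 0]) == pytest.approx(-1.0, abs=1e-2)
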