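"""Grid construction, CoMFA/CoMSIA field values and their invariants."""

import numpy as np
import pytest

from qsar3d.fields import (
    DEFAULT_PROBE,
    LJ_PARAMS,
    Grid,
    assemble_descriptor_matrix,
    build_grid,
    comsia_field,
    coulomb_field,
    lennard_jones_field,
    read_cube,
    stack_blocks,
    write_cube,
)


def _point_grid(x, y, z):
    return Grid(origin=(x, y, z), spacing=1.0, dims=(1, 1, 1))


# ---------------------------------------------------------------------------
# grid arithmetic


def test_grid_single_atom_margin_spacing(atom_factory):
    mol = atom_factory()
    grid = build_grid([mol], margin=4.0, spacing=2.0)
    assert grid.dims == (5, 5, 5)
    assert grid.n_points == 125
    np.testing.assert_allclose(grid.origin, (-4.0, -4.0, -4.0))
    xs, _, _ = grid.axes()
    np.testing.assert_allclose(xs, [-4, -2, 0, 2, 4])


def test_grid_fine_spacing_rounding(atom_factory):
    grid = build_grid([atom_factory()], margin=4.0, spacing=0.6)
    assert grid.dims == (15, 15, 15)  # ceil(8/0.6) + 1


def test_grid_rejects_bad_inputs(atom_factory):
    with pytest.raises(ValueError):
        build_grid([], margin=4.0, spacing=2.0)
    with pytest.raises(ValueError):
        build_grid([atom_factory()], margin=-1.0, spacing=2.0)
    with pytest.raises(ValueError):
        build_grid([atom_factory()], margin=4.0, spacing=0.0)


# ---------------------------------------------------------------------------
# Lennard-Jones probe energies


def test_lj_zero_crossing_and_well_depth(atom_factory):
    mol = atom_factory(symbols=["C"])
    r_min = LJ_PARAMS["C"][0] + DEFAULT_PROBE.vdw_radius
    eps = np.sqrt(LJ_PARAMS["C"][1] * DEFAULT_PROBE.epsilon)
    r_zero = r_min / 2 ** (1 / 6)
    assert lennard_jones_field(mol, _point_grid(r_zero, 0, 0))[0] == pytest.approx(0.0, abs=1e-9)
    assert lennard_jones_field(mol, _point_grid(r_min, 0, 0))[0] == pytest.approx(-eps, abs=1e-9)


def test_lj_clamps_at_cutoff(atom_factory):
    mol = atom_factory()
    assert lennard_jones_field(mol, _point_grid(0, 0, 0))[0] == 30.0
    assert lennard_jones_field(mol, _point_grid(0.3, 0, 0))[0] == 30.0


def test_lj_vanishes_far_away(atom_factory):
    mol = atom_factory()
    assert abs(lennard_jones_field(mol, _point_grid(50.0, 0, 0))[0]) < 1e-6


# ---------------------------------------------------------------------------
# Coulomb probe energies


def test_coulomb_unit_charges_at_1A(atom_factory):
    mol = atom_factory(charges=[1.0])
    # distance-dependent dielectric D(r)=r → 332/r² = 332 at 1 Å
    assert coulomb_field(mol, _point_grid(1.0, 0, 0))[0] == pytest.approx(332.0, abs=1e-9)


def test_coulomb_dielectric_variants(atom_factory):
    mol = atom_factory(charges=[1.0])
    assert coulomb_field(mol, _point_grid(4.0, 0, 0))[0] == pytest.approx(332.0 / 16.0, abs=1e-9)
    assert coulomb_field(mol, _point_grid(4.0, 0, 0), dielectric=1.0)[0] == pytest.approx(
        332.0 / 4.0, abs=1e-9
    )


def test_coulomb_zero_charges(atom_factory):
    mol = atom_factory(charges=[0.0])
    grid = build_grid([mol], margin=3.0, spacing=1.5)
    np.testing.assert_array_equal(coulomb_field(mol, grid), 0.0)


def test_coulomb_superposition(atom_factory):
    grid = _point_grid(5.0, 1.0, -2.0)
    a = atom_factory(symbols=["N"], coords=[[0, 0, 0]], charges=[0.4])
    b = atom_factory(symbols=["O"], coords=[[1.2, 0, 0]], charges=[-0.4])
    ab = atom_factory(
        symbols=["N", "O"], coords=[[0, 0, 0], [1.2, 0, 0]], charges=[0.4, -0.4]
    )
    assert coulomb_field(ab, grid)[0] == pytest.approx(
        coulomb_field(a, grid)[0] + coulomb_field(b, grid)[0], abs=1e-12
    )


# ---------------------------------------------------------------------------
# CoMSIA similarity indices


def test_comsia_atom_on_grid_point(atom_factory):
    mol = atom_factory(hydrophobic=[1.0])
    assert comsia_field(mol, _point_grid(0, 0, 0), "hydrophobic")[0] == pytest.approx(-1.0)


def test_comsia_gaussian_attenuation(atom_factory):
    mol = atom_factory(hydrophobic=[1.0])
    val = comsia_field(mol, _point_grid(1.0, 0, 0), "hydrophobic", alpha=0.3)[0]
    assert val == pytest.approx(-np.exp(-0.3), abs=1e-9)


def test_comsia_absent_property_gives_zero(atom_factory):
    mol = atom_factory(donors=[False])
    grid = build_grid([mol], margin=3.0, spacing=1.5)
    np.testing.assert_array_equal(comsia_field(mol, grid, "donor"), 0.0)


def test_comsia_unknown_kind(atom_factory):
    with pytest.raises(ValueError, match="unknown"):
        comsia_field(atom_factory(), _point_grid(0, 0, 0), "magnetic")


def test_comsia_bounded_by_weight_sum(series12):
    mol = series12["molecules"][0]
    grid = series12["grid"]
    for kind, weights in [
        ("steric", mol.vdw_radii**3),
        ("electrostatic", mol.charges),
        ("hydrophobic", mol.hydrophobic),
    ]:
        vals = comsia_field(mol, grid, kind)
        assert np.all(np.abs(vals) <= np.abs(weights).sum() + 1e-12)
        assert np.all(np.isfinite(vals))


def test_comsia_additive_over_atoms(atom_factory):
    grid = _point_grid(0.7, -0.3, 1.1)
    a = atom_factory(hydrophobic=[0.5])
    b = atom_factory(coords=[[1.5, 0, 0]], hydrophobic=[-0.2])
    ab = atom_factory(
        symbols=["C", "C"], coords=[[0, 0, 0], [1.5, 0, 0]], hydrophobic=[0.5, -0.2]
    )
    assert comsia_field(ab, grid, "hydrophobic")[0] == pytest.approx(
        comsia_field(a, grid, "hydrophobic")[0] + comsia_field(b, grid, "hydrophobic")[0],
        abs=1e-12,
    )


# ---------------------------------------------------------------------------
# descriptor-matrix assembly


def test_assemble_shapes_and_block_order(series12):
    blocks = series12["blocks"]
    assert [b.field_kind for b in blocks] == ["steric", "electrostatic"]
    n = len(series12["molecules"])
    for b in blocks:
        assert b.values.shape == (n, series12["grid"].n_points)
    X, block_index = stack_blocks(blocks)
    assert X.shape == (n, 2 * series12["grid"].n_points)
    assert (np.bincount(block_index) == series12["grid"].n_points).all()


def test_assemble_comsia_five_blocks(series12):
    blocks = assemble_descriptor_matrix(
        series12["molecules"][:4], series12["grid"], method="comsia"
    )
    assert [b.field_kind for b in blocks] == [
        "steric", "electrostatic", "hydrophobic", "donor", "acceptor"
    ]
    for b in blocks:
        assert np.all(np.isfinite(b.values))


def test_duplicate_compounds_give_identical_rows(series12):
    mol = series12["molecules"][0]
    blocks = assemble_descriptor_matrix([mol, mol], series12["grid"], method="comfa")
    for b in blocks:
        np.testing.assert_array_equal(b.values[0], b.values[1])


def test_rigid_translation_invariance(series12):
    mols = series12["molecules"][:3]
    grid = build_grid(mols, margin=3.0, spacing=2.0)
    shift = np.array([3.7, -1.2, 0.5])
    moved = [m.translated(shift) for m in mols]
    grid_moved = grid.translated(shift)
    for method in ("comfa", "comsia"):
        ref = assemble_descriptor_matrix(mols, grid, method=method)
        new = assemble_descriptor_matrix(moved, grid_moved, method=method)
        for b_ref, b_new in zip(ref, new):
            np.testing.assert_allclose(b_new.values, b_ref.values, atol=1e-9)


def test_electrostatic_mean_fill_inside_steric_envelope(atom_factory):
    # compound A sits on the grid point (steric clamp) while B is far away;
    # A's electrostatic value must become the column mean over the others (= B's)
    grid = _point_grid(0.0, 0.0, 0.0)
    a = atom_factory(name="A", charges=[1.0])
    b = atom_factory(name="B", coords=[[6.0, 0, 0]], charges=[1.0])
    blocks = assemble_descriptor_matrix([a, b], grid, method="comfa")
    steric, elec = blocks
    assert steric.values[0, 0] == 30.0 and steric.values[1, 0] < 30.0
    expected_b = 332.0 / 36.0
    assert elec.values[1, 0] == pytest.approx(expected_b, abs=1e-9)
    assert elec.values[0, 0] == pytest.approx(expected_b, abs=1e-9)  # filled


def test_assemble_deterministic(series12):
    a = assemble_descriptor_matrix(series12["molecules"], series12["grid"])
    b = assemble_descriptor_matrix(series12["molecules"], series12["grid"])
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x.values, y.values)


# ---------------------------------------------------------------------------
# cube files


def test_cube_roundtrip(tmp_path, series12):
    grid = Grid(origin=(-2.0, -1.0, 0.0), spacing=0.5, dims=(3, 4, 5))
    rng = np.random.default_rng(0)
    values = rng.normal(size=grid.n_points)
    path = tmp_path / "field.cube"
    write_cube(path, grid, values, molecule=series12["molecules"][0])
    grid2, values2 = read_cube(path)
    assert grid2.dims == grid.dims
    np.testing.assert_allclose(grid2.origin, grid.origin, atol=1e-5)
    assert grid2.spacing == pytest.approx(grid.spacing, abs=1e-6)
    np.testing.assert_allclose(values2, values, atol=1e-4)
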