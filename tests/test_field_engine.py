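"""Grid construction, CoMFA/CoMSIA field values and column filtering."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from qsar3d import (
    Atom,
    FieldBlock,
    GridRegion,
    Molecule,
    Probe,
    build_grid,
    column_filter,
    comfa_blocks,
    comfa_fields,
    comsia_fields,
    default_comfa_probe,
    load_blocks,
    save_blocks,
)
from qsar3d.field_engine import COULOMB_KCAL


def _mol(coords, charges=None, radii=None, eps=None, props=None, mol_id="m"):
    coords = np.atleast_2d(coords)
    n = len(coords)
    charges = charges if charges is not None else np.zeros(n)
    radii = radii if radii is not None else np.full(n, 1.7)
    eps = eps if eps is not None else np.full(n, 0.11)
    props = props if props is not None else np.zeros((n, 5))
    atoms = [
        Atom("C", c, q, r, e, p)
        for c, q, r, e, p in zip(coords, charges, radii, eps, props)
    ]
    return Molecule(mol_id, atoms)


class TestBuildGrid:
    @pytest.mark.parametrize(
        "coords,spacing,margin,origin,dims",
        [
            ([[0, 0, 0]], 1.0, 4.0, (-4, -4, -4), (9, 9, 9)),
            ([[0, 0, 0]], 1.0, 0.0, (0, 0, 0), (1, 1, 1)),
            ([[0, 0, 0], [2, 0, 0]], 1.0, 1.0, (-1, -1, -1), (5, 3, 3)),
        ],
    )
    def test_lattice_bounds(self, coords, spacing, margin, origin, dims):
        grid = build_grid([_mol(coords)], spacing, margin)
        assert grid.dims == dims
        assert np.allclose(grid.origin, origin)

    def test_every_atom_enclosed_with_margin(self):
        rng = np.random.default_rng(0)
        mols = [_mol(rng.normal(0, 3, (8, 3))) for _ in range(4)]
        grid = build_grid(mols, spacing=1.5, margin=4.0)
        pts = grid.points()
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        allc = np.vstack([m.coords for m in mols])
        assert np.all(allc.min(axis=0) - lo >= 4.0 - 1e-9)
        assert np.all(hi - allc.max(axis=0) >= 4.0 - 1e-9)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            build_grid([], 1.0, 4.0)


class TestComfa:
    def test_steric_plateau_at_cutoff_on_contact(self):
        # an atom sitting exactly on a lattice point -> +cutoff exactly
        mol = _mol([[0.0, 0.0, 0.0]])
        grid = build_grid([mol], spacing=1.0, margin=2.0)
        steric, _, excluded = comfa_fields(mol, grid, cutoff=30.0)
        on_atom = np.flatnonzero(np.all(grid.points() == 0.0, axis=1))[0]
        assert steric[on_atom] == 30.0
        assert excluded[on_atom]
        assert steric.max() == 30.0

    def test_neutral_molecule_has_zero_electrostatics(self):
        mol = _mol([[0.0, 0, 0], [1.5, 0, 0]])
        grid = build_grid([mol], spacing=1.0, margin=3.0)
        _, elec, excluded = comfa_fields(mol, grid)
        assert np.all(elec[~excluded] == 0.0)

    def test_single_atom_matches_hand_summed_energy(self):
        """Direct evaluation oracle: explicit LJ + Coulomb at one point."""
        mol = _mol([[0.3, -0.2, 0.1]], charges=[-0.4], radii=[1.52], eps=[0.21])
        probe = default_comfa_probe()
        point = np.array([[2.0, 1.0, -1.5]])
        steric, elec, _ = comfa_fields(mol, point, probe, cutoff=30.0)
        r = np.linalg.norm(point[0] - mol.coords[0])
        rmin = 1.52 + probe.vdw_radius
        epsc = np.sqrt(0.21 * probe.well_depth)
        lj = epsc * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
        coul = COULOMB_KCAL * probe.charge * (-0.4) / r**2
        assert steric[0] == pytest.approx(lj, abs=1e-12)
        assert elec[0] == pytest.approx(coul, abs=1e-12)

    def test_truncation_bound_holds_everywhere(self):
        rng = np.random.default_rng(2)
        mol = _mol(rng.normal(0, 2, (10, 3)), charges=rng.normal(0, 0.5, 10))
        grid = build_grid([mol], spacing=1.0, margin=4.0)
        steric, elec, _ = comfa_fields(mol, grid, cutoff=30.0)
        assert steric.min() >= -30.0 and steric.max() <= 30.0
        assert elec.min() >= -30.0 and elec.max() <= 30.0

    def test_excluded_electrostatics_replaced_by_column_mean(self):
        # molecule A buried at the lattice point, molecule B far away:
        # A's electrostatic entry must equal B's (the non-excluded mean)
        a = _mol([[0.0, 0, 0]], charges=[0.5], mol_id="a")
        b = _mol([[3.0, 0, 0]], charges=[-0.3], mol_id="b")
        grid = GridRegion((0.0, 0.0, 0.0), 1.0, (1, 1, 1))
        blocks = comfa_blocks([a, b], grid)
        elec = blocks["comfa_electrostatic"].values
        expected_b = COULOMB_KCAL * 1.0 * (-0.3) / 9.0
        assert elec[1, 0] == pytest.approx(expected_b, abs=1e-12)
        assert elec[0, 0] == pytest.approx(expected_b, abs=1e-12)


class TestComsia:
    def test_point_on_atom_returns_property_weight(self):
        props = np.array([[2.0, 2.0, 2.0, 2.0, 2.0]])
        mol = _mol([[0.0, 0, 0]], props=props)
        vals = comsia_fields(mol, np.array([[0.0, 0, 0]]), alpha=0.3)
        assert np.allclose(vals[:, 0], 2.0, atol=1e-15)

    def test_gaussian_attenuation_at_one_angstrom(self):
        props = np.array([[2.0, 0, 0, 0, 0]])
        mol = _mol([[0.0, 0, 0]], props=props)
        vals = comsia_fields(mol, np.array([[1.0, 0, 0]]), alpha=0.3)
        assert vals[0, 0] == pytest.approx(2.0 * np.exp(-0.3), abs=1e-12)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(0, 2, (5, 3))
        props = rng.normal(0, 1, (5, 5))
        mol = _mol(coords, props=props)
        points = rng.normal(0, 3, (10, 3))
        vals = comsia_fields(mol, points, alpha=0.3)
        for qi, point in enumerate(points):
            for k in range(5):
                ref = sum(
                    props[i, k] * np.exp(-0.3 * np.sum((point - coords[i]) ** 2))
                    for i in range(5)
                )
                assert vals[k, qi] == pytest.approx(ref, abs=1e-12)

    def test_values_vanish_far_from_grid(self):
        props = np.ones((3, 5))
        near = _mol([[0, 0, 0], [1, 0, 0], [0, 1, 0]], props=props)
        grid = build_grid([near], spacing=1.0, margin=2.0)
        base = np.abs(comsia_fields(near, grid)).max()
        far = near.with_coords(near.coords + np.array([25.0, 0, 0]))
        far_vals = np.abs(comsia_fields(far, grid)).max()
        assert far_vals < 1e-4 * base


class TestRigidMotionInvariance:
    def test_joint_transform_reproduces_descriptors(self):
        rng = np.random.default_rng(11)
        mol = _mol(
            rng.normal(0, 2, (6, 3)),
            charges=rng.normal(0, 0.3, 6),
            props=rng.normal(0, 1, (6, 5)),
        )
        grid = build_grid([mol], spacing=2.0, margin=3.0)
        points = grid.points()
        R = Rotation.from_euler("xyz", [17, -42, 95], degrees=True).as_matrix()
        t = np.array([2.5, -1.0, 4.0])
        mol_t = mol.with_coords(mol.coords @ R.T + t)
        points_t = points @ R.T + t

        s0, e0, _ = comfa_fields(mol, points)
        s1, e1, _ = comfa_fields(mol_t, points_t)
        assert np.max(np.abs(s1 - s0)) < 1e-9
        assert np.max(np.abs(e1 - e0)) < 1e-9

        c0 = comsia_fields(mol, points)
        c1 = comsia_fields(mol_t, points_t)
        assert np.max(np.abs(c1 - c0)) < 1e-9


def _block(values, label="f"):
    values = np.asarray(values, dtype=float)
    grid = GridRegion((0.0, 0.0, 0.0), 1.0, (values.shape[1], 1, 1))
    return FieldBlock(label, values, grid, ("a", "b", "c")[: values.shape[0]])


class TestColumnFilter:
    def test_range_rule_with_boundary_kept(self):
        # ranges 0.5, 2.0, 5.0 -> threshold 2.0 keeps columns 2 and 3
        vals = np.array([[0.0, 0.0, 0.0], [0.25, 1.0, 2.5], [0.5, 2.0, 5.0]])
        filtered, masks = column_filter([_block(vals)], threshold=2.0)
        assert masks["f"].tolist() == [False, True, True]
        assert filtered["f"].point_ids.tolist() == [1, 2]

    def test_constant_column_always_dropped(self):
        vals = np.array([[1.0, 3.0], [1.0, 4.0], [1.0, 5.0]])
        _, masks = column_filter([_block(vals)], threshold=0.5)
        assert masks["f"].tolist() == [False, True]

    def test_zero_threshold_keeps_everything(self):
        vals = np.array([[1.0, 3.0], [1.0, 4.0]])
        _, masks = column_filter([_block(vals)], threshold=0.0)
        assert masks["f"].all()

    def test_all_columns_dropped_is_an_error(self):
        vals = np.ones((3, 4))
        with pytest.raises(ValueError, match="threshold"):
            column_filter([_block(vals)], threshold=2.0)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(0, 3, (5, 40))
        blk = FieldBlock(
            "f", vals, GridRegion((0.0, 0.0, 0.0), 1.0, (40, 1, 1)),
            tuple(f"m{i}" for i in range(5)),
        )
        kept = []
        for thr in (0.5, 1.0, 2.0, 4.0, 8.0):
            _, masks = column_filter([blk], threshold=thr)
            kept.append(int(masks["f"].sum()))
        assert kept == sorted(kept, reverse=True)


class TestSerialization:
    def test_blocks_round_trip(self, tmp_path, synthetic_study):
        mols = synthetic_study["train"][:5]
        grid = build_grid(mols, spacing=3.0, margin=2.0)
        blocks = comfa_blocks(mols, grid)
        filtered, masks = column_filter(blocks, threshold=2.0)
        save_blocks(filtered, tmp_path / "fields", masks)
        loaded, loaded_masks = load_blocks(tmp_path / "fields")
        for label, blk in filtered.items():
            assert np.allclose(loaded[label].values, blk.values, atol=1e-9)
            assert loaded[label].grid == blk.grid
            assert np.array_equal(loaded[label].point_ids, blk.point_ids)
            assert np.array_equal(loaded_masks[label], masks[label])
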