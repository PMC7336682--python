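import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from driftdock.docking import (
    Branch,
    DockingObjective,
    LigandModel,
    OUT_OF_GRID_PENALTY,
    PdbqtError,
    _combined_lj,
    apply_pose,
    apply_pose_batch,
    build_maps,
    parse_pdbqt,
    parse_receptor_pdbqt,
    read_maps,
    score_pose,
    trilinear,
    write_maps,
    write_pdbqt,
    write_receptor_pdbqt,
)
from driftdock.geometry import axis_angle_matrices, quat_to_matrix
from driftdock.space import DockingGenotype


@pytest.fixture
def butane_like() -> LigandModel:
    """Four-atom chain with one rotatable bond (terminal pair moves)."""
    coords = np.array(
        [[0.0, 0, 0], [1.5, 0, 0], [2.25, 1.3, 0], [3.75, 1.3, 0.0]]
    )
    return LigandModel(
        names=("C1", "C2", "C3", "C4"),
        types=("C", "C", "C", "C"),
        charges=np.array([0.1, -0.1, 0.1, -0.1]),
        ref_coords=coords,
        bonds=((0, 1), (1, 2), (2, 3)),
        root=(0, 1),
        branches=(Branch(parent_atom=1, child_atom=2, moved=(2, 3)),),
    )


@pytest.fixture
def small_maps():
    """A tiny receptor and a fine lattice around the origin."""
    receptor = [
        ("C", -1.0, np.array([3.0, 0.0, 0.0])),
        ("O", -0.5, np.array([-2.0, 2.0, 1.0])),
        ("N", 0.5, np.array([0.0, -3.0, -1.0])),
    ]
    maps = build_maps(receptor, np.zeros(3), spacing=0.25, npts=48)
    return receptor, maps


class TestGeometryPrimitives:
    def test_quaternion_matrices_match_scipy(self):
        rng = np.random.default_rng(0)
        q = rng.standard_normal((50, 4))
        ours = quat_to_matrix(q)
        theirs = Rotation.from_quat(q).as_matrix()
        assert np.allclose(ours, theirs, atol=1e-12)

    def test_axis_angle_matrices_match_scipy(self):
        rng = np.random.default_rng(1)
        axis = rng.standard_normal(3)
        angles = rng.uniform(-np.pi, np.pi, size=20)
        ours = axis_angle_matrices(axis, angles)
        u = axis / np.linalg.norm(axis)
        theirs = Rotation.from_rotvec(np.outer(angles, u)).as_matrix()
        assert np.allclose(ours, theirs, atol=1e-12)


class TestApplyPose:
    def test_identity_genotype_returns_reference(self, butane_like):
        g = DockingGenotype(np.zeros(3), np.array([0, 0, 0, 1.0]), [0.0])
        assert np.allclose(apply_pose(butane_like, g), butane_like.ref_coords)

    def test_pure_translation_shifts_every_atom(self, butane_like):
        t = np.array([2.0, -1.0, 0.5])
        g = DockingGenotype(t, np.array([0, 0, 0, 1.0]), [0.0])
        assert np.allclose(apply_pose(butane_like, g), butane_like.ref_coords + t)

    def test_branch_rotation_matches_rotation_matrix_oracle(self, butane_like):
        angle = np.pi
        g = DockingGenotype(np.zeros(3), np.array([0, 0, 0, 1.0]), [angle])
        coords = apply_pose(butane_like, g)
        # root untouched
        assert np.allclose(coords[:2], butane_like.ref_coords[:2])
        # moved set rotated about the 1->2 axis through atom 1 (scipy oracle)
        a = butane_like.ref_coords[1]
        axis = butane_like.ref_coords[2] - a
        R = Rotation.from_rotvec(angle * axis / np.linalg.norm(axis)).as_matrix()
        expected = (butane_like.ref_coords[[2, 3]] - a) @ R.T + a
        assert np.allclose(coords[[2, 3]], expected, atol=1e-12)

    def test_rigid_fragments_stay_rigid(self, fixture_ntor6):
        lig = fixture_ntor6.ligand
        rng = np.random.default_rng(3)
        X = np.concatenate(
            [
                rng.uniform(-3, 3, 3),
                rng.standard_normal(4),
                rng.uniform(-np.pi, np.pi, lig.n_torsions),
            ]
        )
        coords = apply_pose_batch(lig, X[None, :])[0]
        ref = lig.ref_coords
        for i, j in lig.bonds:
            d_ref = np.linalg.norm(ref[i] - ref[j])
            d_new = np.linalg.norm(coords[i] - coords[j])
            assert d_new == pytest.approx(d_ref, abs=1e-9)

    def test_arity_mismatch_rejected(self, butane_like):
        with pytest.raises(ValueError):
            apply_pose_batch(butane_like, np.zeros((1, 9)))


class TestTrilinear:
    def test_node_value_recovered_exactly(self, small_maps):
        _, maps = small_maps
        grid = maps.affinity["C"]
        point = maps.origin + maps.spacing * np.array([5, 7, 3])
        out = trilinear(grid, maps.origin, maps.spacing, point[None, :])
        assert out[0] == pytest.approx(grid[5, 7, 3], rel=1e-12)

    def test_edge_midpoint_is_mean_of_nodes(self, small_maps):
        _, maps = small_maps
        grid = maps.affinity["C"]
        point = maps.origin + maps.spacing * np.array([5.5, 7, 3])
        out = trilinear(grid, maps.origin, maps.spacing, point[None, :])
        assert out[0] == pytest.approx((grid[5, 7, 3] + grid[6, 7, 3]) / 2, rel=1e-12)

    def test_interior_points_match_weighted_corner_oracle(self, small_maps):
        _, maps = small_maps
        grid = maps.electrostatic
        rng = np.random.default_rng(4)
        pts = maps.origin + rng.uniform(1, 40, size=(50, 3)) * maps.spacing
        ours = trilinear(grid, maps.origin, maps.spacing, pts)
        for p, v in zip(pts, ours):
            u = (p - maps.origin) / maps.spacing
            i = u.astype(int)
            f = u - i
            acc = 0.0
            for dx in (0, 1):
                for dy in (0, 1):
                    for dz in (0, 1):
                        w = (
                            (f[0] if dx else 1 - f[0])
                            * (f[1] if dy else 1 - f[1])
                            * (f[2] if dz else 1 - f[2])
                        )
                        acc += w * grid[i[0] + dx, i[1] + dy, i[2] + dz]
            assert v == pytest.approx(acc, rel=1e-10, abs=1e-12)

    def test_outside_point_returns_penalty(self, small_maps):
        _, maps = small_maps
        out = trilinear(
            maps.affinity["C"], maps.origin, maps.spacing, np.array([[999.0, 0, 0]])
        )
        assert out[0] == OUT_OF_GRID_PENALTY


class TestBuildMaps:
    def test_lj_minimum_at_equilibrium_distance(self):
        eps, req = _combined_lj("C", "C")
        receptor = [("C", 0.0, np.zeros(3))]
        # place a node exactly at r_eq by choosing origin/spacing accordingly
        maps = build_maps(receptor, np.zeros(3), spacing=req / 4, npts=16)
        node = maps.origin + (req / 4) * np.array([12, 8, 8])  # distance req on +x
        val = trilinear(maps.affinity["C"], maps.origin, maps.spacing, node[None, :])
        assert val[0] == pytest.approx(-eps, rel=1e-9)

    def test_electrostatic_linearity_in_charges(self):
        rng = np.random.default_rng(5)
        atoms = [("C", float(q), rng.uniform(-3, 3, 3)) for q in rng.uniform(-1, 1, 4)]
        doubled = [(t, 2 * q, xyz) for t, q, xyz in atoms]
        m1 = build_maps(atoms, np.zeros(3), spacing=0.5, npts=16)
        m2 = build_maps(doubled, np.zeros(3), spacing=0.5, npts=16)
        # linear wherever the cap does not bind
        free = np.abs(m1.electrostatic) < 400.0
        assert np.allclose(
            m2.electrostatic[free], 2 * m1.electrostatic[free], rtol=1e-9
        )

    def test_clash_nodes_capped(self):
        receptor = [("C", 0.0, np.zeros(3))]
        maps = build_maps(receptor, np.zeros(3), spacing=0.5, npts=8)
        assert maps.affinity["C"].max() <= 1.0e5
        assert np.isfinite(maps.affinity["C"]).all()

    def test_empty_receptor_rejected(self):
        with pytest.raises(ValueError):
            build_maps([], np.zeros(3))


class TestScoring:
    def test_single_neutral_atom_at_node_scores_node_affinity(self, small_maps):
        _, maps = small_maps
        node_idx = np.array([10, 10, 10])
        node = maps.origin + maps.spacing * node_idx
        lig = LigandModel(
            names=("C1",),
            types=("C",),
            charges=np.array([0.0]),
            ref_coords=node[None, :],
            bonds=(),
            root=(0,),
            branches=(),
        )
        g = DockingGenotype(np.zeros(3), np.array([0, 0, 0, 1.0]), [])
        pose = score_pose(lig, maps, g)
        expected = maps.affinity["C"][tuple(node_idx)]
        assert pose.docked_energy == pytest.approx(expected, rel=1e-9)

    def test_ligand_outside_grid_dominated_by_penalty(self, butane_like, small_maps):
        _, maps = small_maps
        g = DockingGenotype(np.array([500.0, 0, 0]), np.array([0, 0, 0, 1.0]), [0.0])
        pose = score_pose(butane_like, maps, g)
        assert pose.docked_energy >= OUT_OF_GRID_PENALTY

    def test_kernel_matches_numpy_reference_route(self, fixture_ntor6):
        obj = fixture_ntor6.objective()
        rng = np.random.default_rng(6)
        X = fixture_ntor6.space().sample(rng, size=64)
        ei_k, et_k = obj.energies(X)
        ei_n, et_n = obj.energies_reference(X)
        assert np.allclose(ei_k, ei_n, rtol=1e-9, atol=1e-7)
        assert np.allclose(et_k, et_n, rtol=1e-9, atol=1e-9)

    def test_grid_energy_matches_continuous_pairwise_oracle(self, butane_like, small_maps):
        """Docked energy agrees with a direct no-grid pairwise sum within the
        grid-discretization tolerance."""
        receptor = [
            ("C", -1.0, np.array([6.0, 0.0, 0.0])),
            ("O", -0.5, np.array([-4.0, 4.0, 1.0])),
            ("N", 0.5, np.array([0.0, -5.0, -3.0])),
        ]
        maps = build_maps(receptor, np.zeros(3), spacing=0.25, npts=72)
        obj = DockingObjective(butane_like, maps)
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(400):
            if checked >= 10:
                break
            g = DockingGenotype(
                rng.uniform(-1.5, 1.5, 3),
                rng.standard_normal(4),
                rng.uniform(-np.pi, np.pi, 1),
            )
            coords = apply_pose(butane_like, g)
            # direct intermolecular sum
            e_inter = 0.0
            nearest = np.inf
            for i in range(4):
                for t, qr, xyz in receptor:
                    r2 = np.sum((coords[i] - xyz) ** 2)
                    nearest = min(nearest, np.sqrt(r2))
                    eps, req = _combined_lj(butane_like.types[i], t)
                    a6 = (req**2 / r2) ** 3
                    e_inter += eps * (a6**2 - 2 * a6)
                    e_inter += butane_like.charges[i] * qr / (4 * r2)
            if nearest < 3.4:  # avoid the steep wall where lattice error blows up
                continue
            checked += 1
            # internal part
            a6 = (
                _combined_lj("C", "C")[1] ** 2 / np.sum((coords[0] - coords[3]) ** 2)
            ) ** 3
            e_int = _combined_lj("C", "C")[0] * (a6**2 - 2 * a6) + (
                butane_like.charges[0] * butane_like.charges[3]
            ) / (4 * np.sum((coords[0] - coords[3]) ** 2))
            total = float(obj(g.to_vector()[None, :])[0])
            assert total == pytest.approx(e_inter + e_int, abs=0.5)
        assert checked >= 5  # enough clash-free poses actually compared

    def test_score_invariant_under_atom_relabeling(self, small_maps):
        _, maps = small_maps
        rng = np.random.default_rng(8)
        coords = rng.uniform(-2, 2, size=(5, 3))
        types = ("C", "N", "O", "C", "H")
        charges = rng.uniform(-0.5, 0.5, 5)
        bonds = ((0, 1), (1, 2), (2, 3), (3, 4))
        lig = LigandModel(
            names=tuple(f"A{i}" for i in range(5)),
            types=types,
            charges=charges,
            ref_coords=coords,
            bonds=bonds,
            root=tuple(range(5)),
            branches=(),
        )
        perm = np.array([3, 1, 4, 0, 2])
        inv = np.argsort(perm)
        lig_p = LigandModel(
            names=tuple(f"A{i}" for i in perm),
            types=tuple(types[i] for i in perm),
            charges=charges[perm],
            ref_coords=coords[perm],
            bonds=tuple(tuple(sorted((int(inv[i]), int(inv[j])))) for i, j in bonds),
            root=tuple(range(5)),
            branches=(),
        )
        g = DockingGenotype(np.array([0.3, -0.2, 0.1]), rng.standard_normal(4), [])
        p1 = score_pose(lig, maps, g)
        p2 = score_pose(lig_p, maps, g)
        assert p1.docked_energy == pytest.approx(p2.docked_energy, rel=1e-9)

    def test_binding_score_adds_torsion_penalty(self, fixture_ntor6):
        obj = fixture_ntor6.objective()
        pose = obj.score(fixture_ntor6.reference_genotype)
        e_inter, e_internal = obj.energies(
            fixture_ntor6.reference_genotype.to_vector()[None, :]
        )
        assert pose.docked_energy == pytest.approx(float(e_inter[0] + e_internal[0]))
        assert pose.binding_score == pytest.approx(float(e_inter[0]) + 0.3 * 6)


class TestPdbqtIO:
    def test_roundtrip_preserves_model_exactly(self, fixture_ntor6):
        lig = fixture_ntor6.ligand
        text = write_pdbqt(lig)
        back = parse_pdbqt(text)
        assert back.names == lig.names
        assert back.types == lig.types
        assert np.array_equal(back.charges, lig.charges)
        assert np.array_equal(back.ref_coords, lig.ref_coords)
        assert set(back.bonds) == set(lig.bonds)
        assert back.root == lig.root
        assert len(back.branches) == len(lig.branches)
        for b1, b2 in zip(back.branches, lig.branches):
            assert (b1.parent_atom, b1.child_atom) == (b2.parent_atom, b2.child_atom)
            assert set(b1.moved) == set(b2.moved)

    def test_branch_count_matches_torsdof(self, fixture_ntor6):
        text = write_pdbqt(fixture_ntor6.ligand)
        assert text.count("BRANCH") - text.count("ENDBRANCH") == 6
        assert "TORSDOF 6" in text

    def test_unclosed_branch_named_in_error(self):
        from driftdock.docking import _format_atom

        text = "\n".join(
            [
                "ROOT",
                _format_atom(1, "C1", np.zeros(3), 0.1, "C"),
                "ENDROOT",
                "BRANCH    1    2",
                _format_atom(2, "C2", np.array([1.5, 0, 0]), 0.1, "C"),
            ]
        )
        with pytest.raises(PdbqtError, match="unclosed BRANCH 1 2"):
            parse_pdbqt(text)

    def test_malformed_atom_line_reports_line_number(self):
        text = "ROOT\nATOM      1  C1  LIG A   1   garbage\nENDROOT\n"
        with pytest.raises(PdbqtError, match="line 2"):
            parse_pdbqt(text)

    def test_torsdof_mismatch_warns(self):
        from driftdock.docking import _format_atom

        text = "\n".join(
            [
                "ROOT",
                _format_atom(1, "C1", np.zeros(3), 0.1, "C"),
                "ENDROOT",
                "TORSDOF 3",
            ]
        )
        with pytest.warns(UserWarning, match="TORSDOF"):
            parse_pdbqt(text)

    def test_posed_conformation_written(self, fixture_ntor6):
        fx = fixture_ntor6
        text = write_pdbqt(fx.ligand, fx.reference_genotype)
        back = parse_pdbqt(text)
        assert np.allclose(back.ref_coords, fx.reference_coordinates, atol=1e-3)

    def test_receptor_roundtrip(self, fixture_ntor6):
        text = write_receptor_pdbqt(fixture_ntor6.receptor_atoms)
        back = parse_receptor_pdbqt(text)
        assert len(back) == len(fixture_ntor6.receptor_atoms)
        for (t1, q1, x1), (t2, q2, x2) in zip(back, fixture_ntor6.receptor_atoms):
            assert t1 == t2 and q1 == pytest.approx(q2) and np.allclose(x1, x2)


class TestMapIO:
    def test_text_roundtrip(self):
        receptor = [("C", -0.4, np.array([1.0, 0, 0])), ("O", 0.2, np.array([0, 1.0, 0]))]
        maps = build_maps(receptor, np.zeros(3), spacing=0.5, npts=8)
        back = read_maps(write_maps(maps))
        assert back.npts == maps.npts
        assert back.spacing == pytest.approx(maps.spacing)
        assert np.allclose(back.origin, maps.origin)
        for t in maps.affinity:
            assert np.allclose(back.affinity[t], maps.affinity[t], rtol=1e-6)
        assert np.allclose(back.electrostatic, maps.electrostatic, rtol=1e-6)
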