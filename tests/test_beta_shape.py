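import math

import numpy as np
import pytest
from scipy.spatial import ConvexHull

from betapocket.beta_shape import (
    TopologyError,
    beta_boundary,
    beta_shape_volume,
    export_mesh_obj,
    export_profile_csv,
    beta_triangles,
    boundary_adjacency,
    boundary_atoms,
    compute_exposure_profile,
    exposure_radius,
    fibonacci_directions,
    is_exposed,
)
from betapocket.structure_io import MolecularModel

DENSE = 10_000  # brute-force oracle direction count


def caged_atom():
    """Unit atom enclosed by 30 unit atoms on a 2.5 A shell around it."""
    shell = fibonacci_directions(30) * 2.5
    return MolecularModel.from_arrays(np.vstack([[0, 0, 0], shell]), 1.0, "C")


class TestIsExposed:
    def test_isolated_atom_always_exposed(self):
        m = MolecularModel.from_arrays([[0, 0, 0]], 1.0, "C")
        for beta in (0.0, 1.4, 100.0):
            assert is_exposed(m, 0, beta)

    def test_open_pair_both_exposed(self):
        m = MolecularModel.from_arrays([[0, 0, 0], [3, 0, 0]], 1.0, "C")
        assert is_exposed(m, 0, 1.4) and is_exposed(m, 1, 1.4)

    def test_caged_atom_blocked_even_with_dense_oracle(self):
        m = caged_atom()
        assert not is_exposed(m, 0, 1.4)
        assert not is_exposed(m, 0, 1.4, n_directions=DENSE)

    def test_negative_beta_rejected(self):
        m = MolecularModel.from_arrays([[0, 0, 0]], 1.0, "C")
        with pytest.raises(ValueError):
            is_exposed(m, 0, -0.1)


class TestExposureRadius:
    def test_isolated_atom_unbounded(self):
        m = MolecularModel.from_arrays([[0, 0, 0]], 1.0, "C")
        assert exposure_radius(m, 0, beta_cap=50.0) == math.inf

    def test_convex_tetrahedron_all_unbounded(self, tetrahedron):
        for i in range(4):
            assert exposure_radius(tetrahedron, i, beta_cap=50.0) == math.inf

    def test_caged_atom_blocked_below_water_but_not_sealed(self):
        # small probes still thread the gaps of the cage, so the exposure
        # interval is short but not empty
        b = exposure_radius(caged_atom(), 0, beta_cap=10.0)
        assert 0.0 < b < 1.4

    def test_open_cage_matches_dense_direction_oracle(self):
        """A caged atom with a mouth: the mouth sets a clean, non-grazing throat."""
        shell = fibonacci_directions(30) * 2.5
        shell = shell[shell[:, 2] <= 2.0]  # remove the top cap -> mouth
        m = MolecularModel.from_arrays(np.vstack([[0, 0, 0], shell]), 1.0, "C")
        fast = exposure_radius(m, 0, beta_cap=10.0, tol=0.01)
        dense = exposure_radius(m, 0, beta_cap=10.0, tol=0.01, n_directions=DENSE)
        assert fast == pytest.approx(dense, abs=0.02)
        # the mouth admits larger probes than the closed cage's lattice gaps
        assert fast > exposure_radius(caged_atom(), 0, beta_cap=10.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_never_overestimates_dense_direction_oracle(self, seed):
        """Direction sampling can only miss free probes, never invent them."""
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-3, 3, (15, 3))
        m = MolecularModel.from_arrays(pts, 1.2, "C")
        for i in range(0, 15, 4):
            fast = exposure_radius(m, i, beta_cap=25.0, tol=0.01)
            dense = exposure_radius(
                m, i, beta_cap=25.0, tol=0.01, n_directions=DENSE
            )
            assert fast <= dense + 0.02 or math.isinf(dense)


class TestBoundaryAtoms:
    def test_all_atoms_of_spread_model_on_boundary_at_zero(self):
        m = MolecularModel.from_arrays(
            [[0, 0, 0], [3, 0, 0], [0, 3, 0]], 1.0, "C"
        )
        assert boundary_atoms(m, 0.0) == {0, 1, 2}

    def test_only_unbounded_atoms_at_huge_beta(self, tetrahedron):
        assert boundary_atoms(tetrahedron, 1e3) == {0, 1, 2, 3}
        caged = caged_atom()
        assert 0 not in boundary_atoms(caged, 1e3)

    def test_monotone_in_beta(self):
        rng = np.random.default_rng(11)
        m = MolecularModel.from_arrays(rng.uniform(-4, 4, (25, 3)), 1.3, "C")
        sets = [boundary_atoms(m, b) for b in (0.3, 1.4, 3.0, 6.0)]
        for small, large in zip(sets, sets[1:]):
            assert large <= small

    def test_profile_matches_direct_computation(self):
        rng = np.random.default_rng(12)
        m = MolecularModel.from_arrays(rng.uniform(-3, 3, (12, 3)), 1.2, "C")
        profile = compute_exposure_profile(m, beta_cap=20.0)
        # profile thresholding and the direct tangency sweep agree away from
        # the bisection tolerance boundary
        for beta in (1.4, 4.0):
            direct = boundary_atoms(m, beta)
            via_profile = {
                i for i, b in enumerate(profile.beta) if b >= beta + 2 * profile.tol
            }
            assert via_profile <= direct


class TestBetaTriangles:
    def test_tetrahedron_faces_exactly(self, tetrahedron):
        # throat radius 2/sqrt(3) - 1 < 1.4: the probe cannot pass a face
        tris = beta_triangles(tetrahedron, 1.4)
        assert sorted(tris) == [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]

    def test_two_atoms_have_no_triples(self):
        m = MolecularModel.from_arrays([[0, 0, 0], [3, 0, 0]], 1.0, "C")
        assert beta_triangles(m, 1.4) == []

    def test_distance_pruning_matches_brute_force(self, tetrahedron):
        # every reported triple must admit a tangent probe clearing all atoms
        from betapocket.sphere_geometry import Sphere, tangent_probe_centers

        c, r = tetrahedron.centers, tetrahedron.radii
        beta = 1.4
        for i, j, k in beta_triangles(tetrahedron, beta):
            sols = tangent_probe_centers(
                Sphere(c[i], r[i]), Sphere(c[j], r[j]), Sphere(c[k], r[k]), beta
            )
            ok = False
            for p in sols:
                d = np.linalg.norm(c - p, axis=1) - r - beta
                d[[i, j, k]] = 0.0
                ok = ok or np.all(d >= -1e-6)
            assert ok


class TestBetaShapeVolume:
    def test_regular_tetrahedron_closed_form(self, tetrahedron):
        expect = 2.0**3 / (6.0 * math.sqrt(2.0))
        assert beta_shape_volume(tetrahedron, 1.4) == pytest.approx(expect, abs=1e-9)

    def test_collinear_model_raises_topology_error(self):
        m = MolecularModel.from_arrays(
            [[0, 0, 0], [2, 0, 0], [4, 0, 0]], 1.0, "C"
        )
        with pytest.raises(TopologyError):
            beta_shape_volume(m, 1.4)

    def test_large_beta_approaches_convex_hull(self):
        rng = np.random.default_rng(5)
        pts = np.array(
            [[i, j, k] for i in (0, 3.0) for j in (0, 3.0) for k in (0, 3.0)]
        ) + rng.normal(0, 0.15, (8, 3))
        m = MolecularModel.from_arrays(pts, 1.0, "C")
        assert beta_shape_volume(m, 60.0) == pytest.approx(
            ConvexHull(pts).volume, rel=1e-6
        )

    def test_below_hull_volume_and_monotone_in_beta(self, tetrahedron):
        hull = ConvexHull(tetrahedron.centers).volume
        vols = [beta_shape_volume(tetrahedron, b) for b in (1.4, 3.0, 10.0)]
        assert all(v <= hull + 1e-9 for v in vols)
        assert vols == sorted(vols)


class TestBoundaryAdjacency:
    def test_touching_pair_connected(self):
        m = MolecularModel.from_arrays([[0, 0, 0], [2, 0, 0]], 1.0, "C")
        assert list(boundary_adjacency(m, 0.0).edges()) == [(0, 1)]

    def test_distant_pair_disconnected(self):
        m = MolecularModel.from_arrays([[0, 0, 0], [6, 0, 0]], 1.0, "C")
        assert list(boundary_adjacency(m, 1.4).edges()) == []

    def test_components_match_union_find_oracle(self):
        rng = np.random.default_rng(9)
        pts = np.vstack([rng.normal(0, 2, (15, 3)), rng.normal(20, 2, (10, 3))])
        m = MolecularModel.from_arrays(pts, 1.0, "C")
        beta = 0.5
        g = boundary_adjacency(m, beta)

        # independent union-find over the same distance rule
        parent = list(range(25))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(25):
            for j in range(i + 1, 25):
                if np.linalg.norm(pts[i] - pts[j]) <= 2.0 + 2.0 * beta:
                    parent[find(i)] = find(j)
        oracle = {}
        for i in range(25):
            oracle.setdefault(find(i), set()).add(i)
        import networkx as nx

        got = {frozenset(comp) for comp in nx.connected_components(g)}
        assert got == {frozenset(c) for c in oracle.values()}


class TestBetaBoundaryAssembly:
    def test_tetrahedron_boundary_description(self, tetrahedron):
        b = beta_boundary(tetrahedron, 1.4)
        assert b.boundary_atom_ids == frozenset({0, 1, 2, 3})
        assert len(b.triangles) == 4
        assert b.adjacency.number_of_edges() == 6  # complete K4

    def test_exports_write_readable_files(self, tetrahedron, tmp_path):
        obj = tmp_path / "tet.obj"
        export_mesh_obj(tetrahedron, 1.4, obj)
        lines = obj.read_text().splitlines()
        assert sum(l.startswith("v ") for l in lines) == 4
        assert sum(l.startswith("f ") for l in lines) == 4
        csv_path = tmp_path / "profile.csv"
        export_profile_csv(compute_exposure_profile(tetrahedron, beta_cap=10.0), csv_path)
        rows = csv_path.read_text().splitlines()
        assert rows[0] == "atom_id,beta_i"
        assert len(rows) == 5


class TestRigidInvariance:
    def test_exposure_and_volume_invariant_under_rigid_motion(
        self, tetrahedron, rigid_motion
    ):
        v_ref = beta_shape_volume(tetrahedron, 1.4)
        for rot, t in rigid_motion:
            moved = MolecularModel.from_arrays(
                tetrahedron.centers @ rot.T + t, tetrahedron.radii, "C"
            )
            assert beta_shape_volume(moved, 1.4) == pytest.approx(v_ref, abs=1e-9)
            assert boundary_atoms(moved, 1.4) == boundary_atoms(tetrahedron, 1.4)

    def test_atom_reordering_invariance(self):
        rng = np.random.default_rng(21)
        pts = rng.uniform(-3, 3, (10, 3))
        m = MolecularModel.from_arrays(pts, 1.2, "C")
        perm = rng.permutation(10)
        mp = MolecularModel.from_arrays(pts[perm], 1.2, "C")
        b = boundary_atoms(m, 1.4)
        bp = boundary_atoms(mp, 1.4)
        assert bp == {int(np.nonzero(perm == i)[0][0]) for i in b}
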