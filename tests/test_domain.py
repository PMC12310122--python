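"""Domain construction, FEM assembly and eigenbasis correctness."""

import numpy as np
import pytest
import scipy.linalg

from lapdyn.domain import (DomainValidationError, TriangleMesh, assemble_fem,
                           brain_slice_mesh, build_graph_domain,
                           compute_basis, load_mesh, load_basis, save_basis,
                           synthetic_connectome, unit_square_mesh, write_off)

UNIT_SQUARE_OFF = """OFF
4 2 0
0 0 0
1 0 0
1 1 0
0 1 0
3 0 1 2
3 0 2 3
"""

UNIT_SQUARE_MSH2 = """$MeshFormat
2.2 0 8
$EndMeshFormat
$Nodes
4
1 0 0 0
2 1 0 0
3 1 1 0
4 0 1 0
$EndNodes
$Elements
2
1 2 2 0 1 1 2 3
2 2 2 0 1 1 3 4
$EndElements
"""


class TestMeshIO:
    def test_off_smallest_valid_mesh(self, tmp_path):
        p = tmp_path / "sq.off"
        p.write_text(UNIT_SQUARE_OFF)
        mesh = load_mesh(str(p))
        assert mesh.n_nodes == 4
        assert mesh.n_triangles == 2

    def test_msh2_parse(self, tmp_path):
        p = tmp_path / "sq.msh"
        p.write_text(UNIT_SQUARE_MSH2)
        mesh = load_mesh(str(p))
        assert mesh.n_nodes == 4
        assert mesh.n_triangles == 2
        assert np.isclose(mesh.triangle_areas().sum(), 1.0)

    def test_out_of_range_index_rejected(self, tmp_path):
        bad = UNIT_SQUARE_OFF.replace("3 0 2 3", "3 0 2 99")
        p = tmp_path / "bad.off"
        p.write_text(bad)
        with pytest.raises(DomainValidationError, match="index"):
            load_mesh(str(p))

    def test_off_round_trip(self, tmp_path):
        mesh = brain_slice_mesh()
        p = tmp_path / "slice.off"
        write_off(mesh, str(p))
        # independent parse of the header line gives the shipped node count
        header = p.read_text().splitlines()[1].split()
        assert int(header[0]) == mesh.n_nodes
        again = load_mesh(str(p))
        assert again.n_nodes == mesh.n_nodes
        np.testing.assert_allclose(again.node_coords, mesh.node_coords,
                                   atol=1e-9)

    def test_degenerate_triangle_rejected(self):
        with pytest.raises(DomainValidationError, match="degenerate"):
            TriangleMesh(np.array([[0.0, 0], [1, 0], [2, 0], [0, 1]]),
                         np.array([[0, 1, 2], [0, 2, 3]]))


class TestFem:
    def test_neumann_kernel_and_partition_of_unity(self):
        fem = assemble_fem(unit_square_mesh(8))
        const = np.ones(fem.n)
        assert np.abs(fem.stiffness @ const).max() < 1e-12
        assert np.isclose(fem.mass.sum(), 1.0, atol=1e-10)

    def test_reference_triangle_mass_matrix(self):
        mesh = TriangleMesh(np.array([[0.0, 0], [1, 0], [0, 1]]),
                            np.array([[0, 1, 2]]))
        fem = assemble_fem(mesh)
        area = 0.5
        expected = area / 12.0 * np.array([[2.0, 1, 1], [1, 2, 1], [1, 1, 2]])
        np.testing.assert_allclose(fem.mass.toarray(), expected, atol=1e-14)

    def test_brain_slice_mesh_valid(self):
        mesh = brain_slice_mesh()
        fem = assemble_fem(mesh)
        assert np.abs(fem.stiffness @ np.ones(fem.n)).max() < 1e-10
        assert np.isclose(fem.mass.sum(), mesh.triangle_areas().sum())


class TestGraph:
    def test_two_node_laplacian(self):
        dom = build_graph_domain(np.array([[0.0, 1.0], [1.0, 0.0]]))
        np.testing.assert_allclose(dom.L, [[1.0, -1.0], [-1.0, 1.0]])

    def test_path_graph_laplacian(self):
        W = np.array([[0.0, 1, 0], [1, 0, 1], [0, 1, 0]])
        dom = build_graph_domain(W)
        np.testing.assert_allclose(
            dom.L, [[1.0, -1, 0], [-1, 2, -1], [0, -1, 1]])

    def test_random_graph_rowsums_and_psd(self, graph10):
        dom, _ = graph10
        np.testing.assert_allclose(dom.L.sum(axis=1), 0.0, atol=1e-12)
        vals = np.linalg.eigvalsh(dom.L)
        assert vals.min() > -1e-10

    def test_negative_weights_rejected(self):
        with pytest.raises(DomainValidationError, match="negative"):
            build_graph_domain(np.array([[0.0, -1.0], [-1.0, 0.0]]))

    def test_disconnected_rejected_unless_allowed(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        with pytest.raises(DomainValidationError, match="connected"):
            build_graph_domain(W)
        dom = build_graph_domain(W, allow_disconnected=True)
        assert dom.n == 4

    def test_asymmetric_input_symmetrized(self):
        W = np.array([[0.0, 2.0], [0.0, 0.0]])
        dom = build_graph_domain(W)
        np.testing.assert_allclose(dom.W, [[0.0, 1.0], [1.0, 0.0]])

    def test_synthetic_connectome_connected_and_normalized(self):
        dom = synthetic_connectome(68, seed=0)
        assert dom.n == 68
        vals = np.linalg.eigvalsh(dom.L)
        assert np.sum(np.abs(vals) < 1e-8) == 1  # exactly one zero eigenvalue
        assert np.isclose(dom.degree.mean(), 1.0)


class TestBasis:
    def test_two_node_closed_form(self, two_node):
        _, basis = two_node
        np.testing.assert_allclose(basis.eigenvalues, [0.0, 2.0], atol=1e-12)

    def test_kernel_mode_constant(self, graph10, square_fem):
        for _, basis in (graph10, square_fem):
            assert abs(basis.eigenvalues[0]) < 1e-10
            phi1 = basis.vectors[:, 0]
            assert np.ptp(phi1) < 1e-8 * max(1.0, abs(phi1[0]))

    def test_orthonormality(self, graph10, square_fem):
        for _, basis in (graph10, square_fem):
            G = basis.gram()
            assert np.abs(G - np.eye(basis.P)).max() < 1e-8

    def test_unit_square_neumann_spectrum(self):
        fem = assemble_fem(unit_square_mesh(22))
        basis = compute_basis(fem, 8)
        nz = basis.eigenvalues[basis.eigenvalues > 1e-8][:6]
        exact = np.array([1, 1, 2, 4, 4, 5]) * np.pi**2
        assert np.all(np.abs(nz - exact) / exact < 0.01)

    def test_dense_oracle_on_seeded_graphs(self):
        # eigenspaces compared through projectors to tolerate degeneracy
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(8, 30))
            W = rng.uniform(0, 1, (n, n)) * (rng.uniform(0, 1, (n, n)) < 0.5)
            W = 0.5 * (W + W.T)
            np.fill_diagonal(W, 0.0)
            W += 1e-3  # ensure connectivity
            np.fill_diagonal(W, 0.0)
            dom = build_graph_domain(W)
            P = n // 2
            basis = compute_basis(dom, P)
            vals, vecs = scipy.linalg.eigh(dom.L)
            np.testing.assert_allclose(basis.eigenvalues, vals[:P], atol=1e-8)
            proj_ref = vecs[:, :P] @ vecs[:, :P].T
            proj = basis.vectors @ basis.vectors.T
            assert np.abs(proj - proj_ref).max() < 1e-6

    def test_mesh_refinement_convergence(self):
        errs = []
        for nx in (8, 16, 32):
            basis = compute_basis(assemble_fem(unit_square_mesh(nx)), 3)
            errs.append(abs(basis.eigenvalues[1] - np.pi**2) / np.pi**2)
        assert errs[0] > errs[1] > errs[2]

    def test_p_out_of_range(self, two_node):
        dom, _ = two_node
        with pytest.raises(DomainValidationError):
            compute_basis(dom, 3)

    def test_basis_archive_round_trip(self, square_fem, tmp_path):
        _, basis = square_fem
        p = tmp_path / "basis.h5"
        save_basis(basis, str(p))
        again = load_basis(str(p))
        np.testing.assert_array_equal(again.eigenvalues, basis.eigenvalues)
        np.testing.assert_array_equal(again.vectors, basis.vectors)
        assert again.mass is not None
        assert (again.mass != basis.mass).nnz == 0
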