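"""Adjacency construction and CAR precision matrices.

The Leroux oracle here rebuilds the joint log-density from the model's
full conditionals alone (Brook's lemma telescoping) and checks it
against the quadratic form of the precision matrix, on every connected
labelled graph with up to 5 nodes.
"""

import itertools

import numpy as np
import networkx as nx
import pytest
import scipy.sparse as sp
from shapely.geometry import box

import arealrisk as ar
from arealrisk.lattice import LatticeError


def all_connected_graphs(max_nodes=5):
    """Every connected labelled graph on 2..max_nodes nodes."""
    for n in range(2, max_nodes + 1):
        pairs = list(itertools.combinations(range(n), 2))
        for mask in range(1, 2 ** len(pairs)):
            edges = [p for k, p in enumerate(pairs) if mask >> k & 1]
            G = nx.Graph(edges)
            G.add_nodes_from(range(n))
            if nx.is_connected(G):
                yield n, edges


def lattice_from_edges(n, edges):
    rows, cols = [], []
    for a, b in edges:
        rows += [a, b]
        cols += [b, a]
    W = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    return ar.Lattice(tuple(range(n)), W)


class TestGridLattice:
    @pytest.mark.parametrize(
        "rows,cols,contig,expect_counts,expect_edges",
        [
            (2, 2, "rook", [2, 2, 2, 2], 4),
            (1, 1, "rook", [0], 0),
            (1, 3, "rook", [1, 2, 1], 2),
        ],
    )
    def test_small_grids(self, rows, cols, contig, expect_counts, expect_edges):
        lat = ar.grid_lattice(rows, cols, contig)
        assert list(lat.n_neighbors) == expect_counts
        assert lat.n_edges == expect_edges

    def test_queen_center_cell_has_eight_neighbors(self):
        lat = ar.grid_lattice(3, 3, "queen")
        assert lat.n_neighbors[lat.index_of("r1c1")] == 8

    @pytest.mark.parametrize("rows,cols", [(0, 3), (3, 0), (-1, 2)])
    def test_nonpositive_dimensions_rejected(self, rows, cols):
        with pytest.raises(ValueError):
            ar.grid_lattice(rows, cols)


class TestBuildAdjacency:
    def test_shared_edge_makes_neighbors(self):
        lat = ar.build_adjacency({"A": box(0, 0, 1, 1), "B": box(1, 0, 2, 1)})
        assert list(lat.n_neighbors) == [1, 1]

    def test_disjoint_squares_not_neighbors(self):
        with pytest.warns(UserWarning, match="no neighbours"):
            lat = ar.build_adjacency(
                {"A": box(0, 0, 1, 1), "B": box(11, 0, 12, 1)}
            )
        assert list(lat.n_neighbors) == [0, 0]
        assert lat.isolated_areas() == ["A", "B"]

    def test_queen_grid_of_squares_center_has_eight(self):
        polys = {
            (i, j): box(j, i, j + 1, i + 1) for i in range(3) for j in range(3)
        }
        lat = ar.build_adjacency(polys, contiguity="queen")
        assert lat.n_neighbors[lat.index_of((1, 1))] == 8

    def test_rook_excludes_corner_touch(self):
        polys = {"A": box(0, 0, 1, 1), "B": box(1, 1, 2, 2)}
        with pytest.warns(UserWarning):
            lat = ar.build_adjacency(polys, contiguity="rook")
        assert lat.n_edges == 0
        lat_q = ar.build_adjacency(polys, contiguity="queen")
        assert lat_q.n_edges == 1

    def test_empty_set_rejected(self):
        with pytest.raises(LatticeError):
            ar.build_adjacency({})


class TestLatticeInvariants:
    def test_asymmetric_adjacency_rejected(self):
        W = sp.csr_matrix(np.array([[0.0, 1.0], [0.0, 0.0]]))
        with pytest.raises(LatticeError):
            ar.Lattice(("a", "b"), W)

    def test_nonbinary_rejected(self):
        W = sp.csr_matrix(np.array([[0.0, 2.0], [2.0, 0.0]]))
        with pytest.raises(LatticeError):
            ar.Lattice(("a", "b"), W)

    def test_duplicate_ids_rejected(self):
        W = sp.csr_matrix((2, 2))
        with pytest.raises(LatticeError):
            ar.Lattice(("a", "a"), W)

    def test_neighbor_counts_are_row_sums(self):
        lat = ar.grid_lattice(3, 4, "queen")
        assert np.array_equal(
            lat.n_neighbors, np.asarray(lat.W.sum(axis=1)).ravel()
        )


class TestIcarPrecision:
    def test_path_of_three_is_graph_laplacian(self, path3):
        Q = ar.icar_precision(path3, tau=1.0).toarray()
        expected = np.array([[1, -1, 0], [-1, 2, -1], [0, -1, 1]], dtype=float)
        assert np.array_equal(Q, expected)

    def test_row_sums_zero(self):
        for lat in (ar.grid_lattice(3, 3), ar.grid_lattice(2, 5, "queen")):
            Q = ar.icar_precision(lat, tau=1.7)
            assert np.allclose(np.asarray(Q.sum(axis=1)).ravel(), 0.0, atol=1e-12)

    def test_four_cycle_scaled(self):
        lat = lattice_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
        Q = ar.icar_precision(lat, tau=2.0).toarray()
        assert np.allclose(np.diag(Q), 4.0)
        for i, j in [(0, 1), (1, 2), (2, 3), (3, 0)]:
            assert Q[i, j] == -2.0

    def test_invalid_tau(self, path3):
        with pytest.raises(ValueError):
            ar.icar_precision(path3, tau=0.0)


class TestLerouxPrecision:
    def test_rho_zero_is_identity(self):
        lat = ar.grid_lattice(3, 3, "queen")
        Q = ar.leroux_precision(lat, rho=0.0, sigma2=1.0).toarray()
        assert np.allclose(Q, np.eye(9))

    def test_rho_one_equals_icar(self):
        lat = ar.grid_lattice(2, 3)
        Q1 = ar.leroux_precision(lat, rho=1.0, sigma2=1.0).toarray()
        Q2 = ar.icar_precision(lat, tau=1.0).toarray()
        assert np.allclose(Q1, Q2)

    def test_two_node_half_rho(self):
        lat = ar.grid_lattice(1, 2)
        Q = ar.leroux_precision(lat, rho=0.5, sigma2=1.0).toarray()
        assert np.allclose(Q, [[1.0, -0.5], [-0.5, 1.0]])

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_invalid_rho(self, bad, path3):
        with pytest.raises(ValueError):
            ar.leroux_precision(path3, rho=bad)

    def test_conditional_moments_match_model(self):
        """Full conditionals implied by the joint precision equal the
        model's stated conditional mean and variance on every connected
        graph with <= 5 nodes."""
        rho, sigma2 = 0.65, 1.3
        for n, edges in all_connected_graphs(5):
            lat = lattice_from_edges(n, edges)
            Q = ar.leroux_precision(lat, rho, sigma2).toarray()
            W = lat.W.toarray()
            d = lat.n_neighbors
            for i in range(n):
                denom = rho * d[i] + 1 - rho
                # conditional of a GMRF: var = 1/Q_ii, mean coeffs -Q_ij/Q_ii
                assert np.isclose(1.0 / Q[i, i], sigma2 / denom, atol=1e-10)
                coeffs = -Q[i, :] / Q[i, i]
                expected = rho * W[i, :] / denom
                expected[i] = 0.0
                coeffs[i] = 0.0
                assert np.allclose(coeffs, expected, atol=1e-10)

    def test_brooks_lemma_reconstruction(self):
        """Rebuild the joint density from the full conditionals alone
        (Brook's lemma telescoping from 0) and compare with the
        quadratic form of the precision, on all connected graphs <= 5
        nodes."""
        rng = np.random.default_rng(42)
        rho, sigma2 = 0.5, 0.8

        def cond_logpdf(x_i, i, x, W, d):
            denom = rho * d[i] + 1 - rho
            m = rho * (W[i] @ x) / denom
            var = sigma2 / denom
            return -0.5 * (x_i - m) ** 2 / var

        for n, edges in all_connected_graphs(4):
            lat = lattice_from_edges(n, edges)
            Q = ar.leroux_precision(lat, rho, sigma2).toarray()
            W = lat.W.toarray()
            d = lat.n_neighbors
            phi = rng.normal(size=n)
            # telescoping: log p(phi) - log p(0)
            total = 0.0
            x_hi = phi.copy()  # coordinates 0..i-1 at phi, rest at 0
            for i in range(n):
                x = np.concatenate([phi[:i], np.zeros(n - i)])
                total += cond_logpdf(phi[i], i, x, W, d)
                total -= cond_logpdf(0.0, i, x, W, d)
            direct = -0.5 * phi @ Q @ phi
            assert np.isclose(total, direct, atol=1e-10)


class TestProperCarPrecision:
    def test_gamma_zero_is_scaled_degree(self):
        lat = ar.grid_lattice(2, 3)
        Q = ar.proper_car_precision(lat, gamma=0.0, tau=2.0).toarray()
        assert np.allclose(Q, 2.0 * np.diag(lat.n_neighbors))

    def test_two_node_eigenvalues(self):
        lat = ar.grid_lattice(1, 2)
        Q = ar.proper_car_precision(lat, gamma=0.5, tau=1.0).toarray()
        assert np.allclose(Q, [[1.0, -0.5], [-0.5, 1.0]])
        assert np.isclose(np.linalg.eigvalsh(Q).min(), 0.5)

    def test_gamma_to_one_limit_is_icar(self):
        lat = ar.grid_lattice(2, 2)
        Q_icar = ar.icar_precision(lat, tau=1.0).toarray()
        Q_near = ar.proper_car_precision(lat, gamma=1 - 1e-9, tau=1.0).toarray()
        assert np.allclose(Q_near, Q_icar, atol=1e-6)

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5])
    def test_invalid_gamma(self, bad, path3):
        with pytest.raises(ValueError):
            ar.proper_car_precision(path3, gamma=bad)


class TestFamilyProperties:
    @pytest.mark.parametrize("family,kwargs", [
        ("icar", {"tau": 2.0}),
        ("leroux", {"rho": 0.7, "sigma2": 0.5}),
        ("proper_car", {"gamma": 0.8, "tau": 1.5}),
        ("iid", {"tau": 3.0}),
    ])
    def test_symmetry(self, family, kwargs):
        lat = ar.grid_lattice(3, 3, "queen")
        Q = ar.PrecisionSpec(family=family, **kwargs).matrix(lat).toarray()
        assert np.allclose(Q, Q.T, atol=1e-14)

    def test_interior_parameters_positive_definite(self):
        """Leroux and proper CAR are PD strictly inside their domains
        (dense eigendecomposition on graphs up to 10 nodes)."""
        graphs = [
            ar.grid_lattice(2, 5),
            ar.grid_lattice(3, 3, "queen"),
            lattice_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)]),
        ]
        for lat in graphs:
            for rho in (0.0, 0.5, 0.99):
                Q = ar.leroux_precision(lat, rho, 1.0).toarray()
                assert np.linalg.eigvalsh(Q).min() > 0
            for g in (0.0, 0.5, 0.99):
                Q = ar.proper_car_precision(lat, g, 1.0).toarray()
                assert np.linalg.eigvalsh(Q).min() > 0

    def test_precision_spec_validation(self):
        with pytest.raises(ValueError):
            ar.PrecisionSpec(family="magic")
        with pytest.raises(ValueError):
            ar.PrecisionSpec(family="leroux", rho=1.2)
        with pytest.raises(ValueError):
            ar.PrecisionSpec(family="proper_car", gamma=1.0)


class TestIO:
    def test_adjacency_csv_round_trip(self, tmp_path):
        lat = ar.grid_lattice(3, 3, "queen")
        path = tmp_path / "adj.csv"
        from arealrisk.lattice import read_adjacency_csv, write_adjacency_csv

        write_adjacency_csv(lat, path)
        back = read_adjacency_csv(path, area_ids=lat.area_ids)
        assert back.area_ids == lat.area_ids
        assert (back.W != lat.W).nnz == 0

    def test_geojson_reader(self, tmp_path):
        import json

        gj = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {"area_id": "A"},
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [[[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]]],
                    },
                },
                {
                    "type": "Feature",
                    "properties": {"area_id": "B"},
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [[[1, 0], [2, 0], [2, 1], [1, 1], [1, 0]]],
                    },
                },
            ],
        }
        p = tmp_path / "areas.geojson"
        p.write_text(json.dumps(gj))
        from arealrisk.lattice import read_geojson_areas

        polys = read_geojson_areas(p)
        lat = ar.build_adjacency(polys)
        assert list(lat.n_neighbors) == [1, 1]
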