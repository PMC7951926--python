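"""Areal adjacency graphs and CAR-family precision matrices.

Disease-mapping models on areal units (zip codes, census tracts, grid
cells) encode spatial dependence through a binary contiguity matrix
``W``: ``w_ij = 1`` when areas *i* and *j* share a boundary, 0
otherwise.  This module builds and validates that graph and constructs
the sparse precision matrices of the Gaussian Markov random field
priors used for spatially structured random effects:

* **ICAR** (intrinsic CAR, "Besag improper"): ``Q = tau * (D - W)``,
  the graph Laplacian scaled by a precision parameter.  Singular, with
  null space spanned by the constant vector on each connected
  component, so it is only usable with a sum-to-zero constraint.
* **Proper CAR** ("Besag proper"): ``Q = tau * (D - gamma * W)`` with
  propriety parameter ``gamma in [0, 1)``; positive definite on a
  connected graph.
* **Leroux**: ``Q = (1/sigma2) * (rho * (D - W) + (1 - rho) * I)``,
  interpolating between independence (``rho = 0``) and the ICAR model
  (``rho = 1``).  Its full conditionals are
  ``phi_i | phi_-i ~ N(rho * sum_j w_ij phi_j / (rho * d_i + 1 - rho),
  sigma2 / (rho * d_i + 1 - rho))``.

``D = diag(d_i)`` is the diagonal matrix of neighbour counts.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from shapely.geometry import shape as _shapely_shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "Lattice",
    "PrecisionSpec",
    "build_adjacency",
    "grid_lattice",
    "icar_precision",
    "leroux_precision",
    "proper_car_precision",
    "iid_precision",
    "read_geojson_areas",
    "read_adjacency_csv",
    "write_adjacency_csv",
]


class LatticeError(ValueError):
    """Invalid areal graph input (duplicate IDs, asymmetry, ...)."""


@dataclass(frozen=True)
class Lattice:
    """An areal contiguity graph.

    Parameters
    ----------
    area_ids
        Ordered unique identifiers, one per area.  All matrices and
        vectors produced from this lattice follow this ordering.
    W
        Symmetric binary sparse adjacency matrix with zero diagonal.
    """

    area_ids: tuple
    W: sp.csr_matrix

    def __post_init__(self):
        ids = tuple(self.area_ids)
        if len(ids) == 0:
            raise LatticeError("lattice must contain at least one area")
        if len(set(ids)) != len(ids):
            raise LatticeError("duplicate area IDs")
        W = sp.csr_matrix(self.W)
        if W.shape != (len(ids), len(ids)):
            raise LatticeError(
                f"adjacency shape {W.shape} does not match {len(ids)} areas"
            )
        if W.diagonal().any():
            raise LatticeError("adjacency has nonzero diagonal")
        if (W != W.T).nnz != 0:
            raise LatticeError("adjacency is not symmetric")
        data = W.data
        if data.size and not np.all((data == 0) | (data == 1)):
            raise LatticeError("adjacency entries must be 0 or 1")
        object.__setattr__(self, "area_ids", ids)
        object.__setattr__(self, "W", W)

    @property
    def n(self) -> int:
        return len(self.area_ids)

    @property
    def n_neighbors(self) -> np.ndarray:
        """Per-area neighbour counts (row sums of W)."""
        return np.asarray(self.W.sum(axis=1)).ravel().astype(int)

    @property
    def n_edges(self) -> int:
        return int(self.W.nnz // 2)

    def index_of(self, area_id) -> int:
        try:
            return self.area_ids.index(area_id)
        except ValueError:
            raise KeyError(f"unknown area ID {area_id!r}") from None

    def components(self) -> tuple[int, np.ndarray]:
        """Connected components: (count, label per area)."""
        ncomp, labels = connected_components(self.W, directed=False)
        return int(ncomp), labels

    def isolated_areas(self) -> list:
        """Areas with no neighbours."""
        deg = self.n_neighbors
        return [a for a, d in zip(self.area_ids, deg) if d == 0]

    def edge_list(self) -> list[tuple]:
        """Undirected edges, each pair listed once, in ID terms."""
        coo = sp.triu(self.W, k=1).tocoo()
        return [
            (self.area_ids[i], self.area_ids[j])
            for i, j in zip(coo.row, coo.col)
        ]


@dataclass(frozen=True)
class PrecisionSpec:
    """Which GMRF prior to build, and with which parameters.

    ``family`` selects the prior; only the parameters that family uses
    are meaningful (``rho``/``sigma2`` for Leroux, ``gamma``/``tau``
    for proper CAR, ``tau`` for ICAR and iid).
    """

    family: str
    rho: float = 0.5
    gamma: float = 0.5
    sigma2: float = 1.0
    tau: float = 1.0

    _FAMILIES = ("icar", "proper_car", "leroux", "iid")

    def __post_init__(self):
        if self.family not in self._FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; expected one of {self._FAMILIES}"
            )
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must lie in [0, 1)")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    def matrix(self, lattice: Lattice) -> sp.csr_matrix:
        """The precision matrix of this prior on the given lattice."""
        if self.family == "icar":
            return icar_precision(lattice, self.tau)
        if self.family == "proper_car":
            return proper_car_precision(lattice, self.gamma, self.tau)
        if self.family == "leroux":
            return leroux_precision(lattice, self.rho, self.sigma2)
        return iid_precision(lattice, self.tau)

    @property
    def singular(self) -> bool:
        """Whether the implied precision is rank-deficient."""
        return self.family == "icar" or (
            self.family == "leroux" and self.rho == 1.0
        )


# ---------------------------------------------------------------------------
# graph construction


def build_adjacency(
    polygons: Mapping[object, BaseGeometry],
    contiguity: str = "queen",
) -> Lattice:
    """Contiguity graph from area polygons.

    Two areas are adjacent iff their boundaries intersect.  With
    ``contiguity="queen"`` (default) a single shared point suffices;
    with ``"rook"`` the shared boundary must have positive length.
    Areas without any neighbour are retained and reported through a
    ``UserWarning``.

    Parameters
    ----------
    polygons
        Mapping from area ID to shapely geometry.  Geometries must be
        valid; no snapping is applied (callers pre-clean geometries).
    """
    if len(polygons) == 0:
        raise LatticeError("empty polygon set")
    ids = list(polygons.keys())
    if len(set(ids)) != len(ids):
        raise LatticeError("duplicate area IDs")
    if contiguity not in ("queen", "rook"):
        raise ValueError("contiguity must be 'queen' or 'rook'")
    geoms = [polygons[a] for a in ids]
    for a, g in zip(ids, geoms):
        if g is None or g.is_empty:
            raise LatticeError(f"area {a!r} has empty geometry")
        if not g.is_valid:
            raise LatticeError(f"area {a!r} has invalid (self-intersecting?) geometry")

    n = len(ids)
    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if not geoms[i].intersects(geoms[j]):
                continue
            if contiguity == "rook":
                inter = geoms[i].boundary.intersection(geoms[j].boundary)
                if inter.length <= 0:
                    continue
            rows.extend((i, j))
            cols.extend((j, i))
    W = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n), dtype=float
    )
    lat = Lattice(tuple(ids), W)
    iso = lat.isolated_areas()
    if iso:
        warnings.warn(
            f"{len(iso)} area(s) have no neighbours: {iso}", UserWarning
        )
    return lat


def grid_lattice(rows: int, cols: int, contiguity: str = "rook") -> Lattice:
    """Regular rows x cols lattice, a standard synthetic stand-in for an
    irregular areal map.

    ``contiguity="rook"`` links edge-sharing cells; ``"queen"`` also
    links corner-touching cells.  Cell IDs are ``"r{i}c{j}"``, row-major.
    """
    if rows < 1 or cols < 1:
        raise ValueError("grid dimensions must be positive")
    if contiguity not in ("rook", "queen"):
        raise ValueError("contiguity must be 'rook' or 'queen'")
    ids = [f"r{i}c{j}" for i in range(rows) for j in range(cols)]
    idx = lambda i, j: i * cols + j
    offsets = [(0, 1), (1, 0)]
    if contiguity == "queen":
        offsets += [(1, 1), (1, -1)]
    r_, c_ = [], []
    for i in range(rows):
        for j in range(cols):
            for di, dj in offsets:
                ii, jj = i + di, j + dj
                if 0 <= ii < rows and 0 <= jj < cols:
                    a, b = idx(i, j), idx(ii, jj)
                    r_.extend((a, b))
                    c_.extend((b, a))
    W = sp.csr_matrix(
        (np.ones(len(r_)), (r_, c_)), shape=(len(ids), len(ids)), dtype=float
    )
    return Lattice(tuple(ids), W)


# ---------------------------------------------------------------------------
# precision matrices


def _degree_matrix(lattice: Lattice) -> sp.dia_matrix:
    return sp.diags(lattice.n_neighbors.astype(float))


def icar_precision(lattice: Lattice, tau: float = 1.0) -> sp.csr_matrix:
    """Intrinsic CAR precision ``tau * (D - W)`` (graph Laplacian).

    Singular: row sums are exactly zero, and the null space is the
    constant vector on each connected component.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    Q = tau * (_degree_matrix(lattice) - lattice.W)
    return sp.csr_matrix(Q)


def leroux_precision(
    lattice: Lattice, rho: float, sigma2: float = 1.0
) -> sp.csr_matrix:
    """Leroux precision ``(1/sigma2) * (rho*(D - W) + (1 - rho)*I)``.

    Positive definite for ``rho < 1``; equals the ICAR precision with
    ``tau = 1/sigma2`` at ``rho = 1`` and a scaled identity at
    ``rho = 0``.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    n = lattice.n
    Q = (rho * (_degree_matrix(lattice) - lattice.W) + (1.0 - rho) * sp.eye(n)) / sigma2
    return sp.csr_matrix(Q)


def proper_car_precision(
    lattice: Lattice, gamma: float, tau: float = 1.0
) -> sp.csr_matrix:
    """Proper-CAR precision ``tau * (D - gamma * W)``.

    Positive definite for ``gamma in [0, 1)`` on a connected graph; the
    ``gamma -> 1`` limit is the singular ICAR matrix.
    """
    if not 0.0 <= gamma < 1.0:
        raise ValueError("gamma must lie in [0, 1)")
    if tau <= 0:
        raise ValueError("tau must be positive")
    Q = tau * (_degree_matrix(lattice) - gamma * lattice.W)
    return sp.csr_matrix(Q)


def iid_precision(lattice: Lattice, tau: float = 1.0) -> sp.csr_matrix:
    """Independent-effects precision ``tau * I``."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    return sp.csr_matrix(tau * sp.eye(lattice.n))


# ---------------------------------------------------------------------------
# I/O


def read_geojson_areas(path, id_property: str = "area_id") -> dict:
    """Read a GeoJSON FeatureCollection into {area_id: shapely geometry}.

    The area identifier is taken from ``properties[id_property]``.
    """
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise LatticeError("expected a GeoJSON FeatureCollection")
    out = {}
    for feat in gj.get("features", []):
        props = feat.get("properties") or {}
        if id_property not in props:
            raise LatticeError(
                f"feature missing ID property {id_property!r}"
            )
        aid = props[id_property]
        if aid in out:
            raise LatticeError(f"duplicate area ID {aid!r} in GeoJSON")
        out[aid] = _shapely_shape(feat["geometry"])
    if not out:
        raise LatticeError("GeoJSON contains no features")
    return out


def read_adjacency_csv(path, area_ids: Sequence | None = None) -> Lattice:
    """Read an undirected edge list (columns ``area_i,area_j``).

    ``area_ids`` fixes the area ordering (and admits isolated areas that
    appear in no edge); by default areas are ordered by first appearance.
    """
    edges = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"area_i", "area_j"} <= set(
            reader.fieldnames
        ):
            raise LatticeError("adjacency CSV must have columns area_i,area_j")
        for row in reader:
            edges.append((row["area_i"], row["area_j"]))
    if area_ids is None:
        seen: dict = {}
        for a, b in edges:
            seen.setdefault(a, None)
            seen.setdefault(b, None)
        area_ids = list(seen)
    ids = list(area_ids)
    pos = {a: k for k, a in enumerate(ids)}
    rows, cols = [], []
    for a, b in edges:
        if a not in pos or b not in pos:
            raise LatticeError(f"edge ({a},{b}) references unknown area")
        rows.extend((pos[a], pos[b]))
        cols.extend((pos[b], pos[a]))
    n = len(ids)
    W = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    W.data[:] = 1.0  # collapse duplicate listings
    return Lattice(tuple(ids), W)


def write_adjacency_csv(lattice: Lattice, path) -> None:
    """Write the undirected edge list, each pair once."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["area_i", "area_j"])
        writer.writerows(lattice.edge_list())
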