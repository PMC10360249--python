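"""Areal adjacency structures and spatial autocorrelation statistics.

Areas are always ordered lexicographically by their string identifier;
every vector or matrix in the project uses that 0-based order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.io import mmwrite
from scipy.sparse.csgraph import connected_components
from shapely import STRtree
from shapely.geometry import box, mapping, shape
from shapely.geometry.base import BaseGeometry

SCHEMES = ("queen", "rook", "knn", "distance_band", "queen2")

#: snap tolerance for "touching", as a fraction of the map diagonal
DEFAULT_SNAP_FRACTION = 1e-6


class LatticeError(ValueError):
    """Invalid lattice construction input."""


@dataclass
class AreaLattice:
    """Polygon lattice with a symmetric binary neighbor relation.

    Attributes
    ----------
    area_ids : list of str
        Unique identifiers, sorted lexicographically.
    polygons : list of shapely geometry
        One planar polygon (projected coordinates) per area, aligned
        with ``area_ids``.
    adjacency : scipy.sparse.csr_array
        Symmetric binary relation, zero diagonal.
    scheme_label : str
        One of ``queen, rook, knn, distance_band, queen2``.
    """

    area_ids: list[str]
    polygons: list[BaseGeometry]
    adjacency: sparse.csr_array
    scheme_label: str
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.area_ids) != len(self.polygons):
            raise LatticeError("polygon count does not match id count")
        if len(set(self.area_ids)) != len(self.area_ids):
            raise LatticeError("duplicate area_id")
        if list(self.area_ids) != sorted(self.area_ids):
            raise LatticeError("area_ids must be lexicographically sorted")
        A = self.adjacency
        if A.shape != (self.n, self.n):
            raise LatticeError("adjacency shape mismatch")
        if (A != A.T).nnz != 0:
            raise LatticeError("adjacency not symmetric")
        if A.diagonal().any():
            raise LatticeError("self-neighbors not allowed")
        self._index = {a: i for i, a in enumerate(self.area_ids)}

    @property
    def n(self) -> int:
        return len(self.area_ids)

    def index(self, area_id: str) -> int:
        return self._index[area_id]

    def neighbors(self, i: int) -> np.ndarray:
        """Neighbor indices of area ``i`` (by position)."""
        return self.adjacency.indices[
            self.adjacency.indptr[i] : self.adjacency.indptr[i + 1]
        ]

    def neighbor_sets(self) -> list[set[int]]:
        return [set(self.neighbors(i).tolist()) for i in range(self.n)]

    def islands(self) -> list[int]:
        deg = np.asarray(self.adjacency.sum(axis=1)).ravel()
        return np.flatnonzero(deg == 0).tolist()

    def components(self) -> np.ndarray:
        """Connected-component label per area."""
        _, labels = connected_components(self.adjacency, directed=False)
        return labels

    def edges(self) -> list[tuple[int, int]]:
        """Unique undirected edges as (i, j) with i < j."""
        coo = self.adjacency.tocoo()
        return [(int(i), int(j)) for i, j in zip(coo.row, coo.col) if i < j]

    def laplacian(self) -> sparse.csr_array:
        deg = np.asarray(self.adjacency.sum(axis=1)).ravel().astype(float)
        return (sparse.diags_array(deg) - self.adjacency.astype(float)).tocsr()


@dataclass(frozen=True)
class MoranResult:
    statistic: float
    expected_value: float
    p_value: float
    n_permutations: int


def _validate_polygons(area_ids: list[str], polygons: list[BaseGeometry]) -> None:
    if len(area_ids) < 2:
        raise LatticeError("need at least 2 areas")
    for aid, g in zip(area_ids, polygons):
        if g is None or g.is_empty:
            raise LatticeError(f"empty geometry for area {aid!r}")
        if not g.is_valid:
            raise LatticeError(f"invalid geometry for area {aid!r}")


def _map_snap(polygons: list[BaseGeometry], snap: float | None) -> float:
    if snap is not None:
        return float(snap)
    xs, ys, xe, ye = zip(*(g.bounds for g in polygons))
    diag = float(np.hypot(max(xe) - min(xs), max(ye) - min(ys)))
    return DEFAULT_SNAP_FRACTION * diag


def _contiguity_pairs(polygons, snap, rook):
    """(i, j) pairs of touching polygons; rook demands positive shared length."""
    tree = STRtree(polygons)
    left, right = tree.query(polygons, predicate="dwithin", distance=snap)
    pairs = set()
    for i, j in zip(left.tolist(), right.tolist()):
        if i >= j:
            continue
        if rook:
            inter = polygons[i].boundary.intersection(polygons[j].boundary)
            length = inter.length
            if length <= snap and polygons[i].distance(polygons[j]) <= snap:
                # near-touching with no exact shared segment: snap-buffer probe
                length = polygons[i].boundary.buffer(snap).intersection(
                    polygons[j].boundary
                ).length
            if length > 2 * snap:
                pairs.add((i, j))
        else:
            pairs.add((i, j))
    return pairs


def _pairs_to_csr(pairs, n) -> sparse.csr_array:
    if not pairs:
        return sparse.csr_array((n, n), dtype=np.int8)
    rows, cols = [], []
    for i, j in pairs:
        rows += [i, j]
        cols += [j, i]
    A = sparse.csr_array(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, n)
    )
    A.data[:] = 1
    return A


def build_adjacency(
    area_ids: list[str],
    polygons: list[BaseGeometry],
    scheme: str = "queen",
    *,
    k: int = 6,
    radius: float | None = None,
    snap: float | None = None,
    warn_islands: bool = True,
) -> AreaLattice:
    """Build a symmetric binary adjacency over a polygon lattice.

    Parameters
    ----------
    scheme
        ``queen``  — boundaries within the snap tolerance (point contact
        suffices); ``rook`` — positive-length shared boundary; ``knn`` —
        k nearest centroids, symmetrised by union; ``distance_band`` —
        centroids within ``radius`` (default: smallest radius leaving no
        island); ``queen2`` — queen plus neighbors-of-neighbors.
    """
    if scheme not in SCHEMES:
        raise LatticeError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    order = np.argsort(np.asarray(area_ids, dtype=object))
    area_ids = [area_ids[i] for i in order]
    polygons = [polygons[i] for i in order]
    _validate_polygons(area_ids, polygons)
    n = len(area_ids)
    snap_d = _map_snap(polygons, snap)

    if scheme in ("queen", "rook", "queen2"):
        pairs = _contiguity_pairs(polygons, snap_d, rook=(scheme == "rook"))
        A = _pairs_to_csr(pairs, n)
        if scheme == "queen2":
            A2 = ((A @ A + A) > 0).astype(np.int8).tolil()
            A2.setdiag(0)
            A = sparse.csr_array(A2)
    elif scheme == "knn":
        if not 1 <= k < n:
            raise LatticeError(f"knn requires 1 <= k < n, got k={k}")
        cent = np.array([[g.centroid.x, g.centroid.y] for g in polygons])
        d = np.linalg.norm(cent[:, None, :] - cent[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        nearest = np.argsort(d, axis=1)[:, :k]
        pairs = set()
        for i in range(n):
            for j in nearest[i]:
                pairs.add((min(i, int(j)), max(i, int(j))))
        A = _pairs_to_csr(pairs, n)
    else:  # distance_band
        cent = np.array([[g.centroid.x, g.centroid.y] for g in polygons])
        d = np.linalg.norm(cent[:, None, :] - cent[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if radius is None:
            radius = float(d.min(axis=1).max()) * (1 + 1e-9)
        rows, cols = np.nonzero(d <= radius)
        pairs = {(int(i), int(j)) for i, j in zip(rows, cols) if i < j}
        A = _pairs_to_csr(pairs, n)

    lattice = AreaLattice(area_ids, polygons, A, scheme)
    isl = lattice.islands()
    if isl and warn_islands:
        warnings.warn(
            f"{len(isl)} island area(s) with no neighbors: "
            f"{[area_ids[i] for i in isl[:5]]}",
            stacklevel=2,
        )
    return lattice


def neighbor_counts(lattice: AreaLattice) -> np.ndarray:
    """Number of neighbors per area (row sums of the adjacency)."""
    return np.asarray(lattice.adjacency.sum(axis=1)).ravel().astype(int)


def morans_i(
    values,
    lattice: AreaLattice,
    n_permutations: int = 999,
    seed: int | None = None,
) -> MoranResult:
    """Global Moran's I with binary weights and a permutation test.

    I = (n/S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2,
    with S0 the total weight. The p-value is two-sided around the
    analytical null expectation -1/(n-1), with the +1 correction
    (count_extreme + 1) / (n_permutations + 1).
    """
    x = np.asarray(values, dtype=float)
    n = lattice.n
    if x.shape != (n,):
        raise ValueError(f"values must have length {n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if np.ptp(x) == 0:
        raise ValueError("zero variance: values are constant")
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")

    W = lattice.adjacency.astype(float)
    s0 = W.sum()
    if s0 == 0:
        raise ValueError("no edges in lattice: Moran's I undefined")

    def stat(z):
        zc = z - z.mean()
        return (n / s0) * float(zc @ (W @ zc)) / float(zc @ zc)

    i_obs = stat(x)
    expected = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    extreme = 0
    ref = abs(i_obs - expected)
    for _ in range(n_permutations):
        if abs(stat(rng.permutation(x)) - expected) >= ref - 1e-12:
            extreme += 1
    p = (extreme + 1) / (n_permutations + 1)
    return MoranResult(i_obs, expected, p, n_permutations)


# ---------------------------------------------------------------------------
# convenience constructors and I/O

def square_grid_lattice(nx: int, ny: int, scheme: str = "queen") -> AreaLattice:
    """Regular nx-by-ny unit-square lattice (ids ``r{row}c{col}``, zero padded)."""
    wr, wc = len(str(ny - 1)), len(str(nx - 1))
    ids, polys = [], []
    for r in range(ny):
        for c in range(nx):
            ids.append(f"r{r:0{wr}d}c{c:0{wc}d}")
            polys.append(box(c, r, c + 1, r + 1))
    return build_adjacency(ids, polys, scheme)


def read_areas_geojson(path) -> tuple[list[str], list[BaseGeometry], dict]:
    """Read a FeatureCollection; returns (ids, polygons, properties-by-id),
    sorted by area_id. Each feature must carry an ``area_id`` property."""
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj["features"]
    recs = []
    for f in feats:
        props = f.get("properties") or {}
        if "area_id" not in props:
            raise LatticeError("feature missing 'area_id' property")
        recs.append((str(props["area_id"]), shape(f["geometry"]), props))
    recs.sort(key=lambda r: r[0])
    ids = [r[0] for r in recs]
    if len(set(ids)) != len(ids):
        raise LatticeError("duplicate area_id in GeoJSON")
    return ids, [r[1] for r in recs], {r[0]: r[2] for r in recs}


def write_areas_geojson(path, area_ids, polygons, properties: dict | None = None):
    """Write polygons as a GeoJSON FeatureCollection (deterministic layout)."""
    feats = []
    for aid, geom in zip(area_ids, polygons):
        props = dict(properties.get(aid, {})) if properties else {}
        props["area_id"] = aid
        feats.append(
            {"type": "Feature", "properties": props, "geometry": mapping(geom)}
        )
    with open(path, "w") as fh:
        json.dump(
            {"type": "FeatureCollection", "features": feats},
            fh,
            sort_keys=True,
            separators=(",", ":"),
        )
        fh.write("\n")


def write_edge_csv(lattice: AreaLattice, path) -> None:
    """Adjacency as an edge list CSV with columns area_id_1, area_id_2."""
    with open(path, "w") as fh:
        fh.write("area_id_1,area_id_2\n")
        for i, j in lattice.edges():
            fh.write(f"{lattice.area_ids[i]},{lattice.area_ids[j]}\n")


def read_edge_csv(path, area_ids: list[str], scheme_label="queen",
                  polygons=None) -> AreaLattice:
    """Rebuild a lattice from an edge-list CSV (polygons optional points)."""
    from shapely.geometry import Point

    area_ids = sorted(area_ids)
    idx = {a: i for i, a in enumerate(area_ids)}
    pairs = set()
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != "area_id_1,area_id_2":
            raise LatticeError("bad edge CSV header")
        for line in fh:
            a, b = line.strip().split(",")
            i, j = idx[a], idx[b]
            pairs.add((min(i, j), max(i, j)))
    if polygons is None:
        polygons = [Point(i, 0).buffer(0.3) for i in range(len(area_ids))]
    A = _pairs_to_csr(pairs, len(area_ids))
    return AreaLattice(area_ids, polygons, A, scheme_label)


def write_matrix_market(lattice: AreaLattice, path) -> None:
    mmwrite(str(path), sparse.coo_matrix(lattice.adjacency))
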