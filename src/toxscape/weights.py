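"""Spatial weights matrices: distance band, queen contiguity, row standardization.

A :class:`SpatialWeights` object pairs an ordered list of region ids with a
sparse weight matrix ``W`` whose entry ``w[j, k]`` links region *j* to its
neighbor *k*.  Binary weights (1 for neighbors, 0 otherwise) are the
construction form; row standardization (each nonempty row rescaled to sum
to 1) is applied before maximum-likelihood spatial regression so that the
autocorrelation coefficient is bounded in (-1, 1).

Serialization uses the plain-text GAL adjacency-list format.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Sequence

import numpy as np
import scipy.sparse as sp

from .containers import Region
from .geometry import pairwise_distances, region_coords

__all__ = [
    "SpatialWeights",
    "distance_band_weights",
    "queen_lattice_weights",
    "queen_polygon_weights",
    "read_gal",
]


class IsolationWarning(UserWarning):
    """Emitted when a weights matrix contains regions with no neighbors."""


class SpatialWeights:
    """Sparse neighbor structure over an ordered set of region ids.

    Parameters
    ----------
    ids : sequence
        Region identifiers, in the row/column order of ``matrix``.
    matrix : scipy.sparse matrix, shape (n, n)
        Nonnegative weights with a zero diagonal.  Before standardization the
        neighbor structure must be symmetric (j in N_k iff k in N_j).
    row_standardized : bool
        Whether rows have been rescaled to sum to one.
    """

    def __init__(self, ids: Sequence, matrix: sp.spmatrix, row_standardized: bool = False):
        ids = list(ids)
        matrix = sp.csr_matrix(matrix, dtype=float)
        n = len(ids)
        if matrix.shape != (n, n):
            raise ValueError(f"matrix shape {matrix.shape} does not match {n} ids")
        if matrix.diagonal().any():
            raise ValueError("self-neighbors are not allowed (nonzero diagonal)")
        if (matrix.data < 0).any():
            raise ValueError("weights must be nonnegative")
        if not row_standardized:
            pat = (matrix != 0)
            if (pat != pat.T).nnz:
                raise ValueError("neighbor structure must be symmetric")
        self.ids = ids
        self.matrix = matrix
        self.row_standardized = bool(row_standardized)
        self._index = {rid: i for i, rid in enumerate(ids)}
        if len(self._index) != n:
            raise ValueError("duplicate ids in weights object")
        self._eigs: np.ndarray | None = None
        iso = self.isolated_ids()
        if iso:
            warnings.warn(
                f"{len(iso)} region(s) have no neighbors: {iso[:5]}{'...' if len(iso) > 5 else ''}",
                IsolationWarning,
                stacklevel=2,
            )

    # -- structure -----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.ids)

    def cardinalities(self) -> np.ndarray:
        """Number of neighbors per region, in id order."""
        return np.diff(self.matrix.indptr)

    def isolated_ids(self) -> List:
        card = self.cardinalities()
        return [rid for rid, c in zip(self.ids, card) if c == 0]

    def neighbors(self, rid) -> Dict:
        """Mapping neighbor id -> weight for one region."""
        j = self._index[rid]
        row = self.matrix.getrow(j)
        return {self.ids[k]: w for k, w in zip(row.indices, row.data)}

    # -- transforms ----------------------------------------------------
    def row_standardize(self) -> "SpatialWeights":
        """Return a copy with each nonempty row rescaled to sum to 1.

        Idempotent; empty rows are left unchanged.
        """
        sums = np.asarray(self.matrix.sum(axis=1)).ravel()
        scale = np.divide(1.0, sums, out=np.zeros_like(sums), where=sums > 0)
        w = sp.diags(scale) @ self.matrix
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", IsolationWarning)
            out = SpatialWeights(self.ids, w, row_standardized=True)
        return out

    def to_dense(self) -> np.ndarray:
        return self.matrix.toarray()

    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues of the (dense) weight matrix, computed once and cached.

        Used for the log-determinant term log|I - rho*W| = sum log(1 - rho*w_i)
        in spatial ML estimation.  Row-standardized weights derived from a
        symmetric binary structure have real spectrum; any numerically complex
        parts are handled by summing complex logs and taking the real part.
        """
        if self._eigs is None:
            self._eigs = np.linalg.eigvals(self.to_dense())
        return self._eigs

    def log_det(self, coef: float) -> float:
        """log |I - coef * W| via the cached spectrum."""
        vals = 1.0 - coef * self.eigenvalues()
        return float(np.log(vals.astype(complex)).sum().real)

    def coef_bounds(self) -> tuple:
        """Open interval of admissible autocorrelation coefficients (1/w_min, 1/w_max)."""
        eig = np.real(self.eigenvalues())
        lo = 1.0 / eig.min() if eig.min() < 0 else -np.inf
        hi = 1.0 / eig.max() if eig.max() > 0 else np.inf
        return (float(lo), float(hi))

    # -- io --------------------------------------------------------------
    def to_gal(self, path) -> None:
        """Write the neighbor structure in GAL format (binary adjacency)."""
        lines = [str(self.n)]
        for rid in self.ids:
            nbrs = list(self.neighbors(rid))
            lines.append(f"{rid} {len(nbrs)}")
            lines.append(" ".join(str(k) for k in nbrs))
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"SpatialWeights(n={self.n}, links={self.matrix.nnz}, "
            f"row_standardized={self.row_standardized})"
        )


def read_gal(path) -> SpatialWeights:
    """Read a binary-weight GAL adjacency file."""
    with open(path, "r", encoding="utf-8") as fh:
        tokens_by_line = [ln.split() for ln in fh if ln.strip()]
    n = int(tokens_by_line[0][0])
    ids: List[str] = []
    nbr_lists: List[List[str]] = []
    i = 1
    for _ in range(n):
        rid, count = tokens_by_line[i][0], int(tokens_by_line[i][1])
        if count > 0:
            nbrs = tokens_by_line[i + 1]
            if len(nbrs) != count:
                raise ValueError(f"GAL entry for {rid}: expected {count} neighbors")
            i += 2
        else:
            nbrs = []
            i += 1
        ids.append(rid)
        nbr_lists.append(nbrs)
    index = {rid: j for j, rid in enumerate(ids)}
    mat = sp.lil_matrix((n, n))
    for j, nbrs in enumerate(nbr_lists):
        for k in nbrs:
            mat[j, index[k]] = 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", IsolationWarning)
        return SpatialWeights(ids, mat)


def distance_band_weights(
    regions: Sequence[Region], threshold: float, coords: str = "planar"
) -> SpatialWeights:
    """Binary weights linking regions whose centroids lie within ``threshold``.

    The boundary is included: a pair at distance exactly equal to the
    threshold counts as neighbors ("within a threshold distance").
    """
    if not (threshold > 0):
        raise ValueError(f"threshold must be > 0, got {threshold}")
    pts = region_coords(regions)
    d = pairwise_distances(pts, pts, coords)
    np.fill_diagonal(d, np.inf)
    adj = (d <= threshold).astype(float)
    return SpatialWeights([r.id for r in regions], sp.csr_matrix(adj))


def queen_lattice_weights(side: int, ids: Sequence | None = None) -> SpatialWeights:
    """Queen contiguity on a ``side`` x ``side`` square lattice.

    Cells are ordered row-major (cell (ix, iy) at index iy*side + ix); two
    cells are neighbors if they share an edge or a corner.
    """
    if side < 1:
        raise ValueError("side must be >= 1")
    n = side * side
    if ids is None:
        ids = list(range(n))
    elif len(ids) != n:
        raise ValueError(f"expected {n} ids for a {side}x{side} lattice")
    rows, cols = [], []
    for iy in range(side):
        for ix in range(side):
            j = iy * side + ix
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dx == dy == 0:
                        continue
                    nx, ny = ix + dx, iy + dy
                    if 0 <= nx < side and 0 <= ny < side:
                        rows.append(j)
                        cols.append(ny * side + nx)
    mat = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    return SpatialWeights(ids, mat)


def queen_polygon_weights(polygons: dict) -> SpatialWeights:
    """Queen contiguity from a mapping of region id -> shapely polygon.

    Two regions are neighbors if their polygons share any boundary point
    (edge or corner).  Raises a ValueError naming the offending region for
    invalid geometries.
    """
    from shapely import STRtree

    ids = list(polygons)
    geoms = []
    for rid in ids:
        g = polygons[rid]
        if g is None or g.is_empty or not g.is_valid:
            raise ValueError(f"invalid geometry for region {rid!r}")
        geoms.append(g)
    tree = STRtree(geoms)
    n = len(ids)
    mat = sp.lil_matrix((n, n))
    for j, g in enumerate(geoms):
        for k in tree.query(g, predicate="intersects"):
            k = int(k)
            if k != j:
                mat[j, k] = 1.0
                mat[k, j] = 1.0
    return SpatialWeights(ids, mat)
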