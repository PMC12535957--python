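"""Persistent homology of weighted-graph flag filtrations, from scratch.

The input is a dissimilarity ("inverted") network with entries in [0, 1]:
small values mean tight connections.  Sweeping a threshold t from 0 to 1
yields a nested family of flag (clique) complexes — a k-simplex enters at
the maximum of its edge values.  Because absent or zero raw edges invert
to exactly 1, the complex at t = 1 is always the full simplex on the
vertex set; the filtration is read off a dense matrix.

Homology is computed over GF(2) up to dimension 2 (components, loops,
voids).  The reduction operates on the anti-transposed (coboundary)
matrix, processing dimensions in increasing order with clearing: death
simplices found while reducing dimension d-1 are skipped as columns in
dimension d.  For flag filtrations this makes nearly every processed
column terminate at a fresh pivot, which is what keeps a dense 76-node
subject with dimensions {0, 1, 2} tractable.  The pairing produced by
coboundary reduction is canonically the same as that of standard
boundary-matrix reduction, so the diagrams are identical.

Conventions (declared, and matched by the brute-force oracle):

* intervals are half-open [b, d); zero-persistence pairs are dropped;
* infinite dimension-0 bars are kept and counted for every t >= birth,
  so the Betti-0 curve ends at the number of components of the final
  complex (1 for dense matrices);
* ties in filtration value are broken by (dimension, lexicographic
  vertex tuple); diagrams do not depend on this choice.

:func:`betti_bruteforce_oracle` is an independent verifier: it rebuilds
the complex at a single threshold and computes Betti numbers directly
from GF(2) ranks of the boundary operators by Gaussian elimination.  It
shares no code path with the reduction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .netio import ValidationError, WeightedNetwork

logger = logging.getLogger(__name__)

DEFAULT_GRID_SIZE = 100


# ---------------------------------------------------------------------------
# combinatorics helpers
# ---------------------------------------------------------------------------

def _binom_table(n: int, kmax: int) -> np.ndarray:
    """C(i, k) for 0 <= i <= n, 0 <= k <= kmax, as int64."""
    tbl = np.zeros((n + 1, kmax + 1), dtype=np.int64)
    tbl[:, 0] = 1
    for i in range(1, n + 1):
        for k in range(1, kmax + 1):
            tbl[i, k] = tbl[i - 1, k] + tbl[i - 1, k - 1]
    return tbl


def _enumerate_simplices(n: int, k: int) -> np.ndarray:
    """All size-(k+1) vertex subsets of range(n), ascending within rows."""
    count = int(_binom_table(n, k + 1)[n, k + 1])
    dt = np.dtype((np.int32, (k + 1,)))
    out = np.fromiter(itertools.combinations(range(n), k + 1), dtype=dt, count=count)
    return out.reshape(count, k + 1)


def _simplex_values(verts: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Filtration value of each simplex: max over its edges' dissimilarities."""
    m, k1 = verts.shape
    if k1 == 1:
        return np.zeros(m)
    vals = np.full(m, -np.inf)
    for i in range(k1):
        for j in range(i + 1, k1):
            np.maximum(vals, w[verts[:, i], verts[:, j]], out=vals)
    return vals


def _colex_rank(verts: np.ndarray, binom: np.ndarray) -> np.ndarray:
    """Colexicographic rank of each ascending vertex tuple."""
    m, k1 = verts.shape
    rank = np.zeros(m, dtype=np.int64)
    for j in range(k1):
        rank += binom[verts[:, j], j + 1]
    return rank


# ---------------------------------------------------------------------------
# filtration
# ---------------------------------------------------------------------------

@dataclass
class FlagFiltration:
    """Flag filtration of a dissimilarity matrix, truncated at dimension
    ``max_hom_dim + 1`` (the highest dimension whose simplices can kill
    requested homology classes).

    Per dimension d, ``verts_by_dim[d]`` is an (n_d, d+1) array of
    ascending vertex tuples and ``values_by_dim[d]`` the matching
    filtration values, rows sorted by (value, lexicographic tuple).
    """

    n_vertices: int
    max_hom_dim: int
    verts_by_dim: dict[int, np.ndarray] = field(repr=False)
    values_by_dim: dict[int, np.ndarray] = field(repr=False)

    @property
    def dims(self) -> list[int]:
        return sorted(self.verts_by_dim)

    def n_simplices(self, d: int) -> int:
        return len(self.values_by_dim[d]) if d in self.values_by_dim else 0

    def simplices(self, d: int | None = None):
        """Yield (vertex tuple, value) pairs in filtration order."""
        dims = self.dims if d is None else [d]
        for dd in dims:
            for row, val in zip(self.verts_by_dim[dd], self.values_by_dim[dd]):
                yield tuple(int(v) for v in row), float(val)

    def simplex_counts_at(self, t: float) -> dict[int, int]:
        """n_d(t): simplices of each dimension with value <= t."""
        return {
            d: int(np.searchsorted(self.values_by_dim[d], t, side="right"))
            for d in self.dims
        }

    def validate_monotone(self) -> None:
        """Every face must enter no later than its cofaces."""
        binom = _binom_table(self.n_vertices, self.max_hom_dim + 2)
        for d in self.dims:
            if d == 0:
                if np.any(self.values_by_dim[0] != 0):
                    raise ValidationError("vertex simplices must have value 0")
                continue
            verts, vals = self.verts_by_dim[d], self.values_by_dim[d]
            face_rank = _colex_rank(self.verts_by_dim[d - 1], binom)
            face_val = np.full(int(binom[self.n_vertices, d]), np.nan)
            face_val[face_rank] = self.values_by_dim[d - 1]
            for drop in range(d + 1):
                keep = [j for j in range(d + 1) if j != drop]
                fv = face_val[_colex_rank(verts[:, keep], binom)]
                if np.any(np.isnan(fv)) or np.any(fv > vals + 1e-12):
                    raise ValidationError(
                        f"non-monotone filtration at dimension {d}"
                    )


def build_flag_filtration(network: WeightedNetwork, max_hom_dim: int) -> FlagFiltration:
    """Enumerate the flag filtration of an inverted-space network.

    Vertices enter at 0, edge (i, j) at its dissimilarity, and every
    higher clique at the max of its edges.  Simplices are enumerated up
    to dimension ``max_hom_dim + 1``; the diagonal is ignored.
    """
    if network.space != "inverted":
        raise ValidationError(
            "flag filtration requires an inverted-space (dissimilarity) network"
        )
    if not 0 <= max_hom_dim <= 2:
        raise ValidationError("max_hom_dim must be 0, 1, or 2")
    n = network.n
    w = network.weights
    verts_by_dim: dict[int, np.ndarray] = {}
    values_by_dim: dict[int, np.ndarray] = {}
    for d in range(max_hom_dim + 2):
        if d + 1 > n:
            break
        verts = _enumerate_simplices(n, d)
        vals = _simplex_values(verts, w)
        keys = tuple(verts[:, j] for j in range(d, -1, -1)) + (vals,)
        order = np.lexsort(keys)
        verts_by_dim[d] = verts[order]
        values_by_dim[d] = vals[order]
    return FlagFiltration(n, max_hom_dim, verts_by_dim, values_by_dim)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

@dataclass
class PersistenceDiagram:
    """Multiset of (dimension, birth, death) intervals, death in (birth, inf]."""

    intervals: list[tuple[int, float, float]]

    def __post_init__(self) -> None:
        for d, b, dd in self.intervals:
            if not dd > b:
                raise ValidationError(f"interval ({b}, {dd}) in dim {d} not increasing")

    def in_dim(self, d: int) -> np.ndarray:
        arr = [(b, dd) for (k, b, dd) in self.intervals if k == d]
        return np.array(arr, dtype=float).reshape(len(arr), 2)

    @property
    def dims(self) -> list[int]:
        return sorted({d for d, _, _ in self.intervals})


def _dim0_pairs(filtration: FlagFiltration):
    """Elder-rule union-find over edges in filtration order.

    Returns (pairs, essential_vertices, death_edge_positions).  Each pair
    is (birth_vertex, edge_position); the component whose oldest vertex
    is younger (larger index) dies at the merging edge.
    """
    n = filtration.n_vertices
    parent = np.arange(n)
    oldest = np.arange(n)  # birth representative of each component root

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    pairs = []
    death_edges = []
    edges = filtration.verts_by_dim.get(1)
    if edges is not None:
        for pos, (u, v) in enumerate(edges):
            ru, rv = find(int(u)), find(int(v))
            if ru == rv:
                continue
            if oldest[ru] <= oldest[rv]:
                keep, die = ru, rv
            else:
                keep, die = rv, ru
            pairs.append((int(oldest[die]), pos))
            parent[die] = keep
            death_edges.append(pos)
    roots = {find(i) for i in range(n)}
    essential = sorted(oldest[r] for r in roots)
    return pairs, essential, death_edges


def _reduce_codimension(
    filtration: FlagFiltration,
    d: int,
    cleared: np.ndarray,
    binom: np.ndarray,
    rank2pos_next: np.ndarray,
):
    """Coboundary column reduction for homology dimension ``d``.

    Columns are d-simplices in decreasing filtration order (cleared ones
    skipped); the rows of a column are its (d+1)-cofacets, indexed in
    reversed filtration order so that the pivot (max row) is the earliest
    cofacet.  Returns (pairs, essentials, death_positions_next_dim) where
    each pair is (column position in dim d, row position in dim d+1),
    positions in ascending filtration order.
    """
    verts = filtration.verts_by_dim[d]
    n_cols = len(verts)
    n_rows = filtration.n_simplices(d + 1)
    n_v = filtration.n_vertices

    # rank -> reversed row position of each (d+1)-simplex
    revpos = np.full(len(rank2pos_next), -1, dtype=np.int64)
    valid = rank2pos_next >= 0
    revpos[valid] = n_rows - 1 - rank2pos_next[valid]

    # per-column pieces of the colex-rank insertion formula
    colex = _colex_rank(verts, binom)
    # suffix[c, p] = sum_{j >= p} (C(v_j, j+2) - C(v_j, j+1))
    diff = binom[verts, np.arange(2, d + 3)] - binom[verts, np.arange(1, d + 2)]
    suffix = np.zeros((n_cols, d + 2), dtype=np.int64)
    suffix[:, :-1] = diff[:, ::-1].cumsum(axis=1)[:, ::-1]

    all_v = np.arange(n_v)
    pivot_owner: dict[int, int] = {}
    stored: dict[int, frozenset] = {}
    pairs: list[tuple[int, int]] = []
    essentials: list[int] = []

    for col in range(n_cols - 1, -1, -1):
        if cleared[col]:
            continue
        vs = verts[col]
        mask = np.ones(n_v, dtype=bool)
        mask[vs] = False
        others = all_v[mask]
        p = np.searchsorted(vs, others)
        ranks = colex[col] + suffix[col, p] + binom[others, p + 1]
        rows = revpos[ranks]
        s = set(rows[rows >= 0].tolist())
        while s:
            piv = max(s)
            owner = pivot_owner.get(piv)
            if owner is None:
                pivot_owner[piv] = col
                stored[col] = frozenset(s)
                pairs.append((col, n_rows - 1 - piv))
                break
            s ^= stored[owner]
        else:
            essentials.append(col)
    deaths = [row for _, row in pairs]
    return pairs, essentials, deaths


def compute_persistence(filtration: FlagFiltration) -> PersistenceDiagram:
    """Persistence pairs of a monotone flag filtration over GF(2).

    Dimension-0 pairs come from elder-rule union-find; higher dimensions
    from coboundary reduction with clearing.  Unpaired simplices of
    dimension <= max_hom_dim yield infinite intervals; zero-length
    intervals are discarded (but still participate in clearing).
    """
    filtration.validate_monotone()
    K = filtration.max_hom_dim
    vals = filtration.values_by_dim
    intervals: list[tuple[int, float, float]] = []

    pairs0, essential0, death_edges = _dim0_pairs(filtration)
    for vtx, epos in pairs0:
        b, dd = 0.0, float(vals[1][epos])
        if dd > b:
            intervals.append((0, b, dd))
    for _ in essential0:
        intervals.append((0, 0.0, np.inf))

    binom = _binom_table(filtration.n_vertices, K + 2)
    cleared_positions = death_edges
    for d in range(1, K + 1):
        if filtration.n_simplices(d) == 0:
            break
        cleared = np.zeros(filtration.n_simplices(d), dtype=bool)
        cleared[cleared_positions] = True
        if filtration.n_simplices(d + 1) == 0:
            # no cofacets: every non-cleared d-simplex is essential
            for col in np.flatnonzero(~cleared):
                intervals.append((d, float(vals[d][col]), np.inf))
            break
        nxt = filtration.verts_by_dim[d + 1]
        rank2pos = np.full(int(binom[filtration.n_vertices, d + 2]), -1, dtype=np.int64)
        rank2pos[_colex_rank(nxt, binom)] = np.arange(len(nxt))
        pairs, essentials, deaths = _reduce_codimension(
            filtration, d, cleared, binom, rank2pos
        )
        for col, row in pairs:
            b, dd = float(vals[d][col]), float(vals[d + 1][row])
            if dd > b:
                intervals.append((d, b, dd))
        for col in essentials:
            intervals.append((d, float(vals[d][col]), np.inf))
        cleared_positions = deaths

    intervals.sort()
    return PersistenceDiagram(intervals)


# ---------------------------------------------------------------------------
# Betti curves
# ---------------------------------------------------------------------------

@dataclass
class BettiCurve:
    """Betti numbers sampled on an equally spaced threshold grid in [0, 1]."""

    grid: np.ndarray
    counts: dict[int, np.ndarray]

    def vector(self, dims: tuple[int, ...]) -> np.ndarray:
        """Concatenate per-dimension curves into one feature vector."""
        return np.concatenate([self.counts[d] for d in dims])


def betti_curve(
    diagram: PersistenceDiagram,
    grid_size: int = DEFAULT_GRID_SIZE,
    dims: tuple[int, ...] = (0, 1, 2),
) -> BettiCurve:
    """beta_k(t) = #{intervals with birth <= t < death} on a uniform grid.

    Infinite deaths count for every t >= birth.  The half-open convention
    makes the curve well defined at grid points coinciding with interval
    endpoints.
    """
    if grid_size < 2:
        raise ValidationError("grid_size must be at least 2")
    grid = np.linspace(0.0, 1.0, grid_size)
    counts = {}
    for d in dims:
        iv = diagram.in_dim(d)
        if len(iv) == 0:
            counts[d] = np.zeros(grid_size, dtype=np.int64)
            continue
        born = iv[:, 0][None, :] <= grid[:, None]
        alive = grid[:, None] < iv[:, 1][None, :]
        counts[d] = (born & alive).sum(axis=1).astype(np.int64)
    return BettiCurve(grid, counts)


def betti_curves_for_network(
    network: WeightedNetwork,
    dims: tuple[int, ...] = (0, 1, 2),
    grid_size: int = DEFAULT_GRID_SIZE,
) -> BettiCurve:
    """Convenience: filtration -> persistence -> Betti curve in one call."""
    filtration = build_flag_filtration(network, max_hom_dim=max(dims))
    return betti_curve(compute_persistence(filtration), grid_size, dims)


# ---------------------------------------------------------------------------
# independent GF(2) rank oracle
# ---------------------------------------------------------------------------

def gf2_rank(mat: np.ndarray) -> int:
    """Rank of a 0/1 matrix over the two-element field (Gaussian elimination)."""
    a = (np.asarray(mat, dtype=np.uint8) % 2).copy()
    rank = 0
    n_rows, n_cols = a.shape
    for col in range(n_cols):
        piv = None
        for r in range(rank, n_rows):
            if a[r, col]:
                piv = r
                break
        if piv is None:
            continue
        a[[rank, piv]] = a[[piv, rank]]
        hits = np.flatnonzero(a[:, col])
        hits = hits[hits != rank]
        a[hits] ^= a[rank]
        rank += 1
        if rank == n_rows:
            break
    return rank


def betti_bruteforce_oracle(network: WeightedNetwork, t: float, k: int) -> int:
    """beta_k of the flag complex at threshold t, via boundary-operator ranks.

    Builds every simplex with value <= t up to dimension k + 1 and returns
    n_k - rank(d_k) - rank(d_{k+1}), ranks over GF(2).  Deliberately naive;
    guarded to small networks (N <= 12 for k = 2, N <= 20 for k <= 1).
    """
    if network.space != "inverted":
        raise ValidationError("oracle expects an inverted-space network")
    n = network.n
    limit = 12 if k == 2 else 20
    if n > limit:
        raise ValidationError(f"oracle size guard: N = {n} > {limit} for k = {k}")
    w = network.weights
    simplices: dict[int, list[tuple[int, ...]]] = {0: [(v,) for v in range(n)]}
    for d in range(1, k + 2):
        simplices[d] = [
            c
            for c in itertools.combinations(range(n), d + 1)
            if max(w[a, b] for a, b in itertools.combinations(c, 2)) <= t
        ]
    n_k = len(simplices[k])

    def boundary_rank(d: int) -> int:
        if d == 0 or not simplices.get(d):
            return 0
        rows = {s: i for i, s in enumerate(simplices[d - 1])}
        mat = np.zeros((len(rows), len(simplices[d])), dtype=np.uint8)
        for j, s in enumerate(simplices[d]):
            for drop in range(d + 1):
                face = s[:drop] + s[drop + 1 :]
                mat[rows[face], j] = 1
        return gf2_rank(mat)

    return n_k - boundary_rank(k) - boundary_rank(k + 1)
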