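"""Basins of attraction of a sampled energy landscape.

The decoy ensemble Ω together with its energies f defines a discrete sample
of the protein's energy landscape.  Embedding Ω in an ε-nearest-neighbor
graph G = (V, E) — an edge (u, v) whenever d(u, v) ≤ ε — recovers enough of
the landscape's neighborhood structure to extract its local organisation:

* a vertex u is a *local minimum* if f(u) ≤ f(v) for every neighbor v;
* every other vertex follows a discrete negative gradient, repeatedly
  taking the incident edge that maximises the descent ratio
  (f(u) − f(v)) / d(u, v), until a local minimum is reached;
* vertices reaching the same minimum form that minimum's *basin*.

Each basin carries a focal energy (energy of its deepest point), a
pseudo-saddle (the lowest member with a strictly lower neighbor draining to
a different basin), a persistence f(saddle) − f(focal), and a stability —
the perpendicular distance of (focal energy, saddle energy) from the
identity line, i.e. persistence / √2.  Shallow basins below a persistence
threshold can be merged into the basin across their saddle, the standard
topological-persistence simplification of a noisy landscape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .decoy_io import DecoySet

__all__ = [
    "NNGraph",
    "Basin",
    "build_nngraph",
    "nngraph_from_distance_matrix",
    "connect_epsilon",
    "find_local_minima",
    "assign_basins",
    "compute_saddles",
    "compute_stability",
    "merge_by_persistence",
    "extract_basins",
    "prefilter_high_energy",
]


@dataclass
class NNGraph:
    """Undirected ε-neighborhood graph over decoy indices."""

    epsilon: float
    n_vertices: int
    neighbors: list[np.ndarray]  # per-vertex neighbor indices, sorted
    distances: list[np.ndarray]  # matching edge lengths, all ≤ ε
    n_components: int

    @property
    def n_edges(self) -> int:
        return sum(len(nb) for nb in self.neighbors) // 2

    def edge_list(self) -> list[tuple[int, int, float]]:
        out = []
        for u in range(self.n_vertices):
            for v, d in zip(self.neighbors[u], self.distances[u]):
                if u < v:
                    out.append((u, int(v), float(d)))
        return out


def _finish_graph(epsilon: float, n: int, pairs: np.ndarray,
                  dvals: np.ndarray) -> NNGraph:
    """Assemble per-vertex adjacency from unique (u < v) edge pairs."""
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    dvals = np.asarray(dvals, dtype=float)
    rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
    cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
    dd = np.concatenate([dvals, dvals])
    order = np.lexsort((cols, rows))
    rows, cols, dd = rows[order], cols[order], dd[order]
    splits = np.searchsorted(rows, np.arange(1, n))
    neighbors = np.split(cols, splits)
    distances = np.split(dd, splits)
    adj = csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    n_comp, _ = connected_components(adj, directed=False)
    return NNGraph(epsilon, n, neighbors, distances, int(n_comp))


def build_nngraph(ds: DecoySet, epsilon: float) -> NNGraph:
    """ε-neighborhood graph over a decoy set: edges exactly where d(u,v) ≤ ε.

    The component count is reported on the graph; a disconnected graph is
    *not* silently repaired (increase ε, e.g. via :func:`connect_epsilon`,
    if a single component is required).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    pts = ds.point_matrix()
    if pts is not None:
        tree = cKDTree(pts)
        pairs = tree.query_pairs(epsilon, output_type="ndarray")
        dvals = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1) \
            if len(pairs) else np.array([])
        return _finish_graph(epsilon, len(ds), pairs, dvals)
    return nngraph_from_distance_matrix(ds.distance_matrix(), epsilon)


def nngraph_from_distance_matrix(dist: np.ndarray, epsilon: float) -> NNGraph:
    """ε-graph from a full symmetric distance matrix (exact-lRMSD backend, tests)."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    mask = dist[iu, ju] <= epsilon
    pairs = np.stack([iu[mask], ju[mask]], axis=1)
    return _finish_graph(epsilon, n, pairs, dist[iu[mask], ju[mask]])


def connect_epsilon(
    ds: DecoySet,
    epsilon0: float = 1.0,
    step: float = 0.5,
    cap: float = 50.0,
    margin_steps: int = 0,
) -> tuple[NNGraph, float]:
    """Increase ε from ε₀ in ``step`` increments until the graph is connected.

    Implements the standard remedy for a disconnected ε-graph under
    non-uniform sampling.  ``margin_steps`` extra increments past the
    connectivity threshold enlarge sparse boundary neighborhoods — at bare
    connectivity, fringe vertices see only one or two neighbors, too few to
    estimate a descent direction, and their noise dimples masquerade as
    basins.  Returns the graph and its ε.
    """
    eps = epsilon0
    while eps <= cap + 1e-12:
        g = build_nngraph(ds, eps)
        if g.n_components == 1:
            if margin_steps:
                eps += margin_steps * step
                g = build_nngraph(ds, eps)
            return g, eps
        eps += step
    raise ValueError(f"graph still disconnected at epsilon cap {cap}")


def find_local_minima(g: NNGraph, f: np.ndarray) -> np.ndarray:
    """Vertices u with f(u) ≤ f(v) for every neighbor v (isolated ⇒ minimum)."""
    f = np.asarray(f, dtype=float)
    out = []
    for u in range(g.n_vertices):
        nb = g.neighbors[u]
        if nb.size == 0 or np.all(f[u] <= f[nb]):
            out.append(u)
    return np.asarray(out, dtype=int)


@dataclass
class Basin:
    """A basin of attraction: focal minimum, members, and its depth profile."""

    focal_min: int
    members: np.ndarray  # vertex indices, sorted
    focal_energy: float
    saddle_vertex: int | None = None
    saddle_energy: float | None = None
    saddle_neighbor: int | None = field(default=None, repr=False)
    persistence: float = math.inf
    stability: float = math.inf

    @property
    def size(self) -> int:
        return len(self.members)


def _descent_targets(g: NNGraph, f: np.ndarray) -> np.ndarray:
    """Steepest-descent pointer per vertex (itself, for local minima).

    The descent edge maximises (f(u) − f(v)) / d(u, v) over neighbors with
    f(v) < f(u); ties go to the lowest-index neighbor.  A vertex with no
    strictly lower neighbor points to itself (local minimum, plateaus
    included).
    """
    f = np.asarray(f, dtype=float)
    target = np.arange(g.n_vertices)
    for u in range(g.n_vertices):
        nb, dd = g.neighbors[u], g.distances[u]
        if nb.size == 0:
            continue
        lower = f[nb] < f[u]
        if not np.any(lower):
            continue
        cand, cd = nb[lower], dd[lower]
        ratios = (f[u] - f[cand]) / cd
        best = ratios.max()
        # lowest-index neighbor among exact ties (neighbors are index-sorted)
        target[u] = int(cand[np.nonzero(ratios == best)[0][0]])
    return target


def assign_basins(g: NNGraph, f: np.ndarray) -> list[Basin]:
    """Partition the vertices into basins by following the negative gradient.

    Every non-minimum vertex iteratively follows its steepest-descent edge
    to a local minimum; vertices reaching the same minimum form its basin.
    Basins are returned ordered by focal vertex index.
    """
    f = np.asarray(f, dtype=float)
    target = _descent_targets(g, f)
    root = target.copy()
    # pointer chasing with path compression; descent strictly decreases f,
    # so this terminates (the cycle guard is belt-and-braces)
    for u in range(g.n_vertices):
        seen = 0
        v = root[u]
        while target[v] != v:
            v = target[v]
            seen += 1
            if seen > g.n_vertices:
                raise RuntimeError("cycle detected in descent map")
        root[u] = v
    basins = []
    for m in np.unique(root):
        members = np.nonzero(root == m)[0]
        basins.append(Basin(int(m), members, float(f[m])))
    return basins


def _labels_of(basins: list[Basin], n: int) -> np.ndarray:
    labels = np.full(n, -1, dtype=int)
    for k, b in enumerate(basins):
        labels[b.members] = k
    return labels


def compute_saddles(g: NNGraph, basins: list[Basin], f: np.ndarray) -> list[Basin]:
    """Fill pseudo-saddle, persistence (and merge target) per basin, in place.

    A pseudo-saddle of basin B is a member u with a neighbor v such that
    f(v) < f(u) and v drains to a different basin; among qualifiers the one
    with minimal f(u) is taken, so persistence = f(saddle) − f(focal) is the
    minimal barrier out of B.  Basins with no qualifier (e.g. the deepest
    basin of a component) keep persistence = +∞.
    """
    f = np.asarray(f, dtype=float)
    labels = _labels_of(basins, g.n_vertices)
    best_u = [None] * len(basins)
    best_v = [None] * len(basins)
    for u in range(g.n_vertices):
        bu = labels[u]
        nb = g.neighbors[u]
        if nb.size == 0:
            continue
        mask = (f[nb] < f[u]) & (labels[nb] != bu)
        if not np.any(mask):
            continue
        if best_u[bu] is None or f[u] < f[best_u[bu]]:
            cand = nb[mask]
            best_u[bu] = u
            best_v[bu] = int(cand[np.argmin(f[cand])])
    for k, b in enumerate(basins):
        if best_u[k] is None:
            b.saddle_vertex = None
            b.saddle_energy = None
            b.saddle_neighbor = None
            b.persistence = math.inf
        else:
            b.saddle_vertex = int(best_u[k])
            b.saddle_energy = float(f[best_u[k]])
            b.saddle_neighbor = best_v[k]
            b.persistence = float(f[best_u[k]] - b.focal_energy)
    return basins


def compute_stability(basins: list[Basin]) -> list[Basin]:
    """Stability = |f(saddle) − f(focal)| / √2, the distance of the basin's
    point in the (focal energy, saddle energy) plane from the identity line."""
    for b in basins:
        b.stability = (
            math.inf if not math.isfinite(b.persistence)
            else abs(b.persistence) / math.sqrt(2.0)
        )
    return basins


def merge_by_persistence(
    g: NNGraph, basins: list[Basin], f: np.ndarray, p_thresh: float
) -> list[Basin]:
    """Merge shallow basins until all survivors have persistence ≥ p_thresh.

    Iteratively the lowest-persistence basin below the threshold is merged
    into the basin its saddle drains to (the basin of the saddle's lower
    neighbor); saddles and persistences are recomputed after every merge.
    The focal minimum of a merged basin is its deepest member.  The basin
    count never increases, and p_thresh = 0 leaves the list unchanged.
    """
    if p_thresh < 0:
        raise ValueError("p_thresh must be >= 0")
    f = np.asarray(f, dtype=float)
    basins = [b for b in basins]
    compute_saddles(g, basins, f)
    while True:
        cand = [
            (b.persistence, b.focal_min, k)
            for k, b in enumerate(basins)
            if math.isfinite(b.persistence) and b.persistence < p_thresh
        ]
        if not cand:
            break
        _, _, k = min(cand)
        victim = basins[k]
        labels = _labels_of(basins, g.n_vertices)
        tgt = int(labels[victim.saddle_neighbor])
        assert tgt != k
        absorber = basins[tgt]
        members = np.sort(np.concatenate([absorber.members, victim.members]))
        focal = int(members[np.argmin(f[members])])
        merged = Basin(focal, members, float(f[focal]))
        basins = [b for i, b in enumerate(basins) if i not in (k, tgt)] + [merged]
        basins.sort(key=lambda b: b.focal_min)
        compute_saddles(g, basins, f)
    compute_stability(basins)
    return basins


def prefilter_high_energy(ds: DecoySet, quantile: float) -> DecoySet:
    """Drop the highest-energy fraction of decoys before graph building.

    Only a *high*-energy prefilter is offered: removing low-energy decoys
    deletes focal minima and fabricates spurious basins, destroying the very
    landscape structure the basins encode.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    cut = np.quantile(ds.energies, 1.0 - quantile)
    keep = [d for d in ds.decoys if d.energy <= cut]
    return DecoySet(decoys=keep, native=ds.native,
                    distance_mode=ds.distance_mode, superposed=ds.superposed)


def extract_basins(
    ds: DecoySet,
    epsilon: float,
    p_thresh: float = 1.0,
    prefilter_quantile: float | None = None,
) -> tuple[list[Basin], NNGraph, DecoySet]:
    """Full basin pipeline: (optional prefilter) → ε-graph → descent → merge.

    Returns the merged basins (saddles and stabilities filled), the graph,
    and the decoy set the vertex indices refer to (differs from the input
    only when a prefilter was applied).
    """
    if prefilter_quantile:
        ds = prefilter_high_energy(ds, prefilter_quantile)
    g = build_nngraph(ds, epsilon)
    f = ds.energies
    basins = assign_basins(g, f)
    basins = merge_by_persistence(g, basins, f, p_thresh)
    return basins, g, ds
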