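"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from basinsel import DecoySet, PlantedLandscapeSpec, generate_planted
from basinsel.decoy_io import Decoy
from basinsel.landscape import NNGraph, nngraph_from_distance_matrix


# -- independent oracles ---------------------------------------------------


def lrmsd_bruteforce(A: np.ndarray, B: np.ndarray) -> float:
    """Minimum RMSD over SO(3) by Euler-grid search + Nelder-Mead refinement.

    Deliberately independent of the Kabsch/SVD route used by the package.
    """
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)

    def rms(rotvec: np.ndarray) -> float:
        R = Rotation.from_rotvec(rotvec).as_matrix()
        return float(np.sqrt(np.mean(np.sum((A - B @ R.T) ** 2, axis=1))))

    step = np.deg2rad(12.0)
    cands = []
    for ez, ey, ex in product(
        np.arange(0, 2 * np.pi, step),
        np.arange(-np.pi / 2, np.pi / 2 + 1e-9, step),
        np.arange(0, 2 * np.pi, step),
    ):
        vec = Rotation.from_euler("zyx", [ez, ey, ex]).as_rotvec()
        cands.append((rms(vec), tuple(vec)))
    cands.sort()
    best = cands[0][0]
    # refine the several best grid cells: a single local search can stall in
    # the wrong rotation well
    for val, vec in cands[:5]:
        res = minimize(
            rms, np.array(vec), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000},
        )
        best = min(best, float(res.fun))
    return best


def descent_oracle(g: NNGraph, f: np.ndarray) -> np.ndarray:
    """Per-vertex exhaustive steepest-ratio descent: follow, from each vertex,
    the neighbor maximising (f(u)−f(v))/d among strictly lower neighbors
    (ties to the lowest index) until none remains.  Returns the reached
    minimum per vertex."""
    f = np.asarray(f, dtype=float)
    out = np.empty(g.n_vertices, dtype=int)
    for u in range(g.n_vertices):
        cur = u
        while True:
            cands = [
                (-(f[cur] - f[v]) / d, int(v))
                for v, d in zip(g.neighbors[cur], g.distances[cur])
                if f[v] < f[cur]
            ]
            if not cands:
                break
            cur = min(cands)[1]
        out[u] = cur
    return out


def pareto_bruteforce(sizes, energies):
    """O(B²) PR/PC counts straight from the strong-dominance definition."""
    B = len(sizes)
    pr = np.zeros(B, dtype=int)
    pc = np.zeros(B, dtype=int)
    for a in range(B):
        for b in range(B):
            if a != b and sizes[a] > sizes[b] and energies[a] < energies[b]:
                pc[a] += 1
                pr[b] += 1
    return pr, pc


def random_geometric_graph(rng: np.random.Generator, n_max: int = 30):
    """A random ε-graph over random planar points, plus random energies."""
    n = int(rng.integers(4, n_max + 1))
    pts = rng.uniform(0, 10, size=(n, 2))
    dist = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    eps = float(rng.uniform(1.0, 6.0))
    f = rng.normal(size=n)
    return nngraph_from_distance_matrix(dist, eps), f


# -- fixtures --------------------------------------------------------------


@pytest.fixture
def path_graph():
    """4-vertex path 0-1-2-3 with unit edges and f = [3, 1, 2, 0.5]."""
    D = np.array(
        [[0, 1, 2, 3], [1, 0, 1, 2], [2, 1, 0, 1], [3, 2, 1, 0]], dtype=float
    )
    return nngraph_from_distance_matrix(D, 1.0), np.array([3.0, 1.0, 2.0, 0.5])


@pytest.fixture
def feature_set_1d():
    """1-D feature decoys at {0, 0.5, 10, 10.4, 20} (hand-traceable clusters)."""
    xs = [0.0, 0.5, 10.0, 10.4, 20.0]
    decoys = [
        Decoy(id=f"d{i}", energy=float(i), features=np.array([x]))
        for i, x in enumerate(xs)
    ]
    return DecoySet(decoys=decoys, distance_mode="precomputed_features")


@pytest.fixture
def planted_three_wells():
    spec = PlantedLandscapeSpec(n_basins=3, samples_per_basin=120, seed=7)
    return generate_planted(spec) + (spec,)


def make_labeled_set(n: int, n_native: int, seed: int = 0) -> DecoySet:
    """Feature decoy set with the first n_native decoys within 1 Å of native."""
    rng = np.random.default_rng(seed)
    decoys = []
    for i in range(n):
        native = i < n_native
        nd = float(rng.uniform(0, 0.9)) if native else float(rng.uniform(3, 9))
        decoys.append(
            Decoy(id=f"d{i}", energy=float(rng.normal()), native_dist=nd,
                  features=rng.uniform(0, 10, size=2))
        )
    return DecoySet(decoys=decoys, distance_mode="precomputed_features")
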