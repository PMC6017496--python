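"""Baseline selection machinery: follow-the-leader clustering and random draws.

Leader clustering is the classic order-dependent, single-scan algorithm used
for clustering very large decoy sets: after shuffling, each decoy either
founds a new cluster (becoming its representative) or joins the first
existing cluster whose representative lies within ε Å.  The order
dependence is deliberate and controlled by an explicit shuffle seed.

The random baseline (Cluster-Random) draws groups uniformly at random from
the whole decoy set, sized like the largest clusters; it calibrates how much
structure a non-random selection strategy actually exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decoy_io import DecoySet

__all__ = ["Cluster", "leader_cluster", "adapt_epsilon", "cluster_random"]


@dataclass
class Cluster:
    """One leader cluster: its representative (founder) and member ids."""

    representative: str
    members: list[str] = field(default_factory=list)
    member_indices: list[int] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)


def leader_cluster(
    ds: DecoySet, epsilon: float, shuffle_seed: int = 0
) -> list[Cluster]:
    """Single-scan follow-the-leader clustering at radius ``epsilon``.

    The decoys are shuffled with ``shuffle_seed`` and scanned once; each
    decoy joins the FIRST cluster (in founding order) whose representative
    is within ``epsilon``, else founds a new cluster.  Clusters are returned
    sorted by size (descending), ties broken by founding order.  The result
    is a partition of the decoy set, and every member lies within ε of its
    cluster's representative.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    n = len(ds)
    ids = ds.ids
    rng = np.random.default_rng(shuffle_seed)
    order = rng.permutation(n)

    pts = ds.point_matrix()
    rep_indices: list[int] = []
    clusters: list[Cluster] = []
    if pts is not None:
        rep_pts: list[np.ndarray] = []
        for i in order:
            i = int(i)
            if rep_pts:
                dists = np.linalg.norm(np.asarray(rep_pts) - pts[i], axis=1)
                hits = np.nonzero(dists <= epsilon)[0]
            else:
                hits = []
            if len(hits) > 0:
                clusters[int(hits[0])].members.append(ids[i])
                clusters[int(hits[0])].member_indices.append(i)
            else:
                rep_pts.append(pts[i])
                rep_indices.append(i)
                clusters.append(Cluster(ids[i], [ids[i]], [i]))
    else:
        for i in order:
            i = int(i)
            placed = False
            for k, rep in enumerate(rep_indices):
                if ds.distance(i, rep) <= epsilon:
                    clusters[k].members.append(ids[i])
                    clusters[k].member_indices.append(i)
                    placed = True
                    break
            if not placed:
                rep_indices.append(i)
                clusters.append(Cluster(ids[i], [ids[i]], [i]))

    founding = {id(c): k for k, c in enumerate(clusters)}
    clusters.sort(key=lambda c: (-c.size, founding[id(c)]))
    return clusters


def adapt_epsilon(
    ds: DecoySet,
    epsilon0: float = 1.0,
    step: float = 0.5,
    cap: float = 10.0,
    shuffle_seed: int = 0,
) -> float:
    """Smallest ε in {ε₀, ε₀+step, …} whose largest leader cluster is non-trivial.

    "Non-trivial" means the largest cluster has at least two members — a
    singleton cluster exists for any ε, so the adaptation rule is read as
    requiring genuine aggregation.  Starts at 1 Å by default and increases
    until that holds, erroring past ``cap``.
    """
    if epsilon0 <= 0 or step <= 0:
        raise ValueError("epsilon0 and step must be positive")
    eps = epsilon0
    while eps <= cap + 1e-12:
        clusters = leader_cluster(ds, eps, shuffle_seed=shuffle_seed)
        if clusters[0].size >= 2:
            return eps
        eps += step
    raise ValueError(
        f"no epsilon <= cap ({cap} Å) produced a non-singleton largest cluster"
    )


def cluster_random(
    ds: DecoySet,
    group_sizes: list[int],
    runs: int = 5,
    seed: int = 0,
) -> list[list[list[str]]]:
    """Uniform random draws matched in size to the top clusters.

    For each of ``runs`` independent repetitions, draws one group per entry
    of ``group_sizes`` uniformly at random from the whole decoy set, without
    replacement within a group.  Returns ``runs`` lists of groups (lists of
    decoy ids); downstream metrics are averaged over the runs.
    """
    n = len(ds)
    for sz in group_sizes:
        if sz > n:
            raise ValueError(f"group size {sz} exceeds decoy set size {n}")
        if sz < 1:
            raise ValueError("group sizes must be >= 1")
    ids = np.array(ds.ids)
    rng = np.random.default_rng(seed)
    out: list[list[list[str]]] = []
    for _ in range(runs):
        run_groups = [
            list(rng.choice(ids, size=sz, replace=False)) for sz in group_sizes
        ]
        out.append(run_groups)
    return out
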