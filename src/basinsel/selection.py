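"""Ranking basins (or clusters) and selecting the top-x groups.

Six strategies are supported.  Two baselines operate on leader clusters:

* ``Cluster-Size`` — the x largest clusters;
* ``Cluster-Random`` — random groups matched in size to the largest
  clusters (5 independent runs, metrics averaged downstream).

Four operate on landscape basins:

* ``Basin-Size`` — basins by size, largest first;
* ``Basin-Size+Energy`` — the ten largest basins, reordered by focal
  energy (lowest first);
* ``Basin-PR`` — basins by Pareto rank (number of basins that strongly
  dominate them on size and negative focal energy), lowest first;
* ``Basin-PR+PC`` — Pareto rank, with ties broken by Pareto count
  (number of basins dominated), highest first.

Strong dominance: basin a dominates basin b iff size(a) > size(b) AND
focal_energy(a) < focal_energy(b).  After each strategy's stated keys, ties
are broken by focal energy ascending, then founding index, so every ranking
is a deterministic total order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .clustering import adapt_epsilon, cluster_random, leader_cluster
from .decoy_io import DecoySet
from .landscape import Basin, extract_basins

__all__ = [
    "STRATEGIES",
    "normalize_strategy",
    "ParetoScores",
    "RankedGroups",
    "dominates",
    "pareto_scores",
    "rank_basins",
    "select",
]

STRATEGIES = (
    "Cluster-Size",
    "Cluster-Random",
    "Basin-Size",
    "Basin-Size+Energy",
    "Basin-PR",
    "Basin-PR+PC",
)

_ALIAS = {s.lower().replace("-", "_").replace("+", "_"): s for s in STRATEGIES}


def normalize_strategy(name: str) -> str:
    key = name.lower().replace("-", "_").replace("+", "_").replace(" ", "_")
    if key not in _ALIAS:
        raise ValueError(
            f"unknown strategy {name!r}; valid strategies: {', '.join(STRATEGIES)}"
        )
    return _ALIAS[key]


def dominates(a: Basin, b: Basin) -> bool:
    """Strong Pareto dominance on (size, −focal energy): strict on both."""
    return a.size > b.size and a.focal_energy < b.focal_energy


@dataclass
class ParetoScores:
    """Per-basin Pareto rank (dominators) and Pareto count (dominated)."""

    pr: np.ndarray
    pc: np.ndarray


def pareto_scores(
    basins: Sequence[Basin], include_stability: bool = False
) -> ParetoScores:
    """Exhaustive pairwise PR/PC.  ΣPR == ΣPC == number of dominating pairs.

    ``include_stability`` adds stability as a third maximised objective — an
    experimental mode; by default persistence-related characteristics are
    deliberately not selection objectives, as they do not improve decoy
    selection and can mask high-purity low-stability basins.
    """
    if len(basins) < 1:
        raise ValueError("need at least one basin")
    sizes = np.array([b.size for b in basins])
    energies = np.array([b.focal_energy for b in basins])
    dom = (sizes[:, None] > sizes[None, :]) & (energies[:, None] < energies[None, :])
    if include_stability:
        stab = np.array([b.stability for b in basins])
        dom &= stab[:, None] > stab[None, :]
    return ParetoScores(pr=dom.sum(axis=0), pc=dom.sum(axis=1))


@dataclass
class RankedGroups:
    """Ordered selection G1..Gx with per-group provenance.

    For Cluster-Random, ``runs`` holds all independent draws and ``groups``
    the first one; metrics should be averaged over ``runs``.
    """

    strategy: str
    groups: list[list[str]]
    provenance: list[dict] = field(default_factory=list)
    runs: list[list[list[str]]] | None = None
    info: dict = field(default_factory=dict)


def rank_basins(
    basins: Sequence[Basin],
    strategy: str,
    x: int,
    ids: Sequence[str] | None = None,
    pool_size: int = 10,
    stability_objective: bool = False,
) -> RankedGroups:
    """Order basins under one of the four basin strategies and take the top x.

    ``ids`` maps vertex indices to decoy ids (indices are used when absent).
    If fewer than x basins exist all are returned and the shortfall flagged
    in ``info['truncated']``.
    """
    if x < 1:
        raise ValueError("x must be >= 1")
    strategy = normalize_strategy(strategy)
    scores = pareto_scores(basins, include_stability=stability_objective)
    idx = list(range(len(basins)))

    def base_key(k: int):  # shared tie-break chain
        return (basins[k].focal_energy, k)

    if strategy == "Basin-Size":
        order = sorted(idx, key=lambda k: (-basins[k].size, *base_key(k)))
    elif strategy == "Basin-Size+Energy":
        by_size = sorted(idx, key=lambda k: (-basins[k].size, *base_key(k)))
        order = sorted(by_size[:pool_size], key=base_key)
    elif strategy == "Basin-PR":
        order = sorted(idx, key=lambda k: (scores.pr[k], *base_key(k)))
    elif strategy == "Basin-PR+PC":
        order = sorted(idx, key=lambda k: (scores.pr[k], -scores.pc[k], *base_key(k)))
    else:
        raise ValueError(f"{strategy} is not a basin strategy")

    chosen = order[:x]
    to_id = (lambda v: ids[v]) if ids is not None else (lambda v: str(v))
    groups = [[to_id(int(v)) for v in basins[k].members] for k in chosen]
    prov = [
        {
            "basin_index": int(k),
            "focal_min": int(basins[k].focal_min),
            "size": int(basins[k].size),
            "focal_energy": float(basins[k].focal_energy),
            "persistence": float(basins[k].persistence),
            "stability": float(basins[k].stability),
            "pr": int(scores.pr[k]),
            "pc": int(scores.pc[k]),
        }
        for k in chosen
    ]
    return RankedGroups(
        strategy=strategy,
        groups=groups,
        provenance=prov,
        info={"truncated": len(basins) < x, "n_basins": len(basins)},
    )


def select(
    ds: DecoySet,
    strategy: str,
    epsilon: float = 1.0,
    x: int = 3,
    seed: int = 0,
    p_thresh: float = 1.0,
    adapt: bool = True,
    runs: int = 5,
    prefilter_quantile: float | None = None,
    pool_size: int = 10,
) -> RankedGroups:
    """End-to-end driver: build clusters or basins as needed, return G1..Gx.

    ``epsilon`` is the initial neighborhood radius (1 Å by default); with
    ``adapt`` it is increased in 0.5 Å steps until the largest leader
    cluster is non-trivial, and the same ε is reused for the basin graph.
    Deterministic given ``seed``.
    """
    strategy = normalize_strategy(strategy)
    if adapt:
        epsilon = adapt_epsilon(ds, epsilon0=epsilon, shuffle_seed=seed)

    if strategy in ("Cluster-Size", "Cluster-Random"):
        clusters = leader_cluster(ds, epsilon, shuffle_seed=seed)
        top = clusters[:x]
        if strategy == "Cluster-Size":
            return RankedGroups(
                strategy=strategy,
                groups=[list(c.members) for c in top],
                provenance=[
                    {"representative": c.representative, "size": c.size}
                    for c in top
                ],
                info={"epsilon": epsilon, "n_clusters": len(clusters),
                      "truncated": len(clusters) < x},
            )
        draws = cluster_random(ds, [c.size for c in top], runs=runs, seed=seed)
        return RankedGroups(
            strategy=strategy,
            groups=draws[0],
            provenance=[{"size": c.size} for c in top],
            runs=draws,
            info={"epsilon": epsilon, "runs": runs},
        )

    basins, g, ds_used = extract_basins(
        ds, epsilon, p_thresh=p_thresh, prefilter_quantile=prefilter_quantile
    )
    ranked = rank_basins(basins, strategy, x, ids=ds_used.ids, pool_size=pool_size)
    ranked.info.update(
        {"epsilon": epsilon, "n_components": g.n_components,
         "p_thresh": p_thresh, "n_decoys_used": len(ds_used)}
    )
    return ranked
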