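"""Native labelling and the n / p / s evaluation metrics.

A decoy counts as *native* when its lRMSD to the experimentally determined
structure is within a per-target threshold ``dist_thresh``.  The threshold
depends on target difficulty, summarised by ``min_dist`` — the lowest
lRMSD-to-native over the whole decoy set:

* easy (min_dist ≤ 0.7 Å): dist_thresh = 2 Å;
* medium (0.7 < min_dist < 2 Å): the smallest value in a 0.5 Å-stepped
  scan of [2, 4.5] Å for which the largest leader cluster contains at
  least one native;
* hard (min_dist ≥ 2 Å): at least 6 Å, increased by the same scan rule
  until the largest cluster admits a native.

Selections are scored on the union U = G1 ∪ … ∪ Gx of the top x groups:

* ``n`` — percentage of all natives captured by U (true-positive rate);
* ``p`` — purity, percentage of U that is native;
* ``s`` — relative size of U in the decoy set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from .decoy_io import DecoySet
from .selection import RankedGroups

__all__ = [
    "EvalConfig",
    "MetricsRow",
    "difficulty_of",
    "label_natives",
    "choose_dist_thresh",
    "score_groups",
]


@dataclass
class EvalConfig:
    dist_thresh: float
    min_dist: float
    difficulty: str  # easy | medium | hard
    x_max: int = 3
    scan_exhausted: bool = False

    def __post_init__(self) -> None:
        if self.dist_thresh <= 0:
            raise ValueError("dist_thresh must be positive")
        if self.difficulty not in ("easy", "medium", "hard"):
            raise ValueError(f"unknown difficulty {self.difficulty!r}")
        if self.difficulty != difficulty_of(self.min_dist):
            raise ValueError(
                f"difficulty {self.difficulty!r} inconsistent with "
                f"min_dist={self.min_dist}"
            )


@dataclass
class MetricsRow:
    """n/p/s (%) for the union of the top-x groups; None marks not-applicable."""

    x: int
    n: float | None
    p: float | None
    s: float


def difficulty_of(min_dist: float) -> str:
    if min_dist <= 0.7:
        return "easy"
    if min_dist < 2.0:
        return "medium"
    return "hard"


def label_natives(
    ds: DecoySet, dist_thresh: float
) -> tuple[dict[str, bool], int]:
    """Label each decoy native iff its distance to native ≤ dist_thresh.

    Uses the precomputed ``native_dist`` column when present, otherwise
    computes lRMSD to the native reference.  Returns (id → label, count).
    """
    if dist_thresh <= 0:
        raise ValueError("dist_thresh must be positive")
    dists = ds.native_distances()
    labels = {i: bool(d <= dist_thresh) for i, d in zip(ds.ids, dists)}
    return labels, sum(labels.values())


def choose_dist_thresh(
    min_dist: float,
    largest_group_native_count: Callable[[float], int] | None = None,
    scan_range: tuple[float, float] = (2.0, 4.5),
    step: float = 0.5,
    hard_min: float = 6.0,
    hard_cap: float = 10.0,
    x_max: int = 3,
) -> EvalConfig:
    """Pick the per-target native threshold from min_dist and the scan rule.

    ``largest_group_native_count`` maps a candidate threshold to the number
    of natives (under that threshold) inside the largest leader cluster; it
    drives the medium/hard scan.  If the scan exhausts its range with no
    native in the largest cluster, the range maximum is returned with
    ``scan_exhausted`` set.
    """
    difficulty = difficulty_of(min_dist)
    if difficulty == "easy":
        return EvalConfig(2.0, min_dist, "easy", x_max)

    lo, hi = (scan_range if difficulty == "medium" else (hard_min, hard_cap))
    if largest_group_native_count is None:
        return EvalConfig(lo, min_dist, difficulty, x_max)
    thresh = lo
    while thresh <= hi + 1e-9:
        if largest_group_native_count(thresh) > 0:
            return EvalConfig(thresh, min_dist, difficulty, x_max)
        thresh += step
    return EvalConfig(hi, min_dist, difficulty, x_max, scan_exhausted=True)


def _metrics_for_union(
    union: set[str], labels: Mapping[str, bool], total_natives: int, n_total: int
) -> tuple[float | None, float | None, float]:
    hits = sum(1 for i in union if labels[i])
    s = 100.0 * len(union) / n_total
    if total_natives == 0:
        return None, None, s  # NA, not 0: there was nothing to find
    n = 100.0 * hits / total_natives
    p = 100.0 * hits / len(union) if union else 0.0
    return n, p, s


def score_groups(
    groups: RankedGroups,
    labels: Mapping[str, bool],
    n_total: int,
    x_max: int = 3,
) -> list[MetricsRow]:
    """n/p/s for each cumulative union G1..Gx, x = 1..x_max.

    For Cluster-Random selections (``groups.runs`` set) the metrics are
    averaged over the independent runs.  ``n_total`` is |Ω|; the native
    total is taken from ``labels`` over the whole set.
    """
    total_natives = sum(bool(v) for v in labels.values())
    run_lists = groups.runs if groups.runs is not None else [groups.groups]
    rows: list[MetricsRow] = []
    for x in range(1, x_max + 1):
        per_run: list[tuple[float | None, float | None, float]] = []
        for run in run_lists:
            union: set[str] = set()
            for grp in run[:x]:
                union.update(grp)
            per_run.append(
                _metrics_for_union(union, labels, total_natives, n_total)
            )
        if total_natives == 0:
            rows.append(MetricsRow(x, None, None,
                                   float(np.mean([m[2] for m in per_run]))))
        else:
            rows.append(
                MetricsRow(
                    x,
                    float(np.mean([m[0] for m in per_run])),
                    float(np.mean([m[1] for m in per_run])),
                    float(np.mean([m[2] for m in per_run])),
                )
            )
    return rows
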