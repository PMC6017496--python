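"""Diagnostic figures: selection scatter and basin disk plots."""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .decoy_io import DecoySet
from .landscape import Basin
from .selection import RankedGroups

__all__ = ["plot_selection", "plot_basin_disks"]

_GROUP_COLORS = ("tab:red", "tab:green", "tab:blue", "tab:orange", "tab:purple")


def plot_selection(ds: DecoySet, groups: RankedGroups, out: str | os.PathLike) -> None:
    """Scatter of all decoys (grey) in the (lRMSD-to-native, energy) plane,
    with the selected top-x groups color-coded."""
    dists = ds.native_distances()
    energies = ds.energies
    pos = {i: k for k, i in enumerate(ds.ids)}
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(dists, energies, s=4, c="0.75", label="all decoys", rasterized=True)
    for gi, grp in enumerate(groups.groups):
        idx = [pos[i] for i in grp]
        ax.scatter(
            dists[idx], energies[idx], s=8,
            c=_GROUP_COLORS[gi % len(_GROUP_COLORS)], label=f"G{gi + 1}",
        )
    ax.set_xlabel("lRMSD to native (Å)")
    ax.set_ylabel("energy")
    ax.set_title(groups.strategy)
    ax.legend(fontsize=8, markerscale=2)
    fig.tight_layout()
    fig.savefig(os.fspath(out), dpi=120)
    plt.close(fig)


def plot_basin_disks(
    basins: Sequence[Basin],
    purities: Sequence[float],
    out: str | os.PathLike,
    selected: Sequence[int] | None = None,
) -> None:
    """Basins as disks at (stability, focal energy): area ∝ size, color = purity.

    Basins with infinite stability (no escape saddle) are drawn as square
    markers at a sentinel x just past the finite maximum, noted in the
    legend.  ``selected`` basin indices are outlined.
    """
    stab = np.array([b.stability for b in basins], dtype=float)
    energy = np.array([b.focal_energy for b in basins])
    sizes = np.array([b.size for b in basins], dtype=float)
    finite = np.isfinite(stab)
    sentinel = (stab[finite].max() * 1.2 + 1.0) if finite.any() else 1.0
    xs = np.where(finite, stab, sentinel)
    areas = 30.0 + 270.0 * sizes / sizes.max()

    fig, ax = plt.subplots(figsize=(6, 4.5))
    sc = ax.scatter(
        xs[finite], energy[finite], s=areas[finite], c=np.asarray(purities)[finite],
        cmap="coolwarm", vmin=0.0, vmax=100.0, edgecolors="k", linewidths=0.3,
    )
    if (~finite).any():
        ax.scatter(
            xs[~finite], energy[~finite], s=areas[~finite],
            c=np.asarray(purities)[~finite], cmap="coolwarm", vmin=0.0, vmax=100.0,
            marker="s", edgecolors="k", linewidths=0.3,
            label="infinite stability (sentinel x)",
        )
        ax.legend(fontsize=7)
    if selected:
        for k in selected:
            ax.scatter(
                xs[k], energy[k], s=areas[k] * 1.8, facecolors="none",
                edgecolors="k", linewidths=1.2, marker="s",
            )
    fig.colorbar(sc, ax=ax, label="purity (%)")
    ax.set_xlabel("stability")
    ax.set_ylabel("focal energy")
    fig.tight_layout()
    fig.savefig(os.fspath(out), dpi=120)
    plt.close(fig)
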