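"""Synthetic decoy sets with planted landscape structure.

Real decoy ensembles (tens of thousands of Rosetta conformations per
target) are too large to ship and too opaque to test against, so this
module plants known structure instead:

* :func:`generate_planted` samples points around k well centers in a
  low-dimensional feature space and scores them with a sum-of-Gaussian-wells
  energy plus observation noise.  The generating well of each point is the
  ground-truth basin label, and an analytic watershed
  (:func:`watershed_labels`) provides an independent membership oracle.
* :func:`generate_toy_conformations` perturbs an ideal α-helix Cα trace
  with per-group coordinate jitter, exercising the PDB / lRMSD path with
  conformations whose expected distance to the reference grows with the
  jitter scale.

Defaults plant wells of depth 10 down to 5 energy units, unit width,
centers separated by 5σ, 150 samples per well, and observation noise at 5%
of the shallowest depth — dense enough that the ε-graph resolves every well
yet noisy enough that persistence filtering has something to remove.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .decoy_io import Conformation, Decoy, DecoySet

__all__ = [
    "PlantedLandscapeSpec",
    "generate_planted",
    "watershed_labels",
    "well_energy",
    "generate_toy_conformations",
    "make_helix",
]


@dataclass
class PlantedLandscapeSpec:
    """Parameters of a planted k-well landscape (all units arbitrary-energy/Å-like)."""

    n_basins: int = 3
    dim: int = 2
    samples_per_basin: int | tuple[int, ...] = 150
    well_centers: np.ndarray | None = None  # (k, dim)
    well_depths: np.ndarray | None = None  # > 0, default linspace(10, 5, k)
    well_widths: np.ndarray | None = None  # σ per well, default 1.0
    noise_sd: float | None = None  # default 5% of the shallowest depth
    native_center_index: int = 0
    separation_factor: float = 4.0  # min center distance, in units of max σ
    truncate_sigma: float = 3.0  # wells sample a truncated Gaussian
    seed: int = 0

    def resolve(self) -> "PlantedLandscapeSpec":
        """Fill defaults and validate; returns a fully concrete copy."""
        k = self.n_basins
        if k < 1:
            raise ValueError("n_basins must be >= 1")
        depths = (
            np.linspace(10.0, 5.0, k)
            if self.well_depths is None
            else np.asarray(self.well_depths, dtype=float)
        )
        widths = (
            np.ones(k)
            if self.well_widths is None
            else np.asarray(self.well_widths, dtype=float)
        )
        if len(depths) != k or len(widths) != k:
            raise ValueError("well_depths and well_widths must have n_basins entries")
        if np.any(depths <= 0) or np.any(widths <= 0):
            raise ValueError("well depths and widths must be positive")
        if self.well_centers is None:
            # centers on a line, spaced comfortably beyond the separation floor
            spacing = 1.25 * self.separation_factor * widths.max()
            centers = np.zeros((k, self.dim))
            centers[:, 0] = spacing * np.arange(k)
        else:
            centers = np.asarray(self.well_centers, dtype=float)
        if centers.shape != (k, self.dim):
            raise ValueError("well_centers must have shape (n_basins, dim)")
        min_sep = self.separation_factor * widths.max()
        for a in range(k):
            for b in range(a + 1, k):
                d = float(np.linalg.norm(centers[a] - centers[b]))
                if d < min_sep - 1e-9:
                    raise ValueError(
                        f"wells {a} and {b} are {d:.3g} apart; "
                        f"the separation invariant requires >= {min_sep:.3g}"
                    )
        counts = self.samples_per_basin
        counts = (
            tuple(int(c) for c in counts)
            if isinstance(counts, (tuple, list, np.ndarray))
            else (int(counts),) * k
        )
        if len(counts) != k or any(c < 1 for c in counts):
            raise ValueError("samples_per_basin must give >= 1 sample per well")
        noise = (
            0.05 * float(depths.min()) if self.noise_sd is None else self.noise_sd
        )
        if noise < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.native_center_index < k:
            raise ValueError("native_center_index out of range")
        return PlantedLandscapeSpec(
            n_basins=k, dim=self.dim, samples_per_basin=counts,
            well_centers=centers, well_depths=depths, well_widths=widths,
            noise_sd=noise, native_center_index=self.native_center_index,
            separation_factor=self.separation_factor,
            truncate_sigma=self.truncate_sigma, seed=self.seed,
        )


def well_energy(X: np.ndarray, spec: PlantedLandscapeSpec) -> np.ndarray:
    """Noise-free planted energy: −Σ_w depth_w · exp(−‖x−c_w‖² / (2σ_w²))."""
    spec = spec.resolve()
    X = np.atleast_2d(X)
    e = np.zeros(len(X))
    for c, depth, sigma in zip(
        spec.well_centers, spec.well_depths, spec.well_widths
    ):
        sq = np.sum((X - c) ** 2, axis=1)
        e -= depth * np.exp(-sq / (2.0 * sigma**2))
    return e


def watershed_labels(X: np.ndarray, spec: PlantedLandscapeSpec) -> np.ndarray:
    """Analytic watershed oracle: the well whose term dominates at each point."""
    spec = spec.resolve()
    X = np.atleast_2d(X)
    contrib = np.stack(
        [
            -depth * np.exp(-np.sum((X - c) ** 2, axis=1) / (2.0 * sigma**2))
            for c, depth, sigma in zip(
                spec.well_centers, spec.well_depths, spec.well_widths
            )
        ],
        axis=1,
    )
    return np.argmin(contrib, axis=1)


def _truncated_normal(
    rng: np.random.Generator, n: int, dim: int, sigma: float, cut: float
) -> np.ndarray:
    """Isotropic Gaussian sample with radius capped at ``cut``·σ (resampling)."""
    out = np.empty((n, dim))
    filled = 0
    while filled < n:
        draw = rng.normal(scale=sigma, size=(2 * (n - filled) + 8, dim))
        ok = draw[np.linalg.norm(draw, axis=1) <= cut * sigma]
        take = min(len(ok), n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def generate_planted(
    spec: PlantedLandscapeSpec,
) -> tuple[DecoySet, np.ndarray]:
    """Sample a planted-well decoy set; returns (DecoySet, ground-truth labels).

    Decoy features are the sampled coordinates; energy is the planted well
    energy plus N(0, noise_sd²) observation noise; native_dist is the
    Euclidean distance to the native well's center.  Byte-identical output
    for identical specs (fixed seed).
    """
    spec = spec.resolve()
    rng = np.random.default_rng(spec.seed)
    xs, labels = [], []
    for w, (c, sigma, count) in enumerate(
        zip(spec.well_centers, spec.well_widths, spec.samples_per_basin)
    ):
        pts = c + _truncated_normal(rng, count, spec.dim, sigma, spec.truncate_sigma)
        xs.append(pts)
        labels.append(np.full(count, w))
    X = np.concatenate(xs)
    labels = np.concatenate(labels)
    energy = well_energy(X, spec)
    if spec.noise_sd > 0:
        energy = energy + rng.normal(scale=spec.noise_sd, size=len(X))
    native_c = spec.well_centers[spec.native_center_index]
    native_d = np.linalg.norm(X - native_c, axis=1)
    width = len(str(len(X) - 1))
    decoys = [
        Decoy(
            id=f"d{i:0{width}d}", energy=float(energy[i]),
            native_dist=float(native_d[i]), features=X[i],
        )
        for i in range(len(X))
    ]
    ds = DecoySet(decoys=decoys, distance_mode="precomputed_features")
    return ds, labels


# -- toy conformations ----------------------------------------------------


def make_helix(n_residues: int = 20) -> Conformation:
    """Ideal α-helix Cα trace: radius 2.3 Å, rise 1.5 Å, 100° per residue."""
    t = np.arange(n_residues)
    theta = np.deg2rad(100.0) * t
    coords = np.stack(
        [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * t], axis=1
    )
    return Conformation(coords, tuple((i + 1, "CA") for i in range(n_residues)))


def generate_toy_conformations(
    n: int,
    jitter_schedule: list[float],
    seed: int = 0,
    n_residues: int = 20,
) -> DecoySet:
    """``n`` decoys per jitter group, perturbing a reference helix.

    Group g adds isotropic Gaussian jitter of scale ``jitter_schedule[g]``
    (Å) to every Cα of the reference; a smooth pseudo-energy (base −50,
    rising with the group's jitter, with small noise) is attached so the
    full PDB → lRMSD → landscape path can be exercised.  Decoy ids are
    ``g<group>_d<index>``; the reference helix is the native.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ref = make_helix(n_residues)
    rng = np.random.default_rng(seed)
    decoys = []
    for g, jitter in enumerate(jitter_schedule):
        for i in range(n):
            noise = rng.normal(scale=jitter, size=ref.coords.shape) if jitter > 0 \
                else np.zeros_like(ref.coords)
            conf = Conformation(ref.coords + noise, ref.labels)
            energy = -50.0 + 5.0 * jitter + float(rng.normal(scale=0.05))
            decoys.append(Decoy(id=f"g{g}_d{i}", energy=energy, conformation=conf))
    return DecoySet(
        decoys=decoys, native=ref, distance_mode="reference_superposed_rmsd"
    )
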