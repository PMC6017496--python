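"""Decoy-set I/O and conformational distances.

A *decoy* is one computationally generated candidate conformation of a
protein, scored by some energy function (e.g. Rosetta score12, in Rosetta
Energy Units).  A :class:`DecoySet` holds the whole sampled ensemble Ω plus
an optional native reference, and exposes the pairwise distance backend the
rest of the package is built on.

Three distance backends are supported:

``full_lrmsd``
    Exact least-RMSD (Kabsch superposition) for every pair — O(n²)
    superpositions, used for small sets and as the gold standard.
``reference_superposed_rmsd``
    The standard speedup: every decoy is rigidly superposed once onto an
    arbitrary reference decoy (the first, by default), after which the plain
    coordinate RMSD is used as the pairwise distance.  This is the default.
``precomputed_features``
    Euclidean distance on fixed-length per-decoy feature vectors (used by
    the synthetic-landscape generator and the tabular dialect).

The canonical on-disk intermediate is a whitespace/tab-delimited score table
with a header: ``id  energy  [native_dist]  [f0 f1 ...]``.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBIO, PDBParser, StructureBuilder
from Bio.SVDSuperimposer import SVDSuperimposer
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "Conformation",
    "Decoy",
    "DecoySet",
    "lrmsd",
    "plain_rmsd",
    "superpose_to_reference",
    "read_decoy_set",
    "read_score_table",
    "write_score_table",
    "read_pdb_conformation",
    "write_pdb_conformation",
]

DISTANCE_MODES = ("full_lrmsd", "reference_superposed_rmsd", "precomputed_features")


@dataclass(frozen=True)
class Conformation:
    """An ordered set of 3-D atom positions (Å) with residue/atom labels."""

    coords: np.ndarray  # (n_atoms, 3)
    labels: tuple[tuple[int, str], ...] = ()  # (residue index, atom name)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if coords.shape[0] < 3:
            raise ValueError("a conformation needs at least 3 atoms")
        if not np.isfinite(coords).all():
            raise ValueError("coordinates must be finite")
        labels = tuple(self.labels)
        if not labels:
            labels = tuple((i + 1, "CA") for i in range(coords.shape[0]))
        if len(labels) != coords.shape[0]:
            raise ValueError("labels and coords must have the same length")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "labels", labels)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class Decoy:
    """One sampled conformation with its scalar energy f(x)."""

    id: str
    energy: float
    conformation: Conformation | None = None
    native_dist: float | None = None
    features: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.energy):
            raise ValueError(f"decoy {self.id!r}: energy must be finite")
        if self.native_dist is not None and self.native_dist < 0:
            raise ValueError(f"decoy {self.id!r}: native_dist must be >= 0")
        if self.features is not None:
            object.__setattr__(
                self, "features", np.asarray(self.features, dtype=float)
            )


@dataclass
class DecoySet:
    """The decoy ensemble Ω, an optional native reference, and a distance backend."""

    decoys: list[Decoy]
    native: Conformation | None = None
    distance_mode: str = "reference_superposed_rmsd"
    superposed: bool = False
    _point_cache: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.decoys) < 1:
            raise ValueError("a decoy set needs at least one decoy")
        ids = [d.id for d in self.decoys]
        if len(set(ids)) != len(ids):
            raise ValueError("decoy ids must be unique")
        if self.distance_mode not in DISTANCE_MODES:
            raise ValueError(
                f"unknown distance_mode {self.distance_mode!r}; "
                f"expected one of {DISTANCE_MODES}"
            )
        if self.distance_mode == "precomputed_features":
            dims = {d.features.shape for d in self.decoys if d.features is not None}
            if len(dims) != 1 or any(d.features is None for d in self.decoys):
                raise ValueError(
                    "precomputed_features mode requires a fixed-length feature "
                    "vector on every decoy"
                )

    def __len__(self) -> int:
        return len(self.decoys)

    @property
    def ids(self) -> list[str]:
        return [d.id for d in self.decoys]

    @property
    def energies(self) -> np.ndarray:
        return np.array([d.energy for d in self.decoys], dtype=float)

    @property
    def native_dists(self) -> np.ndarray | None:
        vals = [d.native_dist for d in self.decoys]
        if any(v is None for v in vals):
            return None
        return np.array(vals, dtype=float)

    # -- distance backend -------------------------------------------------

    def point_matrix(self) -> np.ndarray | None:
        """A Euclidean embedding of the decoys, if the backend admits one.

        In feature mode these are the feature vectors.  In
        reference-superposed mode the flattened coordinates are scaled by
        1/sqrt(n_atoms) so that Euclidean distance equals plain RMSD.
        Returns None for the exact full-lRMSD backend.
        """
        if self._point_cache is not None:
            return self._point_cache
        if self.distance_mode == "precomputed_features":
            pts = np.stack([d.features for d in self.decoys])
        elif self.distance_mode == "reference_superposed_rmsd":
            ds = self if self.superposed else superpose_to_reference(self, 0)
            n_atoms = ds.decoys[0].conformation.n_atoms
            pts = np.stack(
                [d.conformation.coords.ravel() for d in ds.decoys]
            ) / math.sqrt(n_atoms)
        else:
            return None
        self._point_cache = pts
        return pts

    def distance_matrix(self) -> np.ndarray:
        pts = self.point_matrix()
        if pts is not None:
            return squareform(pdist(pts))
        n = len(self)
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = lrmsd(self.decoys[i].conformation, self.decoys[j].conformation)
                out[i, j] = out[j, i] = d
        return out

    def distance(self, i: int, j: int) -> float:
        pts = self.point_matrix()
        if pts is not None:
            return float(np.linalg.norm(pts[i] - pts[j]))
        return lrmsd(self.decoys[i].conformation, self.decoys[j].conformation)

    def native_distances(self, force: bool = False) -> np.ndarray:
        """Per-decoy lRMSD to the native reference (cached on the decoys)."""
        cached = self.native_dists
        if cached is not None and not force:
            return cached
        if self.native is None:
            raise ValueError(
                "no native reference and no precomputed native_dist column"
            )
        return np.array(
            [lrmsd(d.conformation, self.native) for d in self.decoys], dtype=float
        )


# -- distances ------------------------------------------------------------


def _check_pair(a: Conformation, b: Conformation) -> None:
    if a.n_atoms != b.n_atoms:
        raise ValueError(
            f"conformations have different atom counts ({a.n_atoms} vs {b.n_atoms})"
        )


def lrmsd(a: Conformation, b: Conformation) -> float:
    """Least RMSD (Å) after optimal rigid-body (Kabsch) superposition.

    Symmetric, non-negative, zero under any rigid motion of one copy.
    """
    _check_pair(a, b)
    sup = SVDSuperimposer()
    sup.set(a.coords, b.coords)
    sup.run()
    return float(sup.get_rms())


def plain_rmsd(a: Conformation, b: Conformation) -> float:
    """Coordinate RMSD (Å) without superposition."""
    _check_pair(a, b)
    return float(np.sqrt(np.mean(np.sum((a.coords - b.coords) ** 2, axis=1))))


def superpose_to_reference(ds: DecoySet, ref_index: int = 0) -> DecoySet:
    """Rigidly superpose every decoy onto ``ds.decoys[ref_index]``.

    After this one-off superposition the plain RMSD between any two decoys
    is used as their distance — the standard O(n) shortcut that avoids n²
    pairwise Kabsch fits (at the cost of distances that upper-bound the true
    pairwise lRMSD).
    """
    if not (0 <= ref_index < len(ds)):
        raise IndexError(f"ref_index {ref_index} out of range for {len(ds)} decoys")
    if any(d.conformation is None for d in ds.decoys):
        raise ValueError("superposition requires coordinates on every decoy")
    ref = ds.decoys[ref_index].conformation
    new_decoys = []
    for d in ds.decoys:
        sup = SVDSuperimposer()
        sup.set(ref.coords, d.conformation.coords)
        sup.run()
        moved = Conformation(sup.get_transformed(), d.conformation.labels)
        new_decoys.append(replace(d, conformation=moved))
    return DecoySet(
        decoys=new_decoys,
        native=ds.native,
        distance_mode=ds.distance_mode,
        superposed=True,
    )


# -- PDB ------------------------------------------------------------------

_PARSER = PDBParser(QUIET=True)


def read_pdb_conformation(path: str | os.PathLike, ca_only: bool = True) -> Conformation:
    """Parse ATOM records of a PDB file into a :class:`Conformation`.

    ``ca_only`` keeps Cα atoms only (robust to side-chain naming); otherwise
    all atoms of standard residues are kept, in file order.
    """
    structure = _PARSER.get_structure("decoy", os.fspath(path))
    coords, labels = [], []
    for model in structure:
        for chain in model:
            for residue in chain:
                if residue.id[0] != " ":  # skip HETATM/water
                    continue
                for atom in residue:
                    if ca_only and atom.get_name() != "CA":
                        continue
                    coords.append(atom.get_coord())
                    labels.append((residue.id[1], atom.get_name()))
        break  # first model only
    if len(coords) < 3:
        raise ValueError(f"{path}: fewer than 3 usable atoms parsed")
    return Conformation(np.array(coords, dtype=float), tuple(labels))


def write_pdb_conformation(conf: Conformation, path: str | os.PathLike) -> None:
    """Write a conformation as a single-chain PDB file (CA trace by default)."""
    builder = StructureBuilder.StructureBuilder()
    builder.init_structure("s")
    builder.init_model(0)
    builder.init_chain("A")
    builder.init_seg("    ")
    for i, ((resid, atom_name), xyz) in enumerate(zip(conf.labels, conf.coords)):
        builder.init_residue("GLY", " ", int(resid), " ")
        builder.init_atom(
            atom_name, np.asarray(xyz, dtype=float), 0.0, 1.0, " ",
            atom_name.center(4), i + 1, element=atom_name[0],
        )
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(os.fspath(path))


# -- score tables / tabular dialect ---------------------------------------


def read_score_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read the canonical whitespace/tab-delimited score table.

    Required columns: ``id``, ``energy``.  Optional: ``native_dist`` and
    feature columns ``f0, f1, ...``.
    """
    df = pd.read_csv(path, sep=r"\s+")
    for col in ("id", "energy"):
        if col not in df.columns:
            raise ValueError(f"score table {path} lacks required column {col!r}")
    df["id"] = df["id"].astype(str)
    try:
        df["energy"] = df["energy"].astype(float)
    except ValueError as exc:
        raise ValueError(f"score table {path}: unparseable energy ({exc})") from exc
    if not np.isfinite(df["energy"]).all():
        bad = df.loc[~np.isfinite(df["energy"]), "id"].iloc[0]
        raise ValueError(f"score table {path}: non-finite energy for id {bad!r}")
    return df


def write_score_table(ds: DecoySet, path: str | os.PathLike) -> None:
    """Write the tabular dialect; lossless to 6 significant digits."""
    rows: dict[str, list] = {"id": ds.ids, "energy": list(ds.energies)}
    nd = ds.native_dists
    if nd is not None:
        rows["native_dist"] = list(nd)
    if ds.distance_mode == "precomputed_features":
        feats = np.stack([d.features for d in ds.decoys])
        for k in range(feats.shape[1]):
            rows[f"f{k}"] = list(feats[:, k])
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def decoy_set_from_table(df: pd.DataFrame) -> DecoySet:
    """Build a feature-mode (or distance-only) DecoySet from a score table."""
    feat_cols = sorted(
        (c for c in df.columns if c.startswith("f") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    has_nd = "native_dist" in df.columns
    decoys = []
    for _, row in df.iterrows():
        feats = row[feat_cols].to_numpy(dtype=float) if feat_cols else None
        nd = float(row["native_dist"]) if has_nd else None
        decoys.append(
            Decoy(id=str(row["id"]), energy=float(row["energy"]),
                  native_dist=nd, features=feats)
        )
    if not feat_cols:
        # distance-only tables still need *some* backend; native_dist-sorted
        # 1-D features keep downstream ops (which only need d(u,v)) usable.
        if not has_nd:
            raise ValueError(
                "tabular decoy sets need feature columns f0.. or native_dist"
            )
        decoys = [replace(d, features=np.array([d.native_dist])) for d in decoys]
    return DecoySet(decoys=decoys, distance_mode="precomputed_features")


def read_decoy_set(
    pdb_dir: str | os.PathLike | None = None,
    score_table: str | os.PathLike = "",
    native_pdb: str | os.PathLike | None = None,
    ca_only: bool = True,
    distance_mode: str = "reference_superposed_rmsd",
) -> DecoySet:
    """Read a decoy set from PDB files + score table, or from a bare table.

    With ``pdb_dir`` given, every score-table row must name a PDB file in
    that directory (``<id>`` or ``<id>.pdb``).  Without it, the table itself
    must carry the tabular dialect (feature columns and/or native_dist) and
    the returned set uses the ``precomputed_features`` backend.
    """
    df = read_score_table(score_table)
    if pdb_dir is None:
        return decoy_set_from_table(df)

    pdb_dir = Path(pdb_dir)
    native = (
        read_pdb_conformation(native_pdb, ca_only=ca_only) if native_pdb else None
    )
    decoys = []
    for _, row in df.iterrows():
        did = str(row["id"])
        path = pdb_dir / did
        if not path.exists():
            path = pdb_dir / f"{did}.pdb"
        if not path.exists():
            raise FileNotFoundError(
                f"decoy {did!r}: no PDB file {did}[.pdb] in {pdb_dir}"
            )
        conf = read_pdb_conformation(path, ca_only=ca_only)
        if native is not None and conf.n_atoms != native.n_atoms:
            raise ValueError(
                f"decoy {did!r}: atom count {conf.n_atoms} does not match "
                f"native ({native.n_atoms}) under ca_only={ca_only}"
            )
        nd = float(row["native_dist"]) if "native_dist" in df.columns else None
        decoys.append(
            Decoy(id=did, energy=float(row["energy"]), conformation=conf,
                  native_dist=nd)
        )
    return DecoySet(decoys=decoys, native=native, distance_mode=distance_mode)
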