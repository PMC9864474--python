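"""Multi-conformer structure I/O and RMSD dissimilarity matrices.

Conformers of one molecule share an atom list (same elements, same order),
so the dissimilarity between two of them is the root-mean-square deviation
between corresponding atoms.  By default coordinates are compared as
given; an optional least-squares rigid superposition (Kabsch) can be
applied first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.transform import Rotation

from .matrix_core import DissimilarityMatrix, validate_matrix

__all__ = [
    "Conformer",
    "ConformerEnsemble",
    "read_xyz",
    "write_xyz",
    "read_sdf",
    "pairwise_rmsd",
    "build_matrix",
]


@dataclass(frozen=True)
class Conformer:
    """One geometry: element symbols plus Cartesian coordinates in Å."""

    id: str
    elements: tuple[str, ...]
    coords: np.ndarray  # (A, 3) float64

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=np.float64)
        if c.ndim != 2 or c.shape[1] != 3:
            raise ValueError(f"coords must be (A, 3), got {c.shape}")
        if len(self.elements) != c.shape[0]:
            raise ValueError(
                f"{len(self.elements)} elements but {c.shape[0]} coordinate rows"
            )
        if c.shape[0] < 1:
            raise ValueError("conformer must have at least one atom")
        if not np.all(np.isfinite(c)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "coords", c)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def without_hydrogens(self) -> "Conformer":
        keep = [i for i, e in enumerate(self.elements) if e.upper() != "H"]
        if not keep:
            raise ValueError("conformer has no heavy atoms")
        return Conformer(
            id=self.id,
            elements=tuple(self.elements[i] for i in keep),
            coords=self.coords[keep],
        )


@dataclass(frozen=True)
class ConformerEnsemble:
    """K >= 2 conformers with identical element sequences."""

    conformers: tuple[Conformer, ...]
    source: str = "synthetic"

    def __post_init__(self):
        if len(self.conformers) < 2:
            raise ValueError("ensemble needs at least 2 conformers")
        ref = self.conformers[0].elements
        for c in self.conformers[1:]:
            if c.elements != ref:
                raise ValueError(
                    f"conformer {c.id!r} has a different element sequence than "
                    f"{self.conformers[0].id!r}: corresponding-atom RMSD is undefined"
                )

    @property
    def size(self) -> int:
        return len(self.conformers)

    @property
    def elements(self) -> tuple[str, ...]:
        return self.conformers[0].elements

    def without_hydrogens(self) -> "ConformerEnsemble":
        return ConformerEnsemble(
            conformers=tuple(c.without_hydrogens() for c in self.conformers),
            source=self.source,
        )

    def coords_array(self) -> np.ndarray:
        """(K, A, 3) stacked coordinates."""
        return np.stack([c.coords for c in self.conformers])


# ---------------------------------------------------------------------------
# file formats

def read_xyz(path: str | Path) -> ConformerEnsemble:
    """Read a multi-record XYZ file (atom-count line, comment line, atom
    lines, repeated).  The comment line supplies the conformer id when
    non-empty, else a running index."""
    path = Path(path)
    lines = path.read_text().splitlines()
    conformers: list[Conformer] = []
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            natoms = int(lines[pos].strip())
        except ValueError as exc:
            raise ValueError(
                f"{path}: expected atom count at line {pos + 1}, got {lines[pos]!r}"
            ) from exc
        if natoms < 1:
            raise ValueError(f"{path}: bad atom count {natoms} at line {pos + 1}")
        if pos + 2 + natoms > len(lines):
            raise ValueError(f"{path}: truncated record starting at line {pos + 1}")
        comment = lines[pos + 1].strip()
        elements: list[str] = []
        coords: list[list[float]] = []
        for k in range(natoms):
            parts = lines[pos + 2 + k].split()
            if len(parts) < 4:
                raise ValueError(
                    f"{path}: malformed atom line {pos + 3 + k}: {lines[pos + 2 + k]!r}"
                )
            elements.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
        conformers.append(
            Conformer(
                id=comment or str(len(conformers)),
                elements=tuple(elements),
                coords=np.array(coords),
            )
        )
        pos += 2 + natoms
    if len(conformers) < 2:
        raise ValueError(f"{path}: need at least 2 XYZ records, found {len(conformers)}")
    return ConformerEnsemble(conformers=tuple(conformers), source=str(path))


def write_xyz(ensemble: ConformerEnsemble, path: str | Path) -> None:
    """Write the ensemble as concatenated XYZ records (full float repr, so a
    read-back reproduces coordinates exactly)."""
    path = Path(path)
    with path.open("w") as fh:
        for c in ensemble.conformers:
            fh.write(f"{c.n_atoms}\n{c.id}\n")
            for e, (x, y, z) in zip(c.elements, c.coords):
                fh.write(f"{e} {float(x)!r} {float(y)!r} {float(z)!r}\n")


def read_sdf(path: str | Path) -> ConformerEnsemble:
    """Read a multi-record SDF/MOL V2000 file, taking elements and
    coordinates from each record's atom block.  Records are split on the
    ``$$$$`` delimiter; bonds and properties are ignored."""
    path = Path(path)
    text = path.read_text()
    records = [r for r in text.split("$$$$") if r.strip()]
    if len(records) < 2:
        raise ValueError(f"{path}: need at least 2 SDF records, found {len(records)}")
    conformers = []
    for ri, rec in enumerate(records):
        lines = rec.lstrip("\n").splitlines()
        if len(lines) < 4:
            raise ValueError(f"{path}: SDF record {ri} too short")
        title = lines[0].strip()
        counts = lines[3]
        try:
            natoms = int(counts[0:3])
        except (ValueError, IndexError) as exc:
            raise ValueError(
                f"{path}: SDF record {ri} has a malformed counts line: {counts!r}"
            ) from exc
        if "V2000" not in counts:
            raise ValueError(f"{path}: SDF record {ri} is not V2000")
        if len(lines) < 4 + natoms:
            raise ValueError(f"{path}: SDF record {ri} atom block truncated")
        elements, coords = [], []
        for k in range(natoms):
            al = lines[4 + k]
            try:
                x, y, z = float(al[0:10]), float(al[10:20]), float(al[20:30])
                el = al[31:34].strip()
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"{path}: SDF record {ri} malformed atom line: {al!r}"
                ) from exc
            if not el:
                raise ValueError(f"{path}: SDF record {ri} atom line missing element")
            elements.append(el)
            coords.append([x, y, z])
        conformers.append(
            Conformer(id=title or str(ri), elements=tuple(elements), coords=np.array(coords))
        )
    return ConformerEnsemble(conformers=tuple(conformers), source=str(path))


# ---------------------------------------------------------------------------
# RMSD

def _check_same_atoms(a: Conformer, b: Conformer) -> None:
    if a.elements != b.elements:
        raise ValueError(
            f"element sequences differ between {a.id!r} and {b.id!r}: "
            "corresponding-atom RMSD is undefined"
        )


def pairwise_rmsd(a: Conformer, b: Conformer, superpose: bool = False) -> float:
    """RMSD between corresponding atoms of two conformers, in Å.

    sqrt(mean over atoms of the squared Euclidean deviation).  With
    ``superpose`` the second conformer is first rigidly superposed onto the
    first by least squares (optimal rotation + translation), making the
    value invariant under rigid motions of either input.
    """
    _check_same_atoms(a, b)
    pa, pb = a.coords, b.coords
    if superpose:
        if pa.shape[0] == 1:
            return 0.0  # a single atom always superposes exactly
        ca, cb = pa - pa.mean(axis=0), pb - pb.mean(axis=0)
        _, rssd = Rotation.align_vectors(ca, cb)
        return float(rssd / np.sqrt(pa.shape[0]))
    return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))


def build_matrix(
    ensemble: ConformerEnsemble,
    superpose: bool = False,
    include_hydrogens: bool = True,
) -> DissimilarityMatrix:
    """All-pairs RMSD matrix of the ensemble; each unordered pair is computed
    once and mirrored.  Labels are the conformer ids; the superposition and
    hydrogen choices are recorded in the matrix metadata."""
    ens = ensemble if include_hydrogens else ensemble.without_hydrogens()
    K = ens.size
    coords = ens.coords_array()
    A = coords.shape[1]
    if superpose:
        values = np.zeros((K, K))
        if A > 1:
            centred = coords - coords.mean(axis=1, keepdims=True)
            for i in range(K - 1):
                for j in range(i + 1, K):
                    _, rssd = Rotation.align_vectors(centred[i], centred[j])
                    values[i, j] = values[j, i] = rssd / np.sqrt(A)
    else:
        # unaligned RMSD is the Euclidean distance between flattened
        # coordinate vectors scaled by 1/sqrt(A)
        flat = coords.reshape(K, -1)
        values = squareform(pdist(flat)) / np.sqrt(A)
    return validate_matrix(
        values,
        labels=[c.id for c in ens.conformers],
        metadata={
            "metric": "rmsd",
            "superpose": superpose,
            "include_hydrogens": include_hydrogens,
            "source": ens.source,
            "n_atoms": A,
        },
    )
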