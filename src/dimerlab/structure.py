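"""Core structural data types and geometric primitives.

A dimer is held as two :class:`MonomerStructure` objects inside a
:class:`DimerConformation`, optionally in a periodic cubic box. Residue
indices are 1-based positions on the full-length sequence and are preserved
through every operation; segment trimming is always explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import ATOMIC_MASS, RESIDUE_CLASS, STANDARD_AA

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "MonomerStructure",
    "DimerConformation",
    "classify_residue",
    "backbone_rmsd",
    "kabsch_rmsd",
    "central_calpha",
    "min_image_distance",
]

_BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})


@dataclass(frozen=True)
class AtomRecord:
    """A single atom: name, element and Cartesian coordinates in Å."""

    name: str
    element: str
    coords: np.ndarray

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", coords)

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"

    @property
    def is_backbone(self) -> bool:
        return self.name in _BACKBONE_NAMES


@dataclass(frozen=True)
class ResidueRecord:
    """One residue: 1-based full-length sequence index, one-letter code, atoms."""

    index: int
    aa: str
    atoms: tuple[AtomRecord, ...]

    def __post_init__(self):
        if self.index < 1:
            raise ValueError(f"residue index must be >= 1, got {self.index}")
        object.__setattr__(self, "atoms", tuple(self.atoms))

    @property
    def chem_class(self) -> str:
        return classify_residue(self.aa)

    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.index} has no atom {name!r}")

    @property
    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms if a.is_heavy], dtype=float)


@dataclass(frozen=True)
class MonomerStructure:
    """An ordered chain of residues with strictly increasing indices."""

    chain_id: str
    residues: tuple[ResidueRecord, ...]

    def __post_init__(self):
        object.__setattr__(self, "residues", tuple(self.residues))
        if not self.residues:
            raise ValueError(f"chain {self.chain_id}: empty chain")
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(f"chain {self.chain_id}: residue indices not strictly increasing")

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def atom_coords(self, names: set[str] | None = None, heavy_only: bool = False) -> np.ndarray:
        out = []
        for r in self.residues:
            for a in r.atoms:
                if names is not None and a.name not in names:
                    continue
                if heavy_only and not a.is_heavy:
                    continue
                out.append(a.coords)
        return np.array(out, dtype=float) if out else np.empty((0, 3))

    def backbone_coords(self) -> np.ndarray:
        """Backbone atom coordinates in a fixed (residue, name) order."""
        out = []
        for r in self.residues:
            for name in ("N", "CA", "C", "O"):
                for a in r.atoms:
                    if a.name == name:
                        out.append(a.coords)
                        break
        return np.array(out, dtype=float) if out else np.empty((0, 3))

    def calpha_coords(self) -> np.ndarray:
        out = [a.coords for r in self.residues for a in r.atoms if a.name == "CA"]
        return np.array(out, dtype=float) if out else np.empty((0, 3))

    def center_of_mass(self, weighted: bool = True) -> np.ndarray:
        """All-atom centre of mass (mass-weighted by default)."""
        coords, masses = [], []
        for r in self.residues:
            for a in r.atoms:
                coords.append(a.coords)
                masses.append(ATOMIC_MASS.get(a.element.upper(), 12.0) if weighted else 1.0)
        return np.average(np.array(coords), axis=0, weights=np.array(masses))

    def with_coords(self, coords: np.ndarray) -> "MonomerStructure":
        """Copy with all atom coordinates replaced (same atom ordering)."""
        coords = np.asarray(coords, dtype=float)
        residues, k = [], 0
        for r in self.residues:
            atoms = []
            for a in r.atoms:
                atoms.append(replace(a, coords=coords[k]))
                k += 1
            residues.append(replace(r, atoms=tuple(atoms)))
        if k != len(coords):
            raise ValueError("coordinate count does not match atom count")
        return replace(self, residues=tuple(residues))


@dataclass(frozen=True)
class DimerConformation:
    """A two-chain dimer, optionally in a periodic cubic box of side box_side Å."""

    monomer_a: MonomerStructure
    monomer_b: MonomerStructure
    box_side: float = 120.0
    periodic: bool = True

    def __post_init__(self):
        if self.periodic and not self.box_side > 0:
            raise ValueError("box_side must be > 0 for a periodic box")

    @property
    def monomers(self) -> tuple[MonomerStructure, MonomerStructure]:
        return (self.monomer_a, self.monomer_b)

    def all_coords(self) -> np.ndarray:
        a = [at.coords for r in self.monomer_a.residues for at in r.atoms]
        b = [at.coords for r in self.monomer_b.residues for at in r.atoms]
        return np.array(a + b, dtype=float)


def classify_residue(aa: str) -> str:
    """Chemical class of a standard residue: charged, polar or apolar."""
    aa = aa.upper()
    if aa not in STANDARD_AA:
        raise ValueError(f"unknown residue {aa!r}")
    return RESIDUE_CLASS[aa]


def kabsch_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """Minimum RMSD between two matched point sets over rigid superposition.

    Kabsch algorithm: centre both sets, take the rotation from the SVD of the
    covariance matrix (with a reflection guard), and evaluate the residual.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("incompatible structures")
    n = len(x)
    if n == 0:
        raise ValueError("incompatible structures: no atoms")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    cov = xc.T @ yc
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    rot = (u * np.array([1.0, 1.0, d])) @ vt
    # explicit residuals: exact for congruent sets (no trace-identity
    # cancellation)
    resid = xc @ rot - yc
    return float(np.sqrt((resid * resid).sum() / n))


def backbone_rmsd(mon: MonomerStructure, ref: MonomerStructure) -> float:
    """Backbone RMSD (N, CA, C, O) after optimal rigid superposition, Å."""
    x = mon.backbone_coords()
    y = ref.backbone_coords()
    if x.shape != y.shape:
        raise ValueError("incompatible structures")
    return kabsch_rmsd(x, y)


def central_calpha(mon: MonomerStructure, weighted: bool = True) -> tuple[int, AtomRecord]:
    """The Cα closest to the monomer's centre of mass.

    Returns ``(residue_index, atom)``; ties broken by lowest residue index.
    """
    com = mon.center_of_mass(weighted=weighted)
    best: tuple[float, int, AtomRecord] | None = None
    for r in mon.residues:
        for a in r.atoms:
            if a.name == "CA":
                d = float(np.linalg.norm(a.coords - com))
                if best is None or d < best[0] - 1e-12:
                    best = (d, r.index, a)
                break
    if best is None:
        raise ValueError(f"chain {mon.chain_id}: no CA atoms")
    return best[1], best[2]


def min_image_distance(x1: np.ndarray, x2: np.ndarray, box_side: float) -> float:
    """Minimum-image Euclidean distance in a cubic periodic box."""
    if not box_side > 0:
        raise ValueError("box_side must be > 0")
    d = np.asarray(x1, dtype=float) - np.asarray(x2, dtype=float)
    d -= box_side * np.round(d / box_side)
    return float(np.linalg.norm(d))
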