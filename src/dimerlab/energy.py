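"""Structure-based (Gō-type) energy model with restraint and pulling terms.

The native-contact potential stands in for a full transferable force field:
site pairs close in the reference structure attract through a Gaussian
well centred at their reference distance, all other non-bonded pairs are purely
repulsive, and chain connectivity is kept by stiff harmonic pseudo-bonds.
Two bespoke terms complete the model: a backbone-RMSD restraint
k_rmsd·(RMSD_A + RMSD_B) that keeps each monomer native-like while leaving
rigid-body motion free, and a constant-force pulling term −F·|x₁−x₂| acting
on the two central Cα anchors (the sign makes the force pull the anchors
apart; distances use the minimum-image convention).

Sites are Cα atoms by default; ``site_level='heavy'`` uses every heavy atom,
which is what the reduced toy dimers need for their planted interfaces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants as C
from .structure import DimerConformation, central_calpha, kabsch_rmsd

__all__ = ["EnergyModel", "build_energy_model", "restraint_energy",
           "pulling_energy", "native_contact_pairs"]


@dataclass
class EnergyModel:
    """All coefficients and precomputed pair lists of the stand-in potential."""

    reference: DimerConformation
    ref_coords: np.ndarray            # (N, 3) site coordinates of the reference
    site_monomer: np.ndarray          # 0/1 per site
    restraint_sites: tuple[np.ndarray, np.ndarray]  # Cα site indices per monomer
    bonds: np.ndarray                 # (n_bonds, 2) int
    bond_r0: np.ndarray
    native_pairs: np.ndarray          # (n_native, 2) int
    native_r0: np.ndarray
    native_eps: np.ndarray            # kcal/mol, > 0
    repulsive_pairs: np.ndarray       # (n_rep, 2) int
    excluded_volume_radius: float = 4.0
    repulsion_strength: float = 1.0
    well_width: float = 0.5          # Å, width of the Gaussian native wells
    bond_k: float = 20.0              # kcal/mol/Å²
    k_rmsd: float = 3.0               # kcal/mol per Å of backbone RMSD
    force_pn: float = 0.0
    anchors: tuple[int, int] = (0, 0)  # site indices of the central Cα atoms
    box_side: float = 120.0
    periodic: bool = True
    site_level: str = "ca"

    @property
    def n_sites(self) -> int:
        return len(self.ref_coords)

    def min_image(self, d: np.ndarray) -> np.ndarray:
        if self.periodic:
            d = d - self.box_side * np.round(d / self.box_side)
        return d

    # --- full-energy terms (used for checks and initialisation) -------------

    def pair_energy(self, coords: np.ndarray) -> float:
        e = 0.0
        if len(self.native_pairs):
            d = self.min_image(coords[self.native_pairs[:, 0]] - coords[self.native_pairs[:, 1]])
            r = np.sqrt(np.einsum("ij,ij->i", d, d))
            dr = r - self.native_r0
            e -= float(np.sum(self.native_eps
                              * np.exp(-dr * dr / (2.0 * self.well_width ** 2))))
        if len(self.repulsive_pairs):
            d = self.min_image(coords[self.repulsive_pairs[:, 0]]
                               - coords[self.repulsive_pairs[:, 1]])
            r = np.sqrt(np.einsum("ij,ij->i", d, d))
            e += float(np.sum(self.repulsion_strength
                              * (self.excluded_volume_radius / np.maximum(r, 0.1)) ** 12))
        if len(self.bonds):
            d = self.min_image(coords[self.bonds[:, 0]] - coords[self.bonds[:, 1]])
            r = np.sqrt(np.einsum("ij,ij->i", d, d))
            e += float(np.sum(self.bond_k * (r - self.bond_r0) ** 2))
        return e

    def restraint_term(self, coords: np.ndarray) -> float:
        if self.k_rmsd == 0:
            return 0.0
        e = 0.0
        for sites in self.restraint_sites:
            e += self.k_rmsd * kabsch_rmsd(coords[sites], self.ref_coords[sites])
        return e

    def pulling_term(self, coords: np.ndarray) -> float:
        if self.force_pn == 0:
            return 0.0
        d = self.min_image(coords[self.anchors[0]] - coords[self.anchors[1]])
        return -self.force_pn * C.KCAL_PER_PN_ANGSTROM * float(np.linalg.norm(d))

    def total_energy(self, coords: np.ndarray) -> float:
        return self.pair_energy(coords) + self.restraint_term(coords) \
            + self.pulling_term(coords)

    def anchor_distance(self, coords: np.ndarray) -> float:
        d = self.min_image(coords[self.anchors[0]] - coords[self.anchors[1]])
        return float(np.linalg.norm(d))


def _site_table(conf: DimerConformation, site_level: str):
    """Coordinates, monomer id, residue index, is-Cα flag per model site."""
    coords, mono, res_idx, is_ca = [], [], [], []
    for m, mon in enumerate(conf.monomers):
        for r in mon.residues:
            for a in r.atoms:
                if site_level == "ca" and a.name != "CA":
                    continue
                if site_level == "heavy" and not a.is_heavy:
                    continue
                coords.append(a.coords)
                mono.append(m)
                res_idx.append(r.index)
                is_ca.append(a.name == "CA")
    return (np.array(coords), np.array(mono), np.array(res_idx),
            np.array(is_ca, dtype=bool))


def native_contact_pairs(coords: np.ndarray, exclude: set[tuple[int, int]],
                         same_residue: np.ndarray, cutoff: float) -> np.ndarray:
    """All site pairs within the native cutoff, minus bonds and same-residue pairs."""
    n = len(coords)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in exclude or same_residue[i] == same_residue[j]:
                continue
            if dist[i, j] <= cutoff:
                out.append((i, j))
    return np.array(out, dtype=int) if out else np.empty((0, 2), dtype=int)


def build_energy_model(ref: DimerConformation, native_cutoff: float = 8.0,
                       well_depth: float = 1.0, inter_monomer_scale: float = 1.0,
                       excluded_volume_radius: float = 4.0,
                       repulsion_strength: float = 1.0, well_width: float = 0.5,
                       bond_k: float = 20.0,
                       k_rmsd: float = 3.0, force_pn: float = 0.0,
                       site_level: str = "ca") -> EnergyModel:
    """Construct the stand-in potential from a reference conformation.

    Native contacts are all site pairs within ``native_cutoff`` in the
    reference (intra- and inter-monomer); inter-monomer well depths are
    multiplied by ``inter_monomer_scale``, the interface-strength dial.
    """
    coords, mono, res_idx, is_ca = _site_table(ref, site_level)
    for m in (0, 1):
        if int(np.sum(mono == m)) < 3:
            raise ValueError("reference must have at least 3 sites per monomer")

    # chain bonds: consecutive Cα within a monomer; non-Cα sites bond to the
    # Cα of their own residue
    bonds, bond_keys = [], set()
    ca_index: dict[tuple[int, int], int] = {}
    for k in range(len(coords)):
        if is_ca[k]:
            ca_index[(int(mono[k]), int(res_idx[k]))] = k
    prev_ca: dict[int, int] = {}
    for k in range(len(coords)):
        m = int(mono[k])
        if is_ca[k]:
            if m in prev_ca:
                bonds.append((prev_ca[m], k))
            prev_ca[m] = k
        else:
            bonds.append((ca_index[(m, int(res_idx[k]))], k))
    bonds = np.array(sorted(tuple(sorted(b)) for b in bonds), dtype=int) \
        if bonds else np.empty((0, 2), dtype=int)
    bond_keys = {tuple(b) for b in bonds.tolist()}
    d = coords[bonds[:, 0]] - coords[bonds[:, 1]] if len(bonds) else np.empty((0, 3))
    bond_r0 = np.sqrt(np.einsum("ij,ij->i", d, d)) if len(bonds) else np.empty(0)

    # same-residue identifier to exclude intra-residue non-bonded pairs
    same_res = mono.astype(np.int64) * 100_000 + res_idx.astype(np.int64)
    native = native_contact_pairs(coords, bond_keys, same_res, native_cutoff)
    if len(native):
        d = coords[native[:, 0]] - coords[native[:, 1]]
        native_r0 = np.sqrt(np.einsum("ij,ij->i", d, d))
        inter = mono[native[:, 0]] != mono[native[:, 1]]
        native_eps = np.full(len(native), float(well_depth))
        native_eps[inter] *= inter_monomer_scale
    else:
        native_r0 = np.empty(0)
        native_eps = np.empty(0)

    native_keys = {tuple(p) for p in native.tolist()}
    rep = [(i, j) for i in range(len(coords)) for j in range(i + 1, len(coords))
           if (i, j) not in bond_keys and (i, j) not in native_keys
           and same_res[i] != same_res[j]]
    rep = np.array(rep, dtype=int) if rep else np.empty((0, 2), dtype=int)

    # anchors: central Cα of each monomer, mapped to site indices
    anchors = []
    for m, mon in enumerate(ref.monomers):
        res, _ = central_calpha(mon)
        anchors.append(ca_index[(m, res)])

    restraint_sites = (np.where((mono == 0) & is_ca)[0], np.where((mono == 1) & is_ca)[0])
    return EnergyModel(reference=ref, ref_coords=coords, site_monomer=mono,
                       restraint_sites=restraint_sites, bonds=bonds, bond_r0=bond_r0,
                       native_pairs=native, native_r0=native_r0, native_eps=native_eps,
                       repulsive_pairs=rep,
                       excluded_volume_radius=excluded_volume_radius,
                       repulsion_strength=repulsion_strength, well_width=well_width,
                       bond_k=bond_k,
                       k_rmsd=k_rmsd, force_pn=force_pn,
                       anchors=(anchors[0], anchors[1]),
                       box_side=ref.box_side, periodic=ref.periodic,
                       site_level=site_level)


def restraint_energy(conf: DimerConformation, ref: DimerConformation,
                     k_rmsd: float) -> float:
    """k_rmsd · (backbone RMSD of monomer A + backbone RMSD of monomer B)."""
    from .structure import backbone_rmsd
    e = 0.0
    for mon, mon_ref in zip(conf.monomers, ref.monomers):
        x = mon.backbone_coords()
        y = mon_ref.backbone_coords()
        if len(x) == 0:  # Cα-only reduced structures
            x = mon.calpha_coords()
            y = mon_ref.calpha_coords()
        if x.shape != y.shape:
            raise ValueError("incompatible structures")
        e += k_rmsd * kabsch_rmsd(x, y)
    return e


def pulling_energy(conf: DimerConformation, force_pn: float,
                   anchors: tuple[tuple[int, int], ...] | None = None) -> float:
    """Constant-force pulling term −F·|x₁−x₂| in kcal/mol.

    ``anchors`` optionally gives (residue_index, per-monomer) of the two
    anchor Cα atoms; by default the central Cα of each monomer is used.
    The minimum-image anchor distance is used in a periodic box.
    """
    xs = []
    for m, mon in enumerate(conf.monomers):
        if anchors is None:
            _, atom = central_calpha(mon)
        else:
            res_idx = anchors[m][0] if isinstance(anchors[m], tuple) else anchors[m]
            res = next(r for r in mon.residues if r.index == res_idx)
            atom = res.atom("CA")
        xs.append(atom.coords)
    d = xs[0] - xs[1]
    if conf.periodic:
        d = d - conf.box_side * np.round(d / conf.box_side)
    return -force_pn * C.KCAL_PER_PN_ANGSTROM * float(np.linalg.norm(d))
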