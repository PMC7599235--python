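"""Synthetic inputs: toy dimers with planted interfaces, native-like
ensembles, backbone geometry builders, and sequence pairs.

Every generator is deterministic given its seed, and records the exact
ground truth it plants so the closed loop generate → analyse → recover can
be tested exactly.

The toy dimers are reduced-representation two-chain complexes: each monomer
is an ideal α-helical Cα trace (rise 1.5 Å, radius 2.3 Å per turn step of
100°), and interface interactions are planted as side-chain pseudo-atoms of
the chemistry matching the requested interaction type (Leu CD1–CD1 for
hydrophobic, Lys NZ–Glu OE1 for ionic, Ser OG–OG for hydrogen bonds),
placed at the midpoint of each rule's distance window so cutoff jitter
cannot flip the ground truth. All non-planted inter-monomer residue pairs
exceed the 5.5 Å contact cutoff by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .seqcompare import SequencePair
from .structure import AtomRecord, DimerConformation, MonomerStructure, ResidueRecord

__all__ = [
    "InterfaceSpec",
    "ToyDimer",
    "make_toy_dimer",
    "make_dimer_series",
    "perturb_ensemble",
    "make_sequence_pair",
    "reference_sequence_pair",
    "build_backbone_chain",
    "build_antiparallel_sheet",
    "PGIC_VARIABLE_POSITIONS",
    "PGIC_NEAR_INTERFACE_POSITIONS",
]

# Variable positions between the two alleles of the grass cytosolic
# phosphoglucose isomerase studied here (1-based, full-length numbering),
# and the subset located near the dimer interface. Used both as planted
# ground truth for the synthetic stand-in pair and as a regression fixture.
PGIC_VARIABLE_POSITIONS = (48, 49, 53, 62, 85, 109, 118, 121, 123, 200,
                           210, 237, 266, 312, 318, 372, 455, 466, 521, 554)
PGIC_NEAR_INTERFACE_POSITIONS = (200, 372, 466, 521)
PGIC_FULL_LENGTH = 567

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

# ideal helix Cα-trace geometry
_HELIX_RISE = 1.5
_HELIX_RADIUS = 2.3
_HELIX_TURN_DEG = 100.0

# planted interaction geometry: type -> (aa_a, atom_a, elem_a, aa_b, atom_b,
# elem_b, planted distance Å = midpoint-ish of the rule window)
_PLANT = {
    "hydrophobic": ("L", "CD1", "C", "L", "CD1", "C", 4.0),
    "ionic": ("K", "NZ", "N", "E", "OE1", "O", 3.5),
    "hbond": ("S", "OG", "O", "S", "OG", "O", 3.0),
}

#: axis-to-axis distance between the two monomer helices, Å
_INTERFACE_GAP = 13.0
#: slot spacing along the chain (residues); 4 residues = 6 Å in z, which
#: keeps distinct planted pairs outside every interaction cutoff
_SLOT_SPACING = 4
_SLOT_MARGIN = 2  # first/last usable slot residue distance from chain ends


def _slot_residues(n_res: int, n_pairs: int) -> list[int]:
    """1-based residues of the interface slots, centred on the chain.

    Centring matters: contacts near the chain middle sit close to the
    anchor Cα atoms, so a bound dimer cannot extend its anchor distance by
    pivoting about an end contact.
    """
    span = (n_pairs - 1) * _SLOT_SPACING
    first = (n_res - span + 1) // 2
    if n_pairs > 0 and (first < _SLOT_MARGIN or first + span > n_res - 1):
        raise ValueError(
            f"infeasible spec: {n_pairs} pairs need a span of {span + 1} residues "
            f"but only {n_res} are available")
    return [first + s * _SLOT_SPACING for s in range(n_pairs)]


@dataclass(frozen=True)
class InterfaceSpec:
    """Requested interface composition of a toy dimer."""

    n_hydrophobic_pairs: int = 0
    n_ionic_pairs: int = 0
    n_hbond_pairs: int = 0
    well_depth_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_hydrophobic_pairs, self.n_ionic_pairs, self.n_hbond_pairs) < 0:
            raise ValueError("pair counts must be >= 0")
        if self.well_depth_scale < 0:
            raise ValueError("well_depth_scale must be >= 0")

    @property
    def n_pairs(self) -> int:
        return self.n_hydrophobic_pairs + self.n_ionic_pairs + self.n_hbond_pairs


@dataclass(frozen=True)
class ToyDimer:
    """A generated dimer plus its exact planted ground truth."""

    conformation: DimerConformation
    sequences: SequencePair
    spec: InterfaceSpec
    planted_contacts: tuple[tuple[int, int, str], ...]  # (res_a, res_b, kind)


def _helix_calpha(n_res: int, x_axis: float, z0: float = 0.0) -> np.ndarray:
    k = np.arange(n_res)
    ang = np.deg2rad(_HELIX_TURN_DEG) * k
    return np.column_stack([x_axis + _HELIX_RADIUS * np.cos(ang),
                            _HELIX_RADIUS * np.sin(ang),
                            z0 + _HELIX_RISE * k])


def make_toy_dimer(n_res_per_monomer: int, spec: InterfaceSpec,
                   box_side: float = 120.0) -> ToyDimer:
    """Build a two-chain toy dimer with an exactly controlled interface."""
    if n_res_per_monomer < 10:
        raise ValueError("need at least 10 residues per monomer")
    rng = np.random.default_rng(spec.seed)

    kinds = (["hydrophobic"] * spec.n_hydrophobic_pairs
             + ["ionic"] * spec.n_ionic_pairs
             + ["hbond"] * spec.n_hbond_pairs)
    slot_residues = _slot_residues(n_res_per_monomer, len(kinds))

    gap = _INTERFACE_GAP
    ca_a = _helix_calpha(n_res_per_monomer, -gap / 2.0)
    ca_b = _helix_calpha(n_res_per_monomer, +gap / 2.0)
    # centre the complex in the box
    centre = np.array([box_side / 2.0] * 3)
    shift = centre - (ca_a.mean(axis=0) + ca_b.mean(axis=0)) / 2.0
    ca_a += shift
    ca_b += shift
    mid_x = (ca_a[:, 0].mean() + ca_b[:, 0].mean()) / 2.0

    seq = [list(rng.choice(list(_AA20), size=n_res_per_monomer)) for _ in range(2)]
    extra_a: dict[int, AtomRecord] = {}
    extra_b: dict[int, AtomRecord] = {}
    planted = []
    for kind, res_1b in zip(kinds, slot_residues):
        aa_a, name_a, elem_a, aa_b, name_b, elem_b, dist = _PLANT[kind]
        i = res_1b - 1
        seq[0][i] = aa_a
        seq[1][i] = aa_b
        z = ca_a[i, 2]
        y = 0.0 + shift[1]
        extra_a[res_1b] = AtomRecord(name=name_a, element=elem_a,
                                     coords=np.array([mid_x - dist / 2.0, y, z]))
        extra_b[res_1b] = AtomRecord(name=name_b, element=elem_b,
                                     coords=np.array([mid_x + dist / 2.0, y, z]))
        planted.append((res_1b, res_1b, kind))

    def build(chain_id, ca, seq_list, extras):
        residues = []
        for i in range(n_res_per_monomer):
            atoms = [AtomRecord(name="CA", element="C", coords=ca[i])]
            if (i + 1) in extras:
                atoms.append(extras[i + 1])
            residues.append(ResidueRecord(index=i + 1, aa=seq_list[i], atoms=tuple(atoms)))
        return MonomerStructure(chain_id=chain_id, residues=tuple(residues))

    mon_a = build("A", ca_a, seq[0], extra_a)
    mon_b = build("B", ca_b, seq[1], extra_b)
    conf = DimerConformation(monomer_a=mon_a, monomer_b=mon_b,
                             box_side=box_side, periodic=True)
    pair = SequencePair(id_a="toy_A", id_b="toy_B",
                        seq_a="".join(seq[0]), seq_b="".join(seq[1]))
    return ToyDimer(conformation=conf, sequences=pair, spec=spec,
                    planted_contacts=tuple(planted))


def make_dimer_series(base_spec: InterfaceSpec, strengths: tuple[float, ...],
                      n_res_per_monomer: int = 16,
                      mode: str = "depth") -> list[ToyDimer]:
    """Dimers identical up to interface strength.

    ``mode='depth'`` scales the native-contact well depths (geometry and
    contact counts identical across the series); ``mode='count'`` scales the
    planted pair counts instead. Strengths must be strictly increasing.
    """
    if len(strengths) < 2 and len(strengths) != 1:
        raise ValueError("need at least one strength")
    if any(b <= a for a, b in zip(strengths, strengths[1:])):
        raise ValueError("strengths must be strictly increasing")
    out = []
    for s in strengths:
        if mode == "depth":
            spec = InterfaceSpec(
                n_hydrophobic_pairs=base_spec.n_hydrophobic_pairs,
                n_ionic_pairs=base_spec.n_ionic_pairs,
                n_hbond_pairs=base_spec.n_hbond_pairs,
                well_depth_scale=base_spec.well_depth_scale * s,
                seed=base_spec.seed)
        elif mode == "count":
            spec = InterfaceSpec(
                n_hydrophobic_pairs=max(1, round(base_spec.n_hydrophobic_pairs * s)),
                n_ionic_pairs=round(base_spec.n_ionic_pairs * s),
                n_hbond_pairs=round(base_spec.n_hbond_pairs * s),
                well_depth_scale=base_spec.well_depth_scale,
                seed=base_spec.seed)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        out.append(make_toy_dimer(n_res_per_monomer, spec))
    return out


def perturb_ensemble(conf: DimerConformation, amplitude: float,
                     n_snapshots: int, seed: int = 0) -> list[DimerConformation]:
    """I.i.d. Gaussian coordinate perturbations of one conformation.

    Amplitude is the per-coordinate standard deviation in Å; amplitude 0
    returns identical copies.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_snapshots):
        mons = []
        for mon in conf.monomers:
            coords = np.array([a.coords for r in mon.residues for a in r.atoms])
            noise = rng.normal(0.0, amplitude, size=coords.shape) if amplitude > 0 else 0.0
            mons.append(mon.with_coords(coords + noise))
        out.append(DimerConformation(monomer_a=mons[0], monomer_b=mons[1],
                                     box_side=conf.box_side, periodic=conf.periodic))
    return out


def make_sequence_pair(length: int, n_subs: int, seed: int = 0
                       ) -> tuple[SequencePair, tuple[int, ...]]:
    """A random protein sequence and a copy with planted substitutions.

    Returns the pair and the sorted 1-based planted positions.
    """
    if not 0 <= n_subs <= length:
        raise ValueError("n_subs must be in [0, length]")
    rng = np.random.default_rng(seed)
    seq_a = rng.choice(list(_AA20), size=length)
    seq_b = seq_a.copy()
    positions = np.sort(rng.choice(length, size=n_subs, replace=False))
    for p in positions:
        alternatives = [aa for aa in _AA20 if aa != seq_a[p]]
        seq_b[p] = alternatives[rng.integers(len(alternatives))]
    pair = SequencePair(id_a="synthetic_a", id_b="synthetic_b",
                        seq_a="".join(seq_a), seq_b="".join(seq_b))
    return pair, tuple(int(p) + 1 for p in positions)


def reference_sequence_pair() -> tuple[SequencePair, tuple[int, ...]]:
    """Synthetic stand-in for the two full-length PgiC alleles.

    A deterministic 567-residue pair differing exactly at the 20 published
    variable positions (the real GenBank records are not bundled; this
    stand-in reproduces their length and difference pattern only). At the
    two interface positions 466 and 521 the second sequence carries a
    charged residue while the first does not, mirroring the reported
    chemistry of those sites.
    """
    rng = np.random.default_rng(567)
    seq_a = rng.choice(list(_AA20), size=PGIC_FULL_LENGTH)
    seq_b = seq_a.copy()
    for p in PGIC_VARIABLE_POSITIONS:
        i = p - 1
        if p in (466, 521):
            seq_a[i] = "S"
            seq_b[i] = "K" if p == 466 else "E"
        else:
            alternatives = [aa for aa in _AA20 if aa != seq_a[i]]
            seq_b[i] = alternatives[rng.integers(len(alternatives))]
    pair = SequencePair(id_a="PgiC1_synthetic", id_b="PgiC2_synthetic",
                        seq_a="".join(seq_a), seq_b="".join(seq_b))
    return pair, PGIC_VARIABLE_POSITIONS


# --- backbone geometry builders (for secondary-structure inputs) ------------

_BOND_CN = 1.329
_BOND_NCA = 1.458
_BOND_CAC = 1.525
_BOND_CO = 1.231
_ANGLE_CACN = 116.2
_ANGLE_CNCA = 121.7
_ANGLE_NCAC = 111.2


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF: position a new atom from three predecessors and internal coords."""
    theta = math.radians(angle_deg)
    chi = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * math.cos(theta),
                  bond * math.sin(theta) * math.cos(chi),
                  bond * math.sin(theta) * math.sin(chi)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_backbone_chain(n_res: int, phi: float, psi: float,
                         chain_id: str = "A", aa: str = "A") -> MonomerStructure:
    """Poly-residue chain with ideal geometry at fixed (φ, ψ), ω = 180°.

    Returns a monomer with full N, CA, C, O backbones (no side chains),
    suitable as input to the secondary-structure assignment. φ = −57°,
    ψ = −47° gives an ideal α-helix; φ = −139°, ψ = 135° an extended strand.
    """
    if n_res < 2:
        raise ValueError("need at least 2 residues")
    n_atoms = [np.array([0.0, 0.0, 0.0])]
    ca_atoms = [np.array([_BOND_NCA, 0.0, 0.0])]
    theta = math.radians(_ANGLE_NCAC)
    c_atoms = [ca_atoms[0] + _BOND_CAC * np.array([-math.cos(theta), math.sin(theta), 0.0])]
    for i in range(1, n_res):
        n_next = _place(n_atoms[-1], ca_atoms[-1], c_atoms[-1], _BOND_CN, _ANGLE_CACN, psi)
        ca_next = _place(ca_atoms[-1], c_atoms[-1], n_next, _BOND_NCA, _ANGLE_CNCA, 180.0)
        c_next = _place(c_atoms[-1], n_next, ca_next, _BOND_CAC, _ANGLE_NCAC, phi)
        n_atoms.append(n_next)
        ca_atoms.append(ca_next)
        c_atoms.append(c_next)
    residues = []
    for i in range(n_res):
        if i + 1 < n_res:
            n_ref = n_atoms[i + 1]
        else:  # virtual next N for the carbonyl of the final residue
            n_ref = _place(n_atoms[i], ca_atoms[i], c_atoms[i], _BOND_CN, _ANGLE_CACN, psi)
        d1 = c_atoms[i] - n_ref
        d2 = c_atoms[i] - ca_atoms[i]
        d = d1 / np.linalg.norm(d1) + d2 / np.linalg.norm(d2)
        o = c_atoms[i] + _BOND_CO * d / np.linalg.norm(d)
        atoms = (AtomRecord("N", "N", n_atoms[i]), AtomRecord("CA", "C", ca_atoms[i]),
                 AtomRecord("C", "C", c_atoms[i]), AtomRecord("O", "O", o))
        residues.append(ResidueRecord(index=i + 1, aa=aa, atoms=atoms))
    return MonomerStructure(chain_id=chain_id, residues=tuple(residues))


def build_antiparallel_sheet(n_per_strand: int = 6, chain_id: str = "A"
                             ) -> MonomerStructure:
    """Two idealized antiparallel strands as one monomer (a flat H-bond ladder).

    Residues 1..n form the first strand, n+1..2n the second, with paired
    residues mutually hydrogen bonded (CO_i···HN_j and CO_j···HN_i). The
    strand-to-strand linkage is geometric only; the builder exists to give
    the bridge-pattern detector a clean, known-answer input.
    """
    n = n_per_strand
    residues = []
    for i in range(1, n + 1):
        x = 3.4 * i
        atoms = (
            AtomRecord("N", "N", np.array([x - 1.2, 0.2, 0.0])),
            AtomRecord("H", "H", np.array([x - 1.2, 1.2, 0.0])),
            AtomRecord("CA", "C", np.array([x, 0.0, 0.0])),
            AtomRecord("C", "C", np.array([x + 1.0, 0.3, 0.0])),
            AtomRecord("O", "O", np.array([x + 1.0, 1.53, 0.0])),
        )
        residues.append(ResidueRecord(index=i, aa="V", atoms=atoms))
    for j in range(n + 1, 2 * n + 1):
        i_pair = 2 * n + 1 - j
        x = 3.4 * i_pair
        atoms = (
            AtomRecord("N", "N", np.array([x + 1.0, 4.43, 0.0])),
            AtomRecord("H", "H", np.array([x + 1.0, 3.43, 0.0])),
            AtomRecord("CA", "C", np.array([x, 4.63, 0.0])),
            AtomRecord("C", "C", np.array([x - 1.2, 4.33, 0.0])),
            AtomRecord("O", "O", np.array([x - 1.2, 3.10, 0.0])),
        )
        residues.append(ResidueRecord(index=j, aa="V", atoms=atoms))
    return MonomerStructure(chain_id=chain_id, residues=tuple(residues))
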