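"""Inter-monomer interface analytics.

Per-conformation quantities: heavy-atom residue-pair contacts (5.5 Å rule),
geometrically typed interactions (hydrogen bond, hydrophobic, ionic,
cation–π), the contact-based binding-affinity estimate, and the
per-position decomposition of typed-interaction differences between two
dimers. Ensemble averaging preserves the run structure: standard errors are
taken over independent-run means, because snapshots within a run are
autocorrelated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from . import constants as C
from .sasa import sasa
from .secondary import secondary_structure
from .structure import DimerConformation, MonomerStructure, classify_residue

__all__ = [
    "ContactPair",
    "TypedInteraction",
    "InterfaceProfile",
    "PositionContribution",
    "inter_monomer_contacts",
    "count_contacts",
    "classify_interactions",
    "binding_affinity",
    "interface_profile",
    "position_decomposition",
    "ensemble_average",
    "METRICS",
]

INTERACTION_TYPES = ("hbond", "hydrophobic", "ionic", "cation_pi")

# --- atom chemistry ---------------------------------------------------------

_POSITIVE_ATOMS = {
    "K": {"NZ"}, "R": {"NE", "NH1", "NH2"}, "H": {"ND1", "NE2"},
}
_NEGATIVE_ATOMS = {
    "D": {"OD1", "OD2"}, "E": {"OE1", "OE2"},
}
_SC_DONORS = {
    "R": {"NE", "NH1", "NH2"}, "N": {"ND2"}, "Q": {"NE2"}, "H": {"ND1", "NE2"},
    "K": {"NZ"}, "S": {"OG"}, "T": {"OG1"}, "W": {"NE1"}, "Y": {"OH"},
}
_SC_ACCEPTORS = {
    "D": {"OD1", "OD2"}, "E": {"OE1", "OE2"}, "N": {"OD1"}, "Q": {"OE1"},
    "H": {"ND1", "NE2"}, "S": {"OG"}, "T": {"OG1"}, "Y": {"OH"},
}
_AROMATIC_RING = {
    "F": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "Y": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "W": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "H": ("CG", "ND1", "CD2", "CE1", "NE2"),
}
_BACKBONE = {"N", "CA", "C", "O"}


@dataclass(frozen=True)
class ContactPair:
    """A residue pair with at least one heavy-atom pair within the cutoff."""

    res_a: int
    res_b: int
    min_dist: float


@dataclass(frozen=True)
class TypedInteraction:
    """One typed inter-monomer interaction between residues res_a and res_b."""

    kind: str
    res_a: int
    res_b: int


@dataclass(frozen=True)
class InterfaceProfile:
    """Interface summary of one conformation."""

    n_c: int
    typed_counts: dict
    class_counts: dict
    nis_apolar: float   # % of non-interacting surface residues that are apolar
    nis_charged: float  # % charged
    dG: float           # kcal/mol


@dataclass(frozen=True)
class PositionContribution:
    position: int
    typed_deltas: dict


# --- contacts ---------------------------------------------------------------

def _heavy_atom_table(mon: MonomerStructure):
    """(coords, residue position per atom) for all heavy atoms of a monomer."""
    coords, res_pos = [], []
    for r in mon.residues:
        for a in r.atoms:
            if a.is_heavy:
                coords.append(a.coords)
                res_pos.append(r.index)
    return np.array(coords) if coords else np.empty((0, 3)), np.array(res_pos, dtype=int)


def inter_monomer_contacts(conf: DimerConformation,
                           cutoff: float = C.CONTACT_CUTOFF) -> list[ContactPair]:
    """Residue pairs across the interface with any heavy-atom pair < cutoff.

    Uses a k-d tree neighbour query over heavy atoms; ``min_dist`` is the
    minimum heavy-atom distance for the pair. Intra-monomer pairs are never
    included.
    """
    xa, ra = _heavy_atom_table(conf.monomer_a)
    xb, rb = _heavy_atom_table(conf.monomer_b)
    if len(xa) == 0 or len(xb) == 0:
        return []
    pairs = cKDTree(xa).query_ball_tree(cKDTree(xb), r=cutoff)
    best: dict[tuple[int, int], float] = {}
    for i, js in enumerate(pairs):
        for j in js:
            d = float(np.linalg.norm(xa[i] - xb[j]))
            if d <= cutoff:
                key = (int(ra[i]), int(rb[j]))
                if d < best.get(key, math.inf):
                    best[key] = d
    return [ContactPair(res_a=a, res_b=b, min_dist=d)
            for (a, b), d in sorted(best.items())]


def count_contacts(conf: DimerConformation, cutoff: float = C.CONTACT_CUTOFF) -> int:
    """n_c: number of distinct inter-monomer residue-pair contacts."""
    return len(inter_monomer_contacts(conf, cutoff))


# --- typed interactions -----------------------------------------------------

def _collect(mon: MonomerStructure, table: dict) -> list[tuple[int, str, np.ndarray]]:
    out = []
    for r in mon.residues:
        names = table.get(r.aa.upper())
        if not names:
            continue
        for a in r.atoms:
            if a.name in names:
                out.append((r.index, a.name, a.coords))
    return out


def _apolar_carbons(mon: MonomerStructure) -> list[tuple[int, np.ndarray]]:
    out = []
    for r in mon.residues:
        if classify_residue(r.aa) != "apolar":
            continue
        for a in r.atoms:
            if a.element.upper() == "C" and a.name not in _BACKBONE:
                out.append((r.index, a.coords))
    return out


def _backbone_polar(mon: MonomerStructure, kind: str) -> list[tuple[int, str, np.ndarray]]:
    name = "N" if kind == "donor" else "O"
    out = []
    for r in mon.residues:
        for a in r.atoms:
            if a.name == name:
                out.append((r.index, name, a.coords))
    return out


def _rings(mon: MonomerStructure) -> list[tuple[int, np.ndarray, np.ndarray]]:
    """(residue, centroid, unit normal) for each aromatic ring present."""
    out = []
    for r in mon.residues:
        names = _AROMATIC_RING.get(r.aa.upper())
        if not names:
            continue
        pts = np.array([a.coords for a in r.atoms if a.name in names])
        if len(pts) < 3:
            continue
        centroid = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - centroid)
        out.append((r.index, centroid, vt[2]))
    return out


def classify_interactions(conf: DimerConformation, cutoffs: dict | None = None,
                          detail: bool = False):
    """Count typed inter-monomer interactions by geometric rules.

    Rules (all cutoffs configurable): hydrogen bond = donor/acceptor
    heavy-atom pair ≤ 3.5 Å (angle criterion applies only when explicit
    hydrogens exist); ionic = opposite-charge side-chain N/O pair ≤ 4.0 Å,
    counted once per residue pair and excluded from the hydrogen-bond count;
    hydrophobic = apolar side-chain carbon pair ≤ 5.0 Å, counted at the
    residue-pair level; cation–π = cationic nitrogen within 6.0 Å of an
    aromatic ring centroid with ring-normal offset angle ≤ 60°.
    """
    cut = {
        "hbond": C.HBOND_CUTOFF, "ionic": C.IONIC_CUTOFF,
        "hydrophobic": C.HYDROPHOBIC_CUTOFF, "cation_pi": C.CATION_PI_CUTOFF,
        "cation_pi_angle": C.CATION_PI_ANGLE_MAX_DEG,
    }
    if cutoffs:
        cut.update(cutoffs)
    mons = conf.monomers
    interactions: list[TypedInteraction] = []

    # ionic: opposite-charge side-chain groups, residue-pair granularity
    ionic_pairs: set[tuple[int, int]] = set()
    ionic_atom_pairs: set[tuple[int, str, int, str]] = set()
    for pos_table, neg_table, flip in (
            (_collect(mons[0], _POSITIVE_ATOMS), _collect(mons[1], _NEGATIVE_ATOMS), False),
            (_collect(mons[1], _POSITIVE_ATOMS), _collect(mons[0], _NEGATIVE_ATOMS), True)):
        for ri, ni, xi in pos_table:
            for rj, nj, xj in neg_table:
                if np.linalg.norm(xi - xj) <= cut["ionic"]:
                    pair = (rj, ri) if flip else (ri, rj)
                    ionic_pairs.add(pair)
                    ap = (pair[0], nj if flip else ni, pair[1], ni if flip else nj)
                    ionic_atom_pairs.add(ap)
    for a, b in sorted(ionic_pairs):
        interactions.append(TypedInteraction("ionic", a, b))

    # hydrogen bonds: donor/acceptor heavy atoms, atom-pair granularity;
    # salt-bridge atom pairs already counted as ionic are excluded
    donors_a = _collect(mons[0], _SC_DONORS) + _backbone_polar(mons[0], "donor")
    donors_b = _collect(mons[1], _SC_DONORS) + _backbone_polar(mons[1], "donor")
    acc_a = _collect(mons[0], _SC_ACCEPTORS) + _backbone_polar(mons[0], "acceptor")
    acc_b = _collect(mons[1], _SC_ACCEPTORS) + _backbone_polar(mons[1], "acceptor")
    cation_atoms = {(i, n) for i, n, _ in _collect(mons[0], _POSITIVE_ATOMS)} | \
                   {(i, n) for i, n, _ in _collect(mons[1], _POSITIVE_ATOMS)}
    anion_atoms = {(i, n) for i, n, _ in _collect(mons[0], _NEGATIVE_ATOMS)} | \
                  {(i, n) for i, n, _ in _collect(mons[1], _NEGATIVE_ATOMS)}
    seen_hb: set[tuple[int, str, int, str]] = set()
    for donors, acceptors, flip in ((donors_a, acc_b, False), (donors_b, acc_a, True)):
        for ri, ni, xi in donors:
            for rj, nj, xj in acceptors:
                if np.linalg.norm(xi - xj) > cut["hbond"]:
                    continue
                if (ri, ni) in cation_atoms and (rj, nj) in anion_atoms:
                    continue  # salt bridge, counted as ionic
                key = (rj, nj, ri, ni) if flip else (ri, ni, rj, nj)
                # donor->acceptor and acceptor->donor of the same O...O pair
                sym = (key[2], key[3], key[0], key[1])
                if key in seen_hb or sym in seen_hb:
                    continue
                seen_hb.add(key)
                interactions.append(TypedInteraction("hbond", key[0], key[2]))

    # hydrophobic: apolar side-chain carbon pairs, residue-pair granularity
    phobic_pairs: set[tuple[int, int]] = set()
    ca_list = _apolar_carbons(mons[0])
    cb_list = _apolar_carbons(mons[1])
    for ri, xi in ca_list:
        for rj, xj in cb_list:
            if np.linalg.norm(xi - xj) <= cut["hydrophobic"]:
                phobic_pairs.add((ri, rj))
    for a, b in sorted(phobic_pairs):
        interactions.append(TypedInteraction("hydrophobic", a, b))

    # cation-pi
    cpi_pairs: set[tuple[int, int]] = set()
    for cations, rings, flip in (
            (_collect(mons[0], _POSITIVE_ATOMS), _rings(mons[1]), False),
            (_collect(mons[1], _POSITIVE_ATOMS), _rings(mons[0]), True)):
        for ri, _, xi in cations:
            for rj, centroid, normal in rings:
                v = xi - centroid
                d = np.linalg.norm(v)
                if d > cut["cation_pi"] or d < 1e-9:
                    continue
                angle = math.degrees(math.acos(min(1.0, abs(float(v @ normal)) / d)))
                if angle <= cut["cation_pi_angle"]:
                    cpi_pairs.add((rj, ri) if flip else (ri, rj))
    for a, b in sorted(cpi_pairs):
        interactions.append(TypedInteraction("cation_pi", a, b))

    counts = {k: sum(1 for t in interactions if t.kind == k) for k in INTERACTION_TYPES}
    if detail:
        return counts, interactions
    return counts


# --- contact-based binding affinity -----------------------------------------

_CLASS_KEY = {"charged": "c", "polar": "p", "apolar": "a"}


def _class_pair_key(aa_a: str, aa_b: str) -> str:
    k = sorted((_CLASS_KEY[classify_residue(aa_a)], _CLASS_KEY[classify_residue(aa_b)]))
    return "".join(k) if k[0] != k[1] else k[0] * 2


def class_contact_counts(conf: DimerConformation,
                         cutoff: float = C.CONTACT_CUTOFF) -> dict:
    """Interface contact counts by residue-class pair {cc, cp, ca, pp, pa, aa}."""
    aa_of_a = {r.index: r.aa for r in conf.monomer_a.residues}
    aa_of_b = {r.index: r.aa for r in conf.monomer_b.residues}
    counts = {k: 0 for k in ("cc", "cp", "ca", "pp", "pa", "aa")}
    for c in inter_monomer_contacts(conf, cutoff):
        counts[_class_pair_key(aa_of_a[c.res_a], aa_of_b[c.res_b])] += 1
    return counts


def nis_percentages(conf: DimerConformation, contacts=None,
                    rel_threshold: float = C.NIS_REL_SASA_THRESHOLD) -> tuple[float, float]:
    """(%apolar, %charged) among non-interacting surface residues.

    Surface = relative SASA (per-residue SASA in the complex over the
    residue's theoretical maximum) above the threshold; non-interacting =
    surface residues not in any interface contact.
    """
    if contacts is None:
        contacts = inter_monomer_contacts(conf)
    interface_a = {c.res_a for c in contacts}
    interface_b = {c.res_b for c in contacts}
    res_sasa = sasa(conf).per_residue
    classes = []
    k = 0
    for mon, iface in ((conf.monomer_a, interface_a), (conf.monomer_b, interface_b)):
        for r in mon.residues:
            rel = res_sasa[k] / C.MAX_ASA[r.aa.upper()]
            if rel > rel_threshold and r.index not in iface:
                classes.append(classify_residue(r.aa))
            k += 1
    if not classes:
        return 0.0, 0.0
    n = len(classes)
    return (100.0 * classes.count("apolar") / n, 100.0 * classes.count("charged") / n)


def affinity_from_profile(class_counts: dict, nis_apolar: float, nis_charged: float,
                          coeffs: dict | None = None) -> float:
    """Evaluate the linear contact-based affinity model (kcal/mol)."""
    w = C.AFFINITY_COEFFS if coeffs is None else coeffs
    dg = w["intercept"]
    for key, count in class_counts.items():
        dg += w.get(key, 0.0) * count
    dg += w["nis_apolar"] * nis_apolar + w["nis_charged"] * nis_charged
    return float(dg)


def binding_affinity(conf: DimerConformation, coeffs: dict | None = None) -> float:
    """Contact-based binding-affinity estimate ΔG for one conformation."""
    counts = class_contact_counts(conf)
    nis_a, nis_c = nis_percentages(conf)
    return affinity_from_profile(counts, nis_a, nis_c, coeffs)


def interface_profile(conf: DimerConformation) -> InterfaceProfile:
    """Full interface summary: n_c, typed counts, class counts, NIS, ΔG."""
    contacts = inter_monomer_contacts(conf)
    typed = classify_interactions(conf)
    class_counts = class_contact_counts(conf)
    nis_a, nis_c = nis_percentages(conf, contacts=contacts)
    dg = affinity_from_profile(class_counts, nis_a, nis_c)
    return InterfaceProfile(n_c=len(contacts), typed_counts=typed,
                            class_counts=class_counts, nis_apolar=nis_a,
                            nis_charged=nis_c, dG=dg)


# --- per-position decomposition ---------------------------------------------

def position_decomposition(interactions_x: Sequence[TypedInteraction],
                           interactions_y: Sequence[TypedInteraction],
                           positions: set[int]) -> dict:
    """Decompose typed-interaction count differences between two dimers.

    For each interaction type: ``total`` = count_x − count_y; ``subset`` =
    the same restricted to interactions with at least one member in
    ``positions``; ``per_position`` = one delta per position (an interaction
    joining two set members contributes to both, so the per-position sum can
    double-count; the overlap is reported as ``double_counted``).
    """
    def count(items, kind, pred):
        return sum(1 for t in items if t.kind == kind and pred(t))

    out = {}
    for kind in INTERACTION_TYPES:
        total = count(interactions_x, kind, lambda t: True) - \
                count(interactions_y, kind, lambda t: True)
        in_set = lambda t: t.res_a in positions or t.res_b in positions
        subset = count(interactions_x, kind, in_set) - count(interactions_y, kind, in_set)
        per_position = []
        for p in sorted(positions):
            at_p = lambda t, p=p: t.res_a == p or t.res_b == p
            per_position.append(PositionContribution(
                position=p,
                typed_deltas={kind: count(interactions_x, kind, at_p)
                              - count(interactions_y, kind, at_p)}))
        both = lambda t: t.res_a in positions and t.res_b in positions
        double = count(interactions_x, kind, both) - count(interactions_y, kind, both)
        out[kind] = {"total": total, "subset": subset,
                     "per_position": per_position, "double_counted": double}
    return out


# --- ensemble averaging -----------------------------------------------------

def _helix_frac(conf: DimerConformation) -> float:
    profs = [secondary_structure(m) for m in conf.monomers]
    n = sum(len(m) for m in conf.monomers)
    return sum(p.helix_frac * len(m) for p, m in zip(profs, conf.monomers)) / n


def _strand_frac(conf: DimerConformation) -> float:
    profs = [secondary_structure(m) for m in conf.monomers]
    n = sum(len(m) for m in conf.monomers)
    return sum(p.strand_frac * len(m) for p, m in zip(profs, conf.monomers)) / n


METRICS: dict[str, Callable[[DimerConformation], float]] = {
    "n_c": lambda c: float(count_contacts(c)),
    "dG": binding_affinity,
    "sasa_total": lambda c: sasa(c).total,
    "sasa_apolar": lambda c: sasa(c).apolar,
    "helix_frac": _helix_frac,
    "strand_frac": _strand_frac,
    "hbond": lambda c: float(classify_interactions(c)["hbond"]),
    "hydrophobic": lambda c: float(classify_interactions(c)["hydrophobic"]),
    "ionic": lambda c: float(classify_interactions(c)["ionic"]),
    "cation_pi": lambda c: float(classify_interactions(c)["cation_pi"]),
}


@dataclass(frozen=True)
class EnsembleAverage:
    mean: float
    se: float | None          # over run means; None if a single run
    run_means: tuple[float, ...]
    values: tuple[tuple[float, ...], ...]  # per run, per snapshot


def ensemble_average(runs: Sequence[Sequence[DimerConformation]],
                     metric: str | Callable[[DimerConformation], float]) -> EnsembleAverage:
    """Evaluate a metric conformation by conformation and average over runs.

    ``runs`` is a list of runs, each a list of snapshots (a flat snapshot
    list is treated as a single run). The across-run mean and the standard
    error over run means are reported; SE is None when only one run is given.
    """
    if callable(metric):
        fn = metric
    else:
        if metric not in METRICS:
            raise KeyError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
        fn = METRICS[metric]
    if runs and isinstance(runs[0], DimerConformation):
        runs = [runs]
    if not runs or not runs[0]:
        raise ValueError("need at least one snapshot")
    values = tuple(tuple(float(fn(conf)) for conf in run) for run in runs)
    run_means = tuple(float(np.mean(v)) for v in values)
    mean = float(np.mean(run_means))
    se = (float(np.std(run_means, ddof=1) / math.sqrt(len(run_means)))
          if len(run_means) > 1 else None)
    return EnsembleAverage(mean=mean, se=se, run_means=run_means, values=values)
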