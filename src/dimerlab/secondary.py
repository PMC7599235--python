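"""Secondary-structure assignment from backbone hydrogen bonding.

A simplified DSSP-style assignment: backbone CO···HN hydrogen bonds are
detected with the Kabsch–Sander electrostatic energy (partial charges on
C,O and N,H; bond if E < −0.5 kcal/mol). α- and 3₁₀-helices come from
consecutive i→i+4 / i→i+3 turn patterns, strands from parallel and
antiparallel bridge patterns, isolated turns are labelled T and everything
else coil. Amide hydrogens, when absent, are reconstructed from the
backbone geometry. Labels: H, G, E, T, C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import MonomerStructure

__all__ = ["SsProfile", "secondary_structure", "kabsch_sander_hbonds"]

#: Kabsch–Sander coupling constant, kcal/mol·Å (q1*q2*332)
_KS_FACTOR = 0.084 * 332.0
_KS_THRESHOLD = -0.5
#: Labels counted as helix / strand in the fraction summaries (config keys).
HELIX_LABELS = ("H", "G")
STRAND_LABELS = ("E",)


@dataclass(frozen=True)
class SsProfile:
    """Per-residue labels plus helix/strand fractions."""

    labels: tuple[str, ...]
    helix_frac: float
    strand_frac: float


def _backbone_arrays(mon: MonomerStructure):
    """Per-residue N, CA, C, O coordinates (NaN where missing)."""
    n = len(mon.residues)
    out = {name: np.full((n, 3), np.nan) for name in ("N", "CA", "C", "O", "H")}
    for i, res in enumerate(mon.residues):
        for a in res.atoms:
            if a.name in out:
                out[a.name][i] = a.coords
    return out


def _place_amide_h(bb: dict) -> np.ndarray:
    """Estimate missing amide H: 1.01 Å from N along the NH bisector direction."""
    n = len(bb["N"])
    h = bb["H"].copy()
    for i in range(1, n):
        if np.all(np.isfinite(h[i])):
            continue
        if not (np.all(np.isfinite(bb["N"][i])) and np.all(np.isfinite(bb["C"][i - 1]))
                and np.all(np.isfinite(bb["CA"][i]))):
            continue
        d1 = bb["N"][i] - bb["C"][i - 1]
        d2 = bb["N"][i] - bb["CA"][i]
        d1 /= np.linalg.norm(d1)
        d2 /= np.linalg.norm(d2)
        direction = d1 + d2
        norm = np.linalg.norm(direction)
        if norm > 1e-8:
            h[i] = bb["N"][i] + 1.01 * direction / norm
    return h


def kabsch_sander_hbonds(mon: MonomerStructure) -> np.ndarray:
    """Boolean matrix hb[i, j]: CO of residue i bonds NH of residue j."""
    bb = _backbone_arrays(mon)
    h = _place_amide_h(bb)
    n = len(mon.residues)
    hb = np.zeros((n, n), dtype=bool)
    for i in range(n):
        c, o = bb["C"][i], bb["O"][i]
        if not (np.all(np.isfinite(c)) and np.all(np.isfinite(o))):
            continue
        for j in range(n):
            if abs(i - j) < 2:
                continue
            nn, hh = bb["N"][j], h[j]
            if not (np.all(np.isfinite(nn)) and np.all(np.isfinite(hh))):
                continue
            r_on = np.linalg.norm(o - nn)
            if r_on > 5.2:  # beyond any plausible bond; saves the 1/r terms
                continue
            energy = _KS_FACTOR * (1.0 / r_on
                                   + 1.0 / np.linalg.norm(c - hh)
                                   - 1.0 / np.linalg.norm(o - hh)
                                   - 1.0 / np.linalg.norm(c - nn))
            if energy < _KS_THRESHOLD:
                hb[i, j] = True
    return hb


def secondary_structure(mon: MonomerStructure) -> SsProfile:
    """Assign per-residue secondary structure labels {H, G, E, T, C}."""
    n = len(mon.residues)
    hb = kabsch_sander_hbonds(mon)
    labels = np.array(["C"] * n, dtype="<U1")

    turn4 = np.array([i + 4 < n and hb[i, i + 4] for i in range(n)])
    turn3 = np.array([i + 3 < n and hb[i, i + 3] for i in range(n)])

    # bridges (strand), assigned first so helix patterns may overwrite
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            parallel = (hb[i - 1, j] and hb[j, i + 1]) or (hb[j - 1, i] and hb[i, j + 1])
            antiparallel = (hb[i, j] and hb[j, i]) or (hb[i - 1, j + 1] and hb[j - 1, i + 1])
            if parallel or antiparallel:
                labels[i] = "E"
                labels[j] = "E"

    # isolated turns
    for i in range(n):
        if turn4[i]:
            for k in range(i + 1, min(i + 4, n)):
                if labels[k] == "C":
                    labels[k] = "T"

    # 3-10 helix: two consecutive i->i+3 turns
    for i in range(n - 4):
        if turn3[i] and turn3[i + 1]:
            for k in range(i + 1, i + 4):
                labels[k] = "G"

    # alpha helix: two consecutive i->i+4 turns (takes precedence)
    for i in range(n - 5):
        if turn4[i] and turn4[i + 1]:
            for k in range(i + 1, i + 5):
                labels[k] = "H"

    labels_t = tuple(labels.tolist())
    helix = sum(labels.tolist().count(s) for s in HELIX_LABELS) / n
    strand = sum(labels.tolist().count(s) for s in STRAND_LABELS) / n
    return SsProfile(labels=labels_t, helix_frac=helix, strand_frac=strand)
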