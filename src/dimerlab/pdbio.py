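"""PDB and FASTA input/output.

The PDB dialect is deliberately strict so that write→read round-trips are
bit-exact at PDB precision: only ATOM/TER/END records are emitted, altloc
codes other than blank/'A' are rejected on read, and HETATM records are
skipped with a logged count. Parse errors name the offending line.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .constants import THREE_TO_ONE, ONE_TO_THREE
from .structure import AtomRecord, DimerConformation, MonomerStructure, ResidueRecord

__all__ = ["read_dimer_pdb", "write_dimer_pdb", "read_fasta"]

logger = logging.getLogger(__name__)


def _guess_element(name: str) -> str:
    stripped = name.strip()
    if stripped[:1].isdigit():  # e.g. 1H, 2HB
        return "H"
    if len(stripped) >= 2 and stripped[:2].upper() in ("SE",):
        return "SE"
    return stripped[:1].upper()


def _parse_atom_line(line: str, lineno: int):
    try:
        serial = line[6:11]
        name = line[12:16].strip()
        altloc = line[16]
        resname = line[17:20].strip()
        chain = line[21]
        resseq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise ValueError(f"malformed ATOM record at line {lineno}: {line.rstrip()!r}") from exc
    del serial
    if altloc not in (" ", "A"):
        raise ValueError(f"unsupported altloc {altloc!r} at line {lineno}")
    if not element:
        element = _guess_element(name)
    return name, resname, chain, resseq, np.array([x, y, z]), element


def read_dimer_pdb(path: str | Path, chain_a: str = "A", chain_b: str = "B",
                   box_side: float = 120.0, periodic: bool = True) -> DimerConformation:
    """Read a two-chain dimer from a PDB file.

    Hydrogens are retained (flagged non-heavy); HETATM records are skipped
    with a logged count; residue numbering is taken from the file.
    """
    path = Path(path)
    per_chain: dict[str, dict[int, tuple[str, list[AtomRecord]]]] = {}
    n_hetatm = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "HETATM":
                n_hetatm += 1
                continue
            if rec != "ATOM":
                continue
            name, resname, chain, resseq, coords, element = _parse_atom_line(line, lineno)
            aa = THREE_TO_ONE.get(resname.upper())
            if aa is None:
                continue  # non-standard residue: treated like HETATM
            residues = per_chain.setdefault(chain, {})
            if resseq not in residues:
                residues[resseq] = (aa, [])
            residues[resseq][1].append(AtomRecord(name=name, element=element, coords=coords))
    if n_hetatm:
        logger.info("skipped %d HETATM records in %s", n_hetatm, path.name)

    monomers = []
    for cid in (chain_a, chain_b):
        if cid not in per_chain:
            raise ValueError(f"chain not found: {cid!r} in {path.name}")
        residues = [
            ResidueRecord(index=i, aa=aa, atoms=tuple(atoms))
            for i, (aa, atoms) in sorted(per_chain[cid].items())
        ]
        if not residues:
            raise ValueError(f"empty chain: {cid!r} has no standard residues")
        monomers.append(MonomerStructure(chain_id=cid, residues=tuple(residues)))
    return DimerConformation(monomer_a=monomers[0], monomer_b=monomers[1],
                             box_side=box_side, periodic=periodic)


def _format_atom(serial: int, atom: AtomRecord, res: ResidueRecord, chain: str) -> str:
    name = atom.name
    # standard PDB alignment: names of <4 chars start in column 14
    field = f" {name:<3s}" if len(name) < 4 else name[:4]
    resname = ONE_TO_THREE[res.aa.upper()]
    x, y, z = atom.coords
    elem = atom.element.upper()[:2].rjust(2)
    return (f"ATOM  {serial:>5d} {field}{'':1s}{resname:>3s} {chain:1s}"
            f"{res.index:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {elem}")


def write_dimer_pdb(conf: DimerConformation, path: str | Path) -> None:
    """Write a dimer as standard ATOM records with TER between chains, END last."""
    lines = []
    serial = 0
    for mon in conf.monomers:
        for res in mon.residues:
            for atom in res.atoms:
                serial += 1
                lines.append(_format_atom(serial, atom, res, mon.chain_id))
        serial += 1
        last = mon.residues[-1]
        lines.append(f"TER   {serial:>5d}      {ONE_TO_THREE[last.aa.upper()]:>3s} "
                     f"{mon.chain_id:1s}{last.index:>4d}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (multi-record) FASTA file as a list of (id, sequence) pairs."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
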