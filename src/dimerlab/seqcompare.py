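"""Pairwise comparison of equal-length protein sequences.

Identifies variable positions between two alleles of the same protein
(1-based, full-length numbering) and applies explicit segment trimming.
No alignment is performed: the sequences must already be equal-length.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "SequencePair",
    "VariantReport",
    "TrimmedSequence",
    "variable_positions",
    "trim_segment",
    "near_interface_subset",
    "write_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SequencePair:
    id_a: str
    id_b: str
    seq_a: str
    seq_b: str

    def __post_init__(self):
        object.__setattr__(self, "seq_a", self.seq_a.upper())
        object.__setattr__(self, "seq_b", self.seq_b.upper())
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(
                f"unequal lengths: {self.id_a} has {len(self.seq_a)} residues, "
                f"{self.id_b} has {len(self.seq_b)}")

    def __len__(self) -> int:
        return len(self.seq_a)


@dataclass(frozen=True)
class VariantReport:
    """Positions where the two sequences differ (1-based, ascending)."""

    substitutions: tuple[tuple[int, str, str], ...]

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(p for p, _, _ in self.substitutions)

    def __len__(self) -> int:
        return len(self.substitutions)


@dataclass(frozen=True)
class TrimmedSequence:
    """A contiguous segment with its original full-length numbering retained."""

    sequence: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive

    @property
    def positions(self) -> range:
        return range(self.start, self.end + 1)

    def __len__(self) -> int:
        return len(self.sequence)


def variable_positions(pair: SequencePair) -> VariantReport:
    """All 1-based positions where the two sequences differ.

    'X' at a position counts as a difference from any other letter and is
    logged; comparison is case-insensitive (sequences are upper-cased).
    """
    subs = []
    for i, (a, b) in enumerate(zip(pair.seq_a, pair.seq_b), start=1):
        if a != b:
            if "X" in (a, b):
                logger.warning("position %d compares an X (%s vs %s)", i, a, b)
            subs.append((i, a, b))
    return VariantReport(substitutions=tuple(subs))


def trim_segment(seq: str, start: int, end: int) -> TrimmedSequence:
    """Slice [start, end] (1-based, inclusive), keeping original numbering."""
    if not (1 <= start <= end <= len(seq)):
        raise ValueError(f"trim bounds ({start}, {end}) out of range for length {len(seq)}")
    return TrimmedSequence(sequence=seq[start - 1:end], start=start, end=end)


def near_interface_subset(report: VariantReport, interface_positions: set[int]) -> VariantReport:
    """Restrict a variant report to positions in the given interface set."""
    return VariantReport(substitutions=tuple(
        s for s in report.substitutions if s[0] in interface_positions))


def write_report(report: VariantReport, tsv_path: str | Path | None = None,
                 json_path: str | Path | None = None) -> None:
    """Write a variant report as TSV (position, aa_a, aa_b) and/or JSON."""
    if tsv_path is not None:
        lines = ["position\taa_a\taa_b"]
        lines += [f"{p}\t{a}\t{b}" for p, a, b in report.substitutions]
        Path(tsv_path).write_text("\n".join(lines) + "\n")
    if json_path is not None:
        payload = {"n_variable": len(report),
                   "substitutions": [
                       {"position": p, "aa_a": a, "aa_b": b}
                       for p, a, b in report.substitutions]}
        Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")
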