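"""Genomic intervals and small sequence utilities shared across modules.

All internal coordinates are 0-based, half-open.  Start-codon-relative
positions (used by the 5'RACE module) follow the field convention that skips
zero: -1 is the base immediately upstream of the A of ATG and +1 is the A
itself.
"""

from __future__ import annotations

from dataclasses import dataclass

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware interval on a named sequence, 0-based half-open."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def extract(self, sequence: str) -> str:
        """Sequence of this interval in strand orientation."""
        sub = sequence[self.start : self.end]
        return revcomp(sub) if self.strand == "-" else sub


def codon_relative(pos: int, start_codon_pos: int) -> int:
    """Convert a 0-based sequence position to a start-codon-relative one.

    The convention has no zero: the A of ATG is +1 and the base immediately
    upstream is -1.
    """
    delta = pos - start_codon_pos
    return delta + 1 if delta >= 0 else delta


def codon_absolute(rel: int, start_codon_pos: int) -> int:
    """Inverse of :func:`codon_relative`."""
    if rel == 0:
        raise ValueError("position 0 does not exist in start-codon-relative coordinates")
    return start_codon_pos + (rel - 1 if rel > 0 else rel)
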