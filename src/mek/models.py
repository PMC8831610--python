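"""Core in-memory containers shared across the toolkit.

All internal coordinates are 0-based half-open on the forward genomic
strand; 1-based inclusive coordinates appear only at file boundaries
(GTF/SAM/junction tables), converted in :mod:`mek.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class GenomeSequence:
    """A single chromosome/contig: uppercase DNA over {A,C,G,T,N}."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for {self.name!r}")

    def __len__(self) -> int:
        return len(self.seq)

    def fetch(self, start: int, end: int, strand: str = "+") -> str:
        """Subsequence on the given strand; minus returns the reverse complement."""
        if start < 0 or end > len(self.seq) or start >= end:
            raise IndexError(
                f"interval [{start},{end}) out of bounds for {self.name} "
                f"(length {len(self.seq)})"
            )
        sub = self.seq[start:end]
        return reverse_complement(sub) if strand == "-" else sub


class Genome(dict):
    """Mapping of sequence name -> GenomeSequence with interval fetch."""

    @classmethod
    def from_sequences(cls, seqs) -> "Genome":
        g = cls()
        for s in seqs:
            if s.name in g:
                raise ValueError(f"duplicate sequence name {s.name!r}")
            g[s.name] = s
        return g

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        return self[chrom].fetch(start, end, strand)


@dataclass
class TranscriptModel:
    """One transcript: ordered exons (genomic order), optional CDS segments.

    Exons are non-overlapping 0-based half-open intervals sorted by genomic
    start regardless of strand; ``strand`` records reading direction.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: Optional[list[tuple[int, int]]] = None

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        if self.cds is not None:
            self.cds = sorted(self.cds)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 > s2:
                raise ValueError(
                    f"overlapping exons in {self.transcript_id}: "
                    f"[{s1},{e1}) and [{s2},{e2})"
                )

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    def internal_exons(self) -> list[tuple[int, int]]:
        return self.exons[1:-1]


JUNCTION_COLUMNS = ["chrom", "start", "end", "strand", "motif", "count"]


@dataclass
class JunctionTable:
    """Per-sample splice-junction counts.

    ``df`` columns: chrom, start, end (0-based half-open intron interval),
    strand, motif in {GT-AG, GC-AG, other}, count (unique reads).
    """

    sample_id: str
    df: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=JUNCTION_COLUMNS)
    )

    def __post_init__(self) -> None:
        missing = set(JUNCTION_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"junction table missing columns {sorted(missing)}")
        if len(self.df) and (self.df["end"] - self.df["start"] < 1).any():
            raise ValueError("intron length must be >= 1")

    def count_of(self, chrom: str, start: int, end: int) -> int:
        m = (
            (self.df["chrom"] == chrom)
            & (self.df["start"] == start)
            & (self.df["end"] == end)
        )
        return int(self.df.loc[m, "count"].sum())


@dataclass
class AlignmentRecord:
    """One mapped SAM record reduced to the fields needed downstream."""

    qname: str
    chrom: str
    pos: int  # 0-based leftmost reference position
    mapq: int
    cigar: list[tuple[str, int]]
    nh: Optional[int] = None

    @property
    def unique(self) -> bool:
        """NH==1 when the tag is present, else MAPQ >= 20."""
        if self.nh is not None:
            return self.nh == 1
        return self.mapq >= 20

    def reference_blocks(self) -> list[tuple[int, int]]:
        """Genomic intervals covered by M blocks, in order."""
        blocks = []
        p = self.pos
        for op, ln in self.cigar:
            if op == "M":
                blocks.append((p, p + ln))
                p += ln
            elif op in ("N", "D"):
                p += ln
        return blocks

    def gaps(self) -> list[tuple[int, int]]:
        """Genomic intervals skipped by N operations, in order."""
        out = []
        p = self.pos
        for op, ln in self.cigar:
            if op == "N":
                out.append((p, p + ln))
                p += ln
            elif op in ("M", "D"):
                p += ln
        return out
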