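"""Microexon-spanning read detection and junction counting.

A microexon-spanning read aligns in at least five parts: an anchor in the
5' flanking exon, an intron gap, a short middle match covering the whole
microexon (1-15 nt), a second intron gap, and an anchor in the 3' flanking
exon. Detection works directly on the CIGAR of a spliced alignment.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .models import (
    JUNCTION_COLUMNS,
    AlignmentRecord,
    Genome,
    JunctionTable,
    reverse_complement,
)

logger = logging.getLogger("mek")

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

DEFAULT_MIN_ANCHOR = 6
DEFAULT_ME_LEN_RANGE = (1, 15)
DEFAULT_INTRON_RANGE = (20, 20000)


@dataclass
class SpanningEvidence:
    """Genomic layout of one microexon-spanning alignment window."""

    chrom: str
    left_anchor: tuple[int, int]
    upstream_intron: tuple[int, int]
    microexon: tuple[int, int]
    downstream_intron: tuple[int, int]
    right_anchor: tuple[int, int]

    @property
    def microexon_len(self) -> int:
        return self.microexon[1] - self.microexon[0]


def parse_cigar(cigar_string: str) -> list[tuple[str, int]]:
    """Parse a CIGAR string into an op list.

    '=' and 'X' are normalized to M and adjacent M runs merged, so the op
    list reflects contiguous reference-matching blocks.
    """
    if not cigar_string or cigar_string == "*":
        raise ValueError("empty CIGAR")
    if _CIGAR_RE.sub("", cigar_string):
        raise ValueError(f"invalid CIGAR {cigar_string!r}")
    ops: list[tuple[str, int]] = []
    for m in _CIGAR_RE.finditer(cigar_string):
        ln, op = int(m.group(1)), m.group(2)
        if ln == 0:
            raise ValueError(f"zero-length op in CIGAR {cigar_string!r}")
        if op in ("=", "X"):
            op = "M"
        if ops and ops[-1][0] == "M" and op == "M":
            ops[-1] = ("M", ops[-1][1] + ln)
        else:
            ops.append((op, ln))
    return ops


def normalize_cigar(cigar: Iterable[tuple[str, int]]) -> list[tuple[str, int]]:
    """Normalize an already-parsed op list (merge M runs, map =/X to M)."""
    ops: list[tuple[str, int]] = []
    for op, ln in cigar:
        if op in ("=", "X"):
            op = "M"
        if ops and ops[-1][0] == "M" and op == "M":
            ops[-1] = ("M", ops[-1][1] + ln)
        else:
            ops.append((op, ln))
    return ops


def detect_spanning(
    record: AlignmentRecord,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    me_len_range: tuple[int, int] = DEFAULT_ME_LEN_RANGE,
    intron_range: tuple[int, int] = DEFAULT_INTRON_RANGE,
) -> list[SpanningEvidence]:
    """Find all microexon-spanning windows in one alignment.

    A window is a consecutive M,N,M,N,M op run whose middle M is within
    ``me_len_range``, both N lengths within ``intron_range``, and both outer
    M blocks at least ``min_anchor``. Non-unique alignments yield nothing.
    Reads with more than five parts are scanned for every embedded window.
    """
    if not record.unique:
        return []
    ops = normalize_cigar(record.cigar)
    # Genomic start offset of each op (S/I/H consume no reference).
    starts = []
    p = record.pos
    for op, ln in ops:
        starts.append(p)
        if op in ("M", "N", "D"):
            p += ln
    out = []
    lo, hi = me_len_range
    ilo, ihi = intron_range
    for i in range(len(ops) - 4):
        window = ops[i : i + 5]
        if [op for op, _ in window] != ["M", "N", "M", "N", "M"]:
            continue
        a1, n1, me, n2, a2 = (ln for _, ln in window)
        if not (lo <= me <= hi):
            continue
        if not (ilo <= n1 <= ihi and ilo <= n2 <= ihi):
            continue
        if a1 < min_anchor or a2 < min_anchor:
            continue
        s = starts[i : i + 5]
        out.append(
            SpanningEvidence(
                chrom=record.chrom,
                left_anchor=(s[0], s[0] + a1),
                upstream_intron=(s[1], s[1] + n1),
                microexon=(s[2], s[2] + me),
                downstream_intron=(s[3], s[3] + n2),
                right_anchor=(s[4], s[4] + a2),
            )
        )
    return out


def junction_motif(genome: Genome, chrom: str, start: int, end: int) -> tuple[str, str]:
    """Classify an intron's splice-site dinucleotides.

    Returns (motif, strand): GT..AG / GC..AG on the plus strand give
    ('GT-AG'/'GC-AG', '+'); their reverse complements CT..AC / CT..GC give
    the same motifs on '-'; anything else is ('other', '.').
    """
    if end - start < 4:
        return "other", "."
    donor = genome.fetch(chrom, start, start + 2)
    acceptor = genome.fetch(chrom, end - 2, end)
    if acceptor == "AG":
        if donor == "GT":
            return "GT-AG", "+"
        if donor == "GC":
            return "GC-AG", "+"
    if donor == "CT":  # reverse complement of AG
        rc_donor = reverse_complement(acceptor)
        if rc_donor == "GT":
            return "GT-AG", "-"
        if rc_donor == "GC":
            return "GC-AG", "-"
    return "other", "."


def count_junctions(
    records: Iterable[AlignmentRecord],
    genome: Genome,
    sample_id: str = "sample",
    min_anchor: int = DEFAULT_MIN_ANCHOR,
) -> JunctionTable:
    """Aggregate per-intron junction counts from one sample's alignments.

    Each N op in a uniquely mapped read contributes one count to its intron
    provided the read aligns at least ``min_anchor`` matched nt on each side
    of the junction. Support is cumulative across further junctions, so a
    1-nt microexon match plus a 6-nt anchor beyond it supports the junction
    it abuts. Splice motif and strand are inferred from genomic
    dinucleotides.
    """
    counts: dict[tuple[str, int, int], int] = {}
    for rec in records:
        if not rec.unique:
            continue
        ops = normalize_cigar(rec.cigar)
        m_total = sum(ln for op, ln in ops if op == "M")
        p = rec.pos
        m_before = 0
        for i, (op, ln) in enumerate(ops):
            if op == "M":
                m_before += ln
            if op == "N":
                if m_before >= min_anchor and m_total - m_before >= min_anchor:
                    key = (rec.chrom, p, p + ln)
                    counts[key] = counts.get(key, 0) + 1
            if op in ("M", "N", "D"):
                p += ln
    rows = []
    for (chrom, start, end), n in sorted(counts.items()):
        if chrom not in genome or end > len(genome[chrom]):
            logger.warning(
                "intron %s:[%d,%d) outside genome bounds; dropped", chrom, start, end
            )
            continue
        motif, strand = junction_motif(genome, chrom, start, end)
        rows.append((chrom, start, end, strand, motif, n))
    df = pd.DataFrame(rows, columns=JUNCTION_COLUMNS)
    return JunctionTable(sample_id, df)
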