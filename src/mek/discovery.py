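"""Microexon calling from multi-sample junction evidence.

Candidate internal microexons are the 1-15 nt genomic gaps between a
compatible pair of canonical introns. A call requires at least
``min_support`` junction reads on both flanking introns in at least one
sample; alternative introns competing on one side are resolved by the
highest mean junction count across the sample population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .models import Genome, JunctionTable, TranscriptModel

CANONICAL = ("GT-AG", "GC-AG")

DEFAULT_MIN_SUPPORT = 5


@dataclass
class MicroexonCall:
    """A called internal microexon with its flanking-intron evidence."""

    chrom: str
    strand: str
    start: int
    end: int
    upstream_intron: tuple[int, int]
    downstream_intron: tuple[int, int]
    upstream_motif: str
    downstream_motif: str
    left_counts: dict[str, int] = field(default_factory=dict)
    right_counts: dict[str, int] = field(default_factory=dict)
    psi: Optional[float] = None
    annotation_status: str = "unannotated_gene"

    @property
    def size(self) -> int:
        return self.end - self.start


def _intron_index(tables: Sequence[JunctionTable]):
    """Pool canonical introns: (chrom,start,end,strand,motif) -> per-sample counts."""
    pooled: dict[tuple, dict[str, int]] = {}
    motifs: dict[tuple, tuple[str, str]] = {}
    for t in tables:
        df = t.df[t.df["motif"].isin(CANONICAL)]
        for row in df.itertuples(index=False):
            key = (row.chrom, row.start, row.end, row.strand)
            pooled.setdefault(key, {})
            pooled[key][t.sample_id] = pooled[key].get(t.sample_id, 0) + int(row.count)
            motifs[key] = (row.motif, row.strand)
    return pooled, motifs


def _mean_count(counts: dict[str, int], n_samples: int) -> float:
    return sum(counts.values()) / n_samples


def call_microexons(
    junction_tables: Sequence[JunctionTable],
    genome: Genome,
    min_support: int = DEFAULT_MIN_SUPPORT,
    me_len_range: tuple[int, int] = (1, 15),
) -> list[MicroexonCall]:
    """Call internal microexons from per-sample junction tables.

    Only introns with canonical splice sites (GT-AG or GC-AG) are
    considered. When several introns compete on one side of a candidate
    exon, the intron with the most average junction reads across samples
    wins (ties: shorter intron, then leftmost).
    """
    n_samples = len(junction_tables)
    pooled, motifs = _intron_index(junction_tables)
    lo, hi = me_len_range

    # Group intron keys by (chrom, strand) and index by end / start position.
    by_end: dict[tuple, dict[int, list[tuple]]] = {}
    by_start: dict[tuple, dict[int, list[tuple]]] = {}
    for key in pooled:
        chrom, start, end, strand = key
        by_end.setdefault((chrom, strand), {}).setdefault(end, []).append(key)
        by_start.setdefault((chrom, strand), {}).setdefault(start, []).append(key)

    def best(introns: list[tuple]) -> tuple:
        return max(
            introns,
            key=lambda k: (
                _mean_count(pooled[k], n_samples),
                -(k[2] - k[1]),  # shorter preferred
                -k[1],  # then leftmost
            ),
        )

    calls = []
    for (chrom, strand), ends in by_end.items():
        starts = by_start[(chrom, strand)]
        for exon_start, left_introns in ends.items():
            for exon_end in range(exon_start + lo, exon_start + hi + 1):
                right_introns = starts.get(exon_end)
                if not right_introns:
                    continue
                left = best(left_introns)
                right = best(right_introns)
                lcounts = pooled[left]
                rcounts = pooled[right]
                samples = {t.sample_id for t in junction_tables}
                supported = any(
                    lcounts.get(s, 0) >= min_support and rcounts.get(s, 0) >= min_support
                    for s in samples
                )
                if not supported:
                    continue
                call = MicroexonCall(
                    chrom=chrom,
                    strand=strand,
                    start=exon_start,
                    end=exon_end,
                    upstream_intron=(left[1], left[2]),
                    downstream_intron=(right[1], right[2]),
                    upstream_motif=motifs[left][0],
                    downstream_motif=motifs[right][0],
                    left_counts={s: lcounts.get(s, 0) for s in samples},
                    right_counts={s: rcounts.get(s, 0) for s in samples},
                )
                call.psi = compute_psi(call, junction_tables)
                calls.append(call)
    calls.sort(key=lambda c: (c.chrom, c.start, c.end, c.strand))
    return calls


def compute_psi(
    call: MicroexonCall, junction_tables: Sequence[JunctionTable]
) -> Optional[float]:
    """Percent spliced-in: fraction of transcripts that include the microexon.

    PSI = I / (I + E), where I averages the summed-over-samples counts of
    the two inclusion junctions and E is the summed count of the canonical
    exclusion junction joining the flanking exons directly. Returns None
    when no informative reads exist.
    """
    left_total = sum(call.left_counts.values())
    right_total = sum(call.right_counts.values())
    inclusion = (left_total + right_total) / 2.0
    excl_start = call.upstream_intron[0]
    excl_end = call.downstream_intron[1]
    exclusion = 0
    for t in junction_tables:
        df = t.df
        m = (
            (df["chrom"] == call.chrom)
            & (df["start"] == excl_start)
            & (df["end"] == excl_end)
            & df["motif"].isin(CANONICAL)
        )
        exclusion += int(df.loc[m, "count"].sum())
    if inclusion + exclusion == 0:
        return None
    return inclusion / (inclusion + exclusion)


def classify_vs_annotation(
    call: MicroexonCall, transcripts: Sequence[TranscriptModel]
) -> str:
    """Place a call relative to an existing annotation.

    Order of precedence: exact internal-exon match with matching flanking
    introns; overlap with a longer annotated exon; strictly inside an
    annotated intron; otherwise in no annotated gene.
    """
    interval = (call.start, call.end)
    overlaps_longer = False
    inside_intron = False
    for tx in transcripts:
        if tx.chrom != call.chrom:
            continue
        exons = tx.exons
        for i, (s, e) in enumerate(exons):
            if 0 < i < len(exons) - 1 and (s, e) == interval:
                if (
                    exons[i - 1][1] == call.upstream_intron[0]
                    and exons[i + 1][0] == call.downstream_intron[1]
                ):
                    return "annotated_exact"
            if e - s > call.size and s < call.end and call.start < e:
                overlaps_longer = True
        for s, e in tx.introns:
            if s < call.start and call.end < e:
                inside_intron = True
    if overlaps_longer:
        return "within_larger_exon"
    if inside_intron:
        return "intronic"
    return "unannotated_gene"


def classify_calls(
    calls: Sequence[MicroexonCall], transcripts: Sequence[TranscriptModel]
) -> None:
    """Annotate ``annotation_status`` on every call in place."""
    for call in calls:
        call.annotation_status = classify_vs_annotation(call, transcripts)


def validate_annotated_microexons(
    transcripts: Sequence[TranscriptModel],
    junction_tables: Sequence[JunctionTable],
    min_support: int = DEFAULT_MIN_SUPPORT,
    me_max: int = 15,
) -> pd.DataFrame:
    """Check which annotated internal microexons have junction-read support.

    An annotated internal exon of at most ``me_max`` nt is supported iff
    some single sample has at least ``min_support`` reads on both of its
    flanking introns. First/last exons are excluded. Returns one row per
    distinct (chrom, exon, flanking introns) event.
    """
    seen = set()
    rows = []
    for tx in transcripts:
        exons = tx.exons
        for i in range(1, len(exons) - 1):
            s, e = exons[i]
            if e - s > me_max:
                continue
            up = (exons[i - 1][1], s)
            down = (e, exons[i + 1][0])
            key = (tx.chrom, s, e, up, down)
            if key in seen:
                continue
            seen.add(key)
            supported = any(
                t.count_of(tx.chrom, *up) >= min_support
                and t.count_of(tx.chrom, *down) >= min_support
                for t in junction_tables
            )
            rows.append(
                {
                    "transcript_id": tx.transcript_id,
                    "chrom": tx.chrom,
                    "start": s,
                    "end": e,
                    "size": e - s,
                    "supported": supported,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "chrom", "start", "end", "size", "supported"],
    )
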