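"""Intron retention, detained-intron classification, and ISE window scans.

Intron retention is quantified per intron per sample as the percentage of
intron retention, PIR = 100 * (i1 + i2) / (i1 + i2 + 2e + 2o): i1 and i2
are continuous reads crossing the exon-intron and intron-exon boundaries,
e counts spliced reads joining the two adjacent exons exactly, and o
counts other alternative gapped reads over the intron. Chromatin-bound
(CB) polyadenylated transcripts with a high unspliced ratio carry detained
introns that require post-transcriptional splicing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import chi2_contingency

from .models import AlignmentRecord
from .spanning import normalize_cigar

logger = logging.getLogger("mek")

DEFAULT_MIN_OVERHANG = 4
MIN_JUNCTION_READS = 10
CB_DETAINED_RATIO = 0.1
CYTO_CS_RATIO = 0.2


@dataclass
class PIRRecord:
    """Junction/retention counts and derived PIR for one intron in one sample."""

    chrom: str
    start: int
    end: int
    strand: str
    sample_id: str
    i1: int
    i2: int
    e: int
    o: int
    pir: Optional[float]

    @property
    def unspliced_ratio(self) -> Optional[float]:
        return None if self.pir is None else self.pir / 100.0


@dataclass
class MotifWindowResult:
    has_t_rich: bool
    has_g_rich: bool


def intron_boundary_counts(
    records: Iterable[AlignmentRecord],
    chrom: str,
    intron: tuple[int, int],
    strand: str = "+",
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> tuple[int, int, int, int]:
    """Count boundary-spanning and junction reads for one intron.

    i1/i2: continuous (single M block) reads crossing the intron's 5'/3'
    boundary by at least ``min_overhang`` nt on each side. e: gapped reads
    whose N gap equals the intron exactly. o: gapped reads whose N gap
    overlaps the intron but differs from it. All junction reads must extend
    at least ``min_overhang`` matched nt from the boundary they cross
    (cumulative across further junctions, so a gapped read whose next match
    is a 1-nt microexon still supports the junction it abuts).
    """
    start, end = intron
    b5, b3 = (start, end) if strand != "-" else (end, start)
    i1 = i2 = e = o = 0
    for rec in records:
        if rec.chrom != chrom or not rec.unique:
            continue
        ops = normalize_cigar(rec.cigar)
        m_total = sum(ln for op, ln in ops if op == "M")
        p = rec.pos
        m_before = 0
        for op, ln in ops:
            if op == "M":
                m_before += ln
                if p <= b5 - min_overhang and b5 + min_overhang <= p + ln:
                    i1 += 1
                if p <= b3 - min_overhang and b3 + min_overhang <= p + ln:
                    i2 += 1
            if op == "N":
                gap = (p, p + ln)
                if m_before >= min_overhang and m_total - m_before >= min_overhang:
                    if gap == intron:
                        e += 1
                    elif gap[0] < end and start < gap[1]:
                        o += 1
            if op in ("M", "N", "D"):
                p += ln
    return i1, i2, e, o


def compute_pir(i1: int, i2: int, e: int, o: int) -> Optional[float]:
    """PIR = 100 * (i1 + i2) / (i1 + i2 + 2e + 2o).

    Returns None (missing) when the total junction-read count
    i1 + i2 + e + o is below 10.
    """
    if min(i1, i2, e, o) < 0:
        raise ValueError("counts must be non-negative")
    total = i1 + i2 + e + o
    if total < MIN_JUNCTION_READS:
        return None
    return 100.0 * (i1 + i2) / (i1 + i2 + 2 * e + 2 * o)


def classify_detained(
    cb_ratios: Sequence[float], cyto_ratios: Sequence[float]
) -> str:
    """Classify one intron from replicate-averaged unspliced ratios.

    Introns that are not constitutively spliced in the cytoplasm (mean
    ratio >= 0.2) are excluded; otherwise a mean chromatin-bound ratio
    > 0.1 marks a detained intron requiring post-transcriptional splicing.
    """
    cb = float(np.mean(cb_ratios))
    cyto = float(np.mean(cyto_ratios))
    if cyto >= CYTO_CS_RATIO:
        return "excluded"
    if cb > CB_DETAINED_RATIO:
        return "detained_PTS"
    return "constitutive_CTS"


def _rolling_count(flags: np.ndarray, window: int) -> np.ndarray:
    if len(flags) < window:
        return np.empty(0)
    cs = np.concatenate([[0], np.cumsum(flags)])
    return cs[window:] - cs[:-window]


def motif_window_scan(
    intron_seq: str,
    t_window: int = 20,
    g_window: int = 10,
    frac: float = 0.8,
    flank: int = 10,
) -> MotifWindowResult:
    """Sliding-window U(T)-rich and G-rich flags on an intron interior.

    The interior excludes ``flank`` nt at each end (splice-site regions).
    A window is T-rich (U-rich in RNA) if strictly more than ``frac`` of
    its 20 nt are T; G-rich if strictly more than ``frac`` of its 10 nt
    are G. Step size is 1 nt.
    """
    seq = intron_seq.upper()
    if len(seq) <= 40:
        logger.warning("intron of length %d too short for window scan", len(seq))
        return MotifWindowResult(False, False)
    interior = seq[flank : len(seq) - flank]
    arr = np.frombuffer(interior.encode(), dtype=np.uint8)
    t_counts = _rolling_count((arr == ord("T")).astype(int), t_window)
    g_counts = _rolling_count((arr == ord("G")).astype(int), g_window)
    has_t = bool(len(t_counts) and (t_counts > frac * t_window).any())
    has_g = bool(len(g_counts) and (g_counts > frac * g_window).any())
    return MotifWindowResult(has_t_rich=has_t, has_g_rich=has_g)


def motif_enrichment(
    me_flags: Sequence[bool], control_flags: Sequence[bool]
) -> tuple[float, Optional[float]]:
    """Pearson chi-squared contrast of motif presence between intron sets.

    Builds the 2x2 table of (has motif, lacks motif) x (microexon-flanking,
    control) and tests without continuity correction. Degenerate tables
    (an all-true or all-false margin) return (0.0, None).
    """
    me = np.asarray(me_flags, dtype=bool)
    ctrl = np.asarray(control_flags, dtype=bool)
    table = np.array(
        [
            [int(me.sum()), int(ctrl.sum())],
            [int((~me).sum()), int((~ctrl).sum())],
        ]
    )
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        return 0.0, None
    res = chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def pir_records(
    records_by_sample: dict[str, list[AlignmentRecord]],
    introns: Sequence[tuple[str, int, int, str]],
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> list[PIRRecord]:
    """Compute PIR for every intron in every sample."""
    out = []
    for sample_id, records in sorted(records_by_sample.items()):
        for chrom, start, end, strand in introns:
            i1, i2, e, o = intron_boundary_counts(
                records, chrom, (start, end), strand, min_overhang
            )
            out.append(
                PIRRecord(
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    sample_id=sample_id,
                    i1=i1,
                    i2=i2,
                    e=e,
                    o=o,
                    pir=compute_pir(i1, i2, e, o),
                )
            )
    return out
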