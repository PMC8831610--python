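"""Split position-weight-matrix construction and genome scanning.

A cluster's unique tag DNAs give one PWM over the full tag length; the
PWM is split at the cluster's canonical exon boundaries into a microexon
part and two or more flanking parts. Each part is scanned independently
over both genome strands and compatible part hits are chained, allowing
an intron gap (with canonical splice sites) or no gap between adjacent
parts. A chained locus where both gaps flanking the microexon part are
introns is a real microexon; a locus where either gap is absent has the
microexon merged into a longer exon.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import Genome, reverse_complement

logger = logging.getLogger("mek")

PSEUDOCOUNT = 0.25
BASES = "ACGT"
_CODE = {b: i for i, b in enumerate("ACGTN")}

DEFAULT_MIN_SCORE_FRAC = 0.8
DEFAULT_GAP_RANGE = (20, 10000)


@dataclass
class PWM:
    """Per-column base probabilities and log-odds over a uniform background."""

    probs: np.ndarray  # 4 x L
    logodds: np.ndarray  # 4 x L

    @property
    def length(self) -> int:
        return self.probs.shape[1]


@dataclass
class SplitPWM:
    """A cluster PWM sliced at exon boundaries into scannable parts."""

    cluster_id: str
    parts: list[PWM]
    roles: list[str]  # 'flank5', 'microexon', 'flank3'
    me_size: int
    me_phase: int

    @property
    def me_index(self) -> int:
        return self.roles.index("microexon")

    @property
    def tag_len(self) -> int:
        return sum(p.length for p in self.parts)


@dataclass
class ScanHit:
    """One chained locus: per-part genomic intervals plus classification."""

    chrom: str
    strand: str
    part_intervals: list[tuple[int, int]]  # hit 5'->3' order, plus-strand coords
    part_indices: list[int]  # indices into SplitPWM.parts
    gaps: list[int]
    gap_motifs: list[Optional[str]]
    score: float
    classification: str  # microexon | merged | partial

    @property
    def span(self) -> tuple[int, int]:
        coords = [c for iv in self.part_intervals for c in iv]
        return (min(coords), max(coords))


def build_pwm(sequences: Sequence[str], alpha: float = PSEUDOCOUNT) -> PWM:
    """Build a PWM from equal-length DNA sequences.

    Column probabilities are (n_b + alpha) / (N + 4*alpha); log-odds are
    base-2 against a uniform 0.25 background. Sequences containing N are
    dropped with a warning; fewer than two usable sequences is an error.
    """
    usable = []
    for s in sequences:
        s = s.upper()
        if set(s) - set(BASES):
            logger.warning("sequence with non-ACGT characters dropped from PWM")
            continue
        usable.append(s)
    if len(usable) < 2:
        raise ValueError("PWM construction requires at least 2 clean sequences")
    lengths = {len(s) for s in usable}
    if len(lengths) != 1:
        raise ValueError(f"PWM sequences must have equal length, got {sorted(lengths)}")
    L = lengths.pop()
    counts = np.zeros((4, L))
    for s in usable:
        idx = np.frompyfunc(_CODE.__getitem__, 1, 1)(np.array(list(s))).astype(int)
        for b in range(4):
            counts[b] += idx == b
    probs = (counts + alpha) / (len(usable) + 4 * alpha)
    logodds = np.log2(probs / 0.25)
    return PWM(probs=probs, logodds=logodds)


def split_pwm(
    pwm: PWM,
    boundary_offsets: Sequence[int],
    me_offset: int,
    me_size: int,
    cluster_id: str = "",
    me_phase: int = 0,
) -> SplitPWM:
    """Slice a tag PWM at exon boundaries and assign part roles.

    ``boundary_offsets`` are offsets strictly inside the tag; the microexon
    must be exactly delimited by two of them (or by a tag end, for
    boundary-truncated clusters).
    """
    L = pwm.length
    bounds = sorted(set(boundary_offsets))
    if any(b <= 0 or b >= L for b in bounds):
        raise ValueError("boundary offsets must be strictly inside the tag")
    cuts = [0] + bounds + [L]
    me_lo, me_hi = me_offset, me_offset + me_size
    if me_lo not in cuts or me_hi not in cuts:
        raise ValueError(
            f"microexon [{me_lo},{me_hi}) is not delimited by boundaries {bounds}"
        )
    parts, roles = [], []
    for s, e in zip(cuts, cuts[1:]):
        parts.append(PWM(probs=pwm.probs[:, s:e], logodds=pwm.logodds[:, s:e]))
        if (s, e) == (me_lo, me_hi):
            roles.append("microexon")
        elif e <= me_lo:
            roles.append("flank5")
        else:
            roles.append("flank3")
    if "microexon" not in roles:
        raise ValueError("no part matches the microexon interval")
    return SplitPWM(
        cluster_id=cluster_id, parts=parts, roles=roles, me_size=me_size, me_phase=me_phase
    )


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(
        seq.encode().translate(bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))),
        dtype=np.uint8,
    )


def _part_scores(codes: np.ndarray, part: PWM) -> np.ndarray:
    """Log-odds score of the part at every start position (N scores -inf)."""
    w = part.length
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty(0)
    lo = np.vstack([part.logodds, np.full((1, w), -1e9)])
    scores = np.zeros(n)
    for j in range(w):
        scores += lo[codes[j : j + n], j]
    return scores


def _score_threshold(part: PWM, frac: float) -> float:
    col_max = part.logodds.max(axis=0).sum()
    col_min = part.logodds.min(axis=0).sum()
    return col_min + frac * (col_max - col_min)


def _chain(
    seq: str,
    cand: list[tuple[np.ndarray, np.ndarray]],
    widths: list[int],
    part_range: range,
    gap_range: tuple[int, int],
) -> list[tuple[list[int], float, list[int], list[Optional[str]]]]:
    """Chain candidate part hits left to right over ``part_range``.

    Returns (positions, total score, gaps, gap motifs) per chain; nonzero
    gaps must begin GT/GC and end AG on the scanned strand.
    """
    gmin, gmax = gap_range
    first = part_range[0]
    chains = [([int(p)], float(s), [], []) for p, s in zip(*cand[first])]
    for k in part_range[1:]:
        pos_k, sc_k = cand[k]
        pos_list = pos_k.tolist()
        new_chains = []
        for positions, score, gaps, motifs in chains:
            end = positions[-1] + widths[k - 1]
            # gap 0 (intron absent)
            i = bisect_left(pos_list, end)
            if i < len(pos_list) and pos_list[i] == end:
                new_chains.append(
                    (positions + [end], score + float(sc_k[i]), gaps + [0], motifs + [None])
                )
            # intron gap within [gmin, gmax] with canonical splice sites
            lo = bisect_left(pos_list, end + gmin)
            hi = bisect_right(pos_list, end + gmax)
            for i in range(lo, hi):
                p = pos_list[i]
                gap_seq = seq[end:p]
                if gap_seq[:2] in ("GT", "GC") and gap_seq[-2:] == "AG":
                    new_chains.append(
                        (
                            positions + [p],
                            score + float(sc_k[i]),
                            gaps + [p - end],
                            motifs + [gap_seq[:2] + "-AG"],
                        )
                    )
        chains = new_chains
        if not chains:
            break
    return chains


def scan_and_assemble(
    genome: Genome,
    spwm: SplitPWM,
    min_score_frac: float = DEFAULT_MIN_SCORE_FRAC,
    gap_range: tuple[int, int] = DEFAULT_GAP_RANGE,
) -> list[ScanHit]:
    """Scan both genome strands with a split PWM and chain part hits.

    Part windows scoring at least ``min_score_frac`` of the min-max
    log-odds range are kept; adjacent parts may be separated by no gap or
    by an intron gap within ``gap_range`` bounded by canonical splice
    sites. Overlapping chains are resolved by most parts, then highest
    score, then leftmost. Chains missing one terminal flank part are
    reported as 'partial'.
    """
    K = len(spwm.parts)
    widths = [p.length for p in spwm.parts]
    me_idx = spwm.me_index
    thresholds = [_score_threshold(p, min_score_frac) for p in spwm.parts]
    raw_hits = []
    for chrom, gseq in sorted(genome.items()):
        L = len(gseq)
        for strand in ("+", "-"):
            seq = gseq.seq if strand == "+" else reverse_complement(gseq.seq)
            codes = _encode(seq)
            cand = []
            for part, thr in zip(spwm.parts, thresholds):
                scores = _part_scores(codes, part)
                keep = np.nonzero(scores >= thr)[0]
                cand.append((keep, scores[keep]))
            ranges = [range(0, K)]
            if K >= 3:
                ranges += [range(1, K), range(0, K - 1)]
            for part_range in ranges:
                if me_idx not in part_range:
                    continue
                full = len(part_range) == K
                for positions, score, gaps, motifs in _chain(
                    seq, cand, widths, part_range, gap_range
                ):
                    ivs = [
                        (p, p + widths[k]) for p, k in zip(positions, part_range)
                    ]
                    if strand == "-":
                        ivs = [(L - e, L - s) for s, e in ivs]
                    if full:
                        g_up = gaps[me_idx - 1] if me_idx > 0 else None
                        g_down = gaps[me_idx] if me_idx < K - 1 else None
                        both_introns = all(
                            g is None or g > 0 for g in (g_up, g_down)
                        ) and any(g is not None for g in (g_up, g_down))
                        cls = "microexon" if both_introns else "merged"
                    else:
                        cls = "partial"
                    raw_hits.append(
                        ScanHit(
                            chrom=chrom,
                            strand=strand,
                            part_intervals=ivs,
                            part_indices=list(part_range),
                            gaps=gaps,
                            gap_motifs=motifs,
                            score=score,
                            classification=cls,
                        )
                    )
    # Full chains are resolved first; partial chains are diagnostics and may
    # only occupy regions no full chain claimed.
    full = [h for h in raw_hits if h.classification != "partial"]
    partial = [h for h in raw_hits if h.classification == "partial"]
    selected = _resolve_overlaps(full)
    free_partial = [
        h
        for h in partial
        if not any(
            o.chrom == h.chrom and o.span[0] < h.span[1] and h.span[0] < o.span[1]
            for o in selected
        )
    ]
    selected += _resolve_overlaps(free_partial)
    selected.sort(key=lambda h: (h.chrom, h.span[0], h.strand))
    return selected


def _resolve_overlaps(hits: list[ScanHit]) -> list[ScanHit]:
    """Keep the non-overlapping chain set with maximal total score.

    Weighted interval scheduling per chromosome. This prevents a single
    chimeric chain spanning two tandem gene copies from displacing the two
    genuine per-copy chains: the pair's combined score wins.
    """
    by_chrom: dict[str, list[ScanHit]] = {}
    for h in hits:
        by_chrom.setdefault(h.chrom, []).append(h)
    out: list[ScanHit] = []
    for chrom in sorted(by_chrom):
        # deterministic order: by end, then start, then strand, then score
        hs = sorted(
            by_chrom[chrom],
            key=lambda h: (h.span[1], h.span[0], h.strand, -h.score),
        )
        ends = [h.span[1] for h in hs]
        n = len(hs)
        # p[i]: rightmost j < i with span[j].end <= span[i].start
        best = [0.0] * (n + 1)
        take = [False] * n
        prev = [0] * n
        for i, h in enumerate(hs):
            j = bisect_right(ends, h.span[0], 0, i)
            prev[i] = j
            with_i = best[j] + h.score
            if with_i > best[i]:
                best[i + 1] = with_i
                take[i] = True
            else:
                best[i + 1] = best[i]
        i = n - 1
        chosen = []
        while i >= 0:
            if take[i]:
                chosen.append(hs[i])
                i = prev[i] - 1
            else:
                i -= 1
        out.extend(chosen)
    return out


def build_cluster_model(cluster, candidates: Sequence[str] = ()) -> SplitPWM:
    """Build the split PWM for a tag cluster.

    Member tag DNAs (plus optional pre-aligned homologous fragments, cleaned
    by :func:`mek.tags.filter_homolog_sequences`) give the PWM; the split
    uses the cluster's canonical exon boundaries and microexon offset.
    """
    from .tags import filter_homolog_sequences

    seqs = filter_homolog_sequences(candidates, cluster)
    pwm = build_pwm(seqs)
    return split_pwm(
        pwm,
        cluster.canonical_boundaries(),
        cluster.canonical_me_offset(),
        cluster.me_size,
        cluster_id=cluster.cluster_id,
        me_phase=cluster.me_phase,
    )


def summarize_rates(
    hits_by_cluster_by_species: dict[str, dict[str, Sequence[ScanHit]]]
) -> pd.DataFrame:
    """Per cluster per species microexon rate.

    rate = (#hits classified microexon) / (#microexon + #merged); partial
    hits are excluded; a cell with no informative hits is NA.
    """
    clusters = sorted(hits_by_cluster_by_species)
    species = sorted({sp for d in hits_by_cluster_by_species.values() for sp in d})
    mat = pd.DataFrame(np.nan, index=clusters, columns=species)
    for cl, by_sp in hits_by_cluster_by_species.items():
        for sp, hits in by_sp.items():
            n_me = sum(1 for h in hits if h.classification == "microexon")
            n_merged = sum(1 for h in hits if h.classification == "merged")
            if n_me + n_merged:
                mat.loc[cl, sp] = n_me / (n_me + n_merged)
    return mat
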