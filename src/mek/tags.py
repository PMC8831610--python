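"""Microexon-tags: fixed-length in-frame coding windows around microexons.

A microexon-tag is (by default) a 108-nt continuous coding window centered
on a coding microexon, shifted to a codon boundary so it translates in
frame into a 36-aa peptide. Tags from different species are grouped by
microexon size and phase and clustered on BLOSUM62 peptide alignment
scores; clusters are the homology units used for genome-wide modeling.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .models import Genome, TranscriptModel

logger = logging.getLogger("mek")

DEFAULT_TAG_LEN = 108
STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class OrfAnnotation:
    """Longest ORF of a transcript, with its genomic CDS segments.

    ``start``/``end`` are transcript coordinates (half-open, including the
    stop codon when present); ``segments`` are genomic intervals composing
    the ORF, listed in transcript (5'->3') order; ``cds_seq`` is the ORF
    nucleotide sequence in mRNA sense.
    """

    transcript_id: str
    chrom: str
    strand: str
    start: int
    end: int
    cds_seq: str
    segments: list[tuple[int, int]]

    @property
    def coding_len(self) -> int:
        """ORF length excluding the terminal stop codon (if present)."""
        n = len(self.cds_seq)
        if n >= 3 and self.cds_seq[-3:] in STOP_CODONS:
            return n - 3
        return n

    def cds_offset(self, genomic_pos: int) -> Optional[int]:
        """Map a genomic position to a 0-based offset within the ORF."""
        cum = 0
        for s, e in self.segments:
            if s <= genomic_pos < e:
                if self.strand == "+":
                    return cum + (genomic_pos - s)
                return cum + (e - 1 - genomic_pos)
            cum += e - s
        return None

    def exon_boundary_offsets(self) -> list[int]:
        """Cumulative CDS offsets of internal segment junctions."""
        out = []
        cum = 0
        for s, e in self.segments[:-1]:
            cum += e - s
            out.append(cum)
        return out


@dataclass
class MicroexonTag:
    """One in-frame coding window around a microexon."""

    species: str
    gene_id: str
    transcript_id: str
    dna: str
    peptide: str
    me_size: int
    me_phase: int
    me_offset: int
    exon_boundary_offsets: list[int]

    @property
    def tag_id(self) -> str:
        return f"{self.species}|{self.transcript_id}|{self.me_size}|{self.me_phase}"

    def me_peptide_interval(self) -> tuple[int, int]:
        """Half-open aa interval of residues (partly) encoded by the microexon."""
        return (self.me_offset // 3, -(-(self.me_offset + self.me_size) // 3))


@dataclass
class TagCluster:
    """A size+phase-homogeneous cluster of microexon-tags."""

    cluster_id: str
    me_size: int
    me_phase: int
    members: list[MicroexonTag]
    motif: Optional[tuple[str, float]] = None

    @property
    def species(self) -> set[str]:
        return {t.species for t in self.members}

    @property
    def tag_len(self) -> int:
        return max(len(t.dna) for t in self.members)

    def canonical_boundaries(self) -> list[int]:
        """Modal exon-boundary offsets over full-length member tags."""
        full = [t for t in self.members if len(t.dna) == self.tag_len]
        counts = Counter(tuple(t.exon_boundary_offsets) for t in full)
        return list(max(counts, key=lambda k: (counts[k], k)))

    def canonical_me_offset(self) -> int:
        full = [t for t in self.members if len(t.dna) == self.tag_len]
        counts = Counter(t.me_offset for t in full)
        return max(counts, key=lambda k: (counts[k], -k))


def find_longest_orf(transcript_seq: str, min_len: int = 0) -> Optional[tuple[int, int]]:
    """Longest ATG-initiated ORF on the transcript's forward strand.

    Returns (start, end) in transcript coordinates, including the stop
    codon when present; an ORF may run to the transcript end without a
    stop. Ties go to the 5'-most start. None if no ORF of >= min_len nt.
    """
    seq = transcript_seq.upper()
    n = len(seq)
    best: Optional[tuple[int, int]] = None
    # For each frame, remember the next stop at or after each codon start.
    for frame in range(3):
        starts = [i for i in range(frame, n - 2, 3) if seq[i : i + 3] == "ATG"]
        stops = [i for i in range(frame, n - 2, 3) if seq[i : i + 3] in STOP_CODONS]
        si = 0
        for a in starts:
            while si < len(stops) and stops[si] < a:
                si += 1
            # scan forward among remaining stops for this start
            j = si
            while j < len(stops) and stops[j] < a:
                j += 1
            if j < len(stops):
                end = stops[j] + 3
            else:
                end = a + ((n - a) // 3) * 3
            length = end - a
            if length >= max(min_len, 3) and (
                best is None
                or length > best[1] - best[0]
                or (length == best[1] - best[0] and a < best[0])
            ):
                best = (a, end)
    return best


def transcript_sequence(tx: TranscriptModel, genome: Genome) -> str:
    """Spliced transcript sequence in mRNA sense orientation."""
    parts = [genome.fetch(tx.chrom, s, e) for s, e in tx.exons]
    seq = "".join(parts)
    if tx.strand == "-":
        from .models import reverse_complement

        seq = reverse_complement(seq)
    return seq


def orf_from_transcript(
    tx: TranscriptModel, genome: Genome, min_len: int = 30
) -> Optional[OrfAnnotation]:
    """Find the longest ORF of a transcript and map it to genomic segments."""
    seq = transcript_sequence(tx, genome)
    hit = find_longest_orf(seq, min_len=min_len)
    if hit is None:
        logger.warning("no ORF >= %d nt in %s; skipped", min_len, tx.transcript_id)
        return None
    start, end = hit
    # Exons in transcript order.
    exons = tx.exons if tx.strand == "+" else list(reversed(tx.exons))
    segments = []
    cum = 0
    for s, e in exons:
        ln = e - s
        lo = max(start, cum)
        hi = min(end, cum + ln)
        if lo < hi:
            if tx.strand == "+":
                segments.append((s + (lo - cum), s + (hi - cum)))
            else:
                segments.append((e - (hi - cum), e - (lo - cum)))
        cum += ln
    return OrfAnnotation(
        transcript_id=tx.transcript_id,
        chrom=tx.chrom,
        strand=tx.strand,
        start=start,
        end=end,
        cds_seq=seq[start:end],
        segments=segments,
    )


def microexon_phase(orf: OrfAnnotation, me_interval: tuple[int, int]) -> int:
    """Reading-frame phase: CDS nucleotides 5' of the microexon, mod 3."""
    gpos = me_interval[0] if orf.strand == "+" else me_interval[1] - 1
    off = orf.cds_offset(gpos)
    if off is None:
        raise ValueError(f"microexon {me_interval} not inside ORF of {orf.transcript_id}")
    return off % 3


def translate(dna: str) -> str:
    return str(Seq(dna).translate())


def extract_microexon_tag(
    orf: OrfAnnotation,
    me_interval: tuple[int, int],
    tag_len: int = DEFAULT_TAG_LEN,
    species: str = "unknown",
    gene_id: str = "",
) -> Optional[MicroexonTag]:
    """Extract the in-frame coding window of ``tag_len`` nt around a microexon.

    The window is centered on the microexon in CDS coordinates and then
    shifted by at most one nt so it starts on a codon boundary (the phase-1
    shift is forward, phase-2 backward, phase-0 none; when the two flanks
    cannot be equal the extra nucleotide goes 3'). The window is truncated
    in frame at the ORF start and at the last codon before the stop, so it
    always translates without internal stop codons.
    """
    gpos = me_interval[0] if orf.strand == "+" else me_interval[1] - 1
    me_start = orf.cds_offset(gpos)
    me_size = me_interval[1] - me_interval[0]
    if me_start is None:
        raise ValueError(f"microexon {me_interval} not inside ORF of {orf.transcript_id}")
    phase = me_start % 3
    ideal = (tag_len - me_size) / 2.0
    # Left flank length congruent to the phase, nearest the ideal half-width;
    # ties resolved downward so the extra nucleotide lands 3' of the microexon.
    candidates = [
        lf
        for lf in range(max(0, int(ideal) - 3), int(ideal) + 4)
        if lf % 3 == phase % 3
    ]
    left = min(candidates, key=lambda lf: (abs(lf - ideal), lf))
    w = me_start - left
    e = w + tag_len
    w = max(w, 0)
    e = min(e, orf.coding_len)
    if e - w < 3:
        logger.warning(
            "tag window shorter than one codon for %s; skipped", orf.transcript_id
        )
        return None
    if not (w <= me_start and me_start + me_size <= e):
        logger.warning(
            "microexon does not fit the truncated tag window for %s; skipped",
            orf.transcript_id,
        )
        return None
    dna = orf.cds_seq[w:e]
    boundaries = [b - w for b in orf.exon_boundary_offsets() if w < b < e]
    return MicroexonTag(
        species=species,
        gene_id=gene_id,
        transcript_id=orf.transcript_id,
        dna=dna,
        peptide=translate(dna),
        me_size=me_size,
        me_phase=phase,
        me_offset=me_start - w,
        exon_boundary_offsets=boundaries,
    )


def write_tags_fasta(tags: Sequence[MicroexonTag], path: str) -> None:
    """Serialize tags as FASTA with structured headers:
    species|gene|transcript|size|phase|offset|comma-separated boundaries.
    """
    with open(path, "w") as fh:
        for t in tags:
            bounds = ",".join(map(str, t.exon_boundary_offsets)) or "-"
            fh.write(
                f">{t.species}|{t.gene_id}|{t.transcript_id}|{t.me_size}|"
                f"{t.me_phase}|{t.me_offset}|{bounds}\n{t.dna}\n"
            )


def read_tags_fasta(path: str) -> list[MicroexonTag]:
    from Bio import SeqIO

    tags = []
    for rec in SeqIO.parse(path, "fasta"):
        fields = rec.description.split("|")
        if len(fields) != 7:
            raise ValueError(f"bad tag header {rec.description!r}")
        species, gene, tx, size, phase, offset, bounds = fields
        dna = str(rec.seq).upper()
        tags.append(
            MicroexonTag(
                species=species,
                gene_id=gene,
                transcript_id=tx,
                dna=dna,
                peptide=translate(dna),
                me_size=int(size),
                me_phase=int(phase),
                me_offset=int(offset),
                exon_boundary_offsets=(
                    [] if bounds == "-" else [int(b) for b in bounds.split(",")]
                ),
            )
        )
    return tags


def clusters_to_json(clusters: Sequence[TagCluster]) -> list[dict]:
    out = []
    for c in clusters:
        out.append(
            {
                "cluster_id": c.cluster_id,
                "me_size": c.me_size,
                "me_phase": c.me_phase,
                "motif": None if c.motif is None else list(c.motif),
                "members": [
                    {
                        "species": t.species,
                        "gene_id": t.gene_id,
                        "transcript_id": t.transcript_id,
                        "dna": t.dna,
                        "me_offset": t.me_offset,
                        "exon_boundary_offsets": t.exon_boundary_offsets,
                    }
                    for t in c.members
                ],
            }
        )
    return out


def clusters_from_json(data: Sequence[dict]) -> list[TagCluster]:
    clusters = []
    for d in data:
        members = [
            MicroexonTag(
                species=m["species"],
                gene_id=m.get("gene_id", ""),
                transcript_id=m.get("transcript_id", ""),
                dna=m["dna"],
                peptide=translate(m["dna"]),
                me_size=d["me_size"],
                me_phase=d["me_phase"],
                me_offset=m["me_offset"],
                exon_boundary_offsets=list(m["exon_boundary_offsets"]),
            )
            for m in d["members"]
        ]
        clusters.append(
            TagCluster(
                cluster_id=d["cluster_id"],
                me_size=d["me_size"],
                me_phase=d["me_phase"],
                members=members,
                motif=None if d.get("motif") is None else tuple(d["motif"]),
            )
        )
    return clusters


def make_peptide_aligner(gap_open: float = -10.0, gap_extend: float = -0.5) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def cluster_tags(
    tags: Sequence[MicroexonTag],
    score_cutoff: float = 50.0,
    min_species: int = 3,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> list[TagCluster]:
    """Cluster microexon-tags within each (size, phase) group.

    Pairwise global peptide alignment scores under BLOSUM62 are converted
    to distances d = s_max - s and clustered with complete linkage; the
    tree is cut so that every within-cluster pair scores at least
    ``score_cutoff``. Clusters represented by fewer than ``min_species``
    distinct species are discarded. Output is order-independent.
    """
    aligner = make_peptide_aligner(gap_open, gap_extend)
    groups: dict[tuple[int, int], list[MicroexonTag]] = {}
    for t in tags:
        groups.setdefault((t.me_size, t.me_phase), []).append(t)
    clusters = []
    for (size, phase) in sorted(groups):
        members = sorted(groups[(size, phase)], key=lambda t: t.tag_id)
        n = len(members)
        if n < 2:
            continue
        scores = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                s = aligner.score(members[i].peptide, members[j].peptide)
                scores[i, j] = scores[j, i] = s
        s_max = scores[np.triu_indices(n, k=1)].max()
        dist = np.maximum(0.0, s_max - scores)
        np.fill_diagonal(dist, 0.0)
        t_cut = s_max - score_cutoff
        if t_cut < 0:
            labels = np.arange(1, n + 1)  # all singletons: no pair reaches the cutoff
        else:
            Z = linkage(squareform(dist, checks=False), method="complete")
            labels = fcluster(Z, t=t_cut, criterion="distance")
        for lab in sorted(set(labels)):
            group = [members[i] for i in range(n) if labels[i] == lab]
            if len({t.species for t in group}) < min_species:
                continue
            clusters.append(
                TagCluster(
                    cluster_id="",
                    me_size=size,
                    me_phase=phase,
                    members=sorted(group, key=lambda t: t.tag_id),
                )
            )
    clusters.sort(key=lambda c: (c.me_size, c.me_phase, c.members[0].tag_id))
    for i, c in enumerate(clusters, start=1):
        c.cluster_id = f"cluster{i}"
    return clusters


def has_inframe_stop(dna: str) -> bool:
    coding = dna[: len(dna) - len(dna) % 3]
    return any(coding[i : i + 3] in STOP_CODONS for i in range(0, len(coding), 3))


def filter_homolog_sequences(
    candidates: Sequence[str], cluster: TagCluster
) -> list[str]:
    """Clean homologous coding fragments for PWM construction.

    Drops fragments with in-frame stop codons and fragments shorter than
    the cluster tag length; longer fragments are trimmed to the tag length.
    The surviving fragments are merged with the member tag DNAs and
    deduplicated (first occurrence wins).
    """
    tag_len = cluster.tag_len
    kept = [t.dna for t in cluster.members if len(t.dna) == tag_len]
    for seq in candidates:
        seq = seq.upper()
        if len(seq) < tag_len:
            continue
        seq = seq[:tag_len]
        if has_inframe_stop(seq):
            continue
        kept.append(seq)
    seen = set()
    unique = []
    for seq in kept:
        if seq not in seen:
            seen.add(seq)
            unique.append(seq)
    if not unique:
        logger.warning("cluster %s has no usable sequences", cluster.cluster_id)
    return unique


def assign_protein_motif(
    tag: MicroexonTag,
    motif_hits: Sequence[tuple[str, tuple[int, int], float]],
    margin: int = 5,
) -> Optional[tuple[str, float]]:
    """Assign the microexon-encoded residues to a protein motif.

    ``motif_hits`` are (name, (aa_start, aa_end), E-value) intervals on the
    parent peptide. The microexon residues must lie within a motif interval
    extended by ``margin`` aa on each side; among several hits the smallest
    E-value wins.
    """
    me_lo, me_hi = tag.me_peptide_interval()
    eligible = [
        (name, ev)
        for name, (m_lo, m_hi), ev in motif_hits
        if m_lo - margin <= me_lo and me_hi <= m_hi + margin
    ]
    if not eligible:
        return None
    return min(eligible, key=lambda x: (x[1], x[0]))
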