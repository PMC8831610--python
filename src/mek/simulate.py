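"""Seeded synthetic fixtures: genomes with planted microexon genes, exact
spliced reads, fraction-specific intron retention, and mutated cross-species
tag families.

Every generator is deterministic under its seed. Reads are error-free by
default (an optional uniform substitution rate is available): the fixtures
exercise the toolkit's logic, not aligner robustness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .models import Genome, GenomeSequence, TranscriptModel, reverse_complement
from .tags import MicroexonTag

_CODON_TABLE = unambiguous_dna_by_id[1]
NON_STOP_CODONS = sorted(_CODON_TABLE.forward_table)
_SYNONYMS: dict[str, list[str]] = {}
for codon, aa in _CODON_TABLE.forward_table.items():
    _SYNONYMS.setdefault(aa, []).append(codon)
for aa in _SYNONYMS:
    _SYNONYMS[aa].sort()

# Microexon phase proportions follow the composition of conserved plant
# clusters (roughly 16:21:8 for phases 0:1:2); sizes are weighted toward
# 9 nt, the most abundant flowering-plant microexon length.
DEFAULT_PHASE_WEIGHTS = {0: 16, 1: 21, 2: 8}
DEFAULT_SIZE_WEIGHTS = {s: (3.0 if s == 9 else 1.0) for s in range(1, 16)}


@dataclass
class FixtureSpec:
    """Parameters of a synthetic microexon fixture."""

    seed: int = 0
    n_genes: int = 50
    me_size_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SIZE_WEIGHTS)
    )
    me_phase_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_PHASE_WEIGHTS)
    )
    n_exons: int = 5
    exon_len_range: tuple[int, int] = (90, 200)
    intron_len_range: tuple[int, int] = (80, 400)
    intergenic_len_range: tuple[int, int] = (300, 800)
    psi: float = 1.0
    retention: dict[str, float] = field(default_factory=dict)  # fraction -> rate
    read_length: int = 100
    depth: float = 30.0
    error_rate: float = 0.0
    n_species: int = 10
    mutation_rate: float = 0.1
    gc: float = 0.36

    def __post_init__(self) -> None:
        lo, hi = self.intron_len_range
        if lo < 20 or hi > 20000:
            raise ValueError("intron lengths must lie within [20, 20000]")
        if not 0.0 <= self.psi <= 1.0:
            raise ValueError("psi must be in [0, 1]")


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.36) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def random_intron(rng: np.random.Generator, length: int, gc: float = 0.36) -> str:
    if length < 4:
        raise ValueError("intron must be at least 4 nt")
    return "GT" + random_dna(rng, length - 4, gc) + "AG"


def random_coding(rng: np.random.Generator, n_codons: int) -> str:
    """Random in-frame coding sequence: ATG, non-stop codons, stop."""
    if n_codons < 2:
        raise ValueError("need at least start and stop codons")
    body = rng.choice(NON_STOP_CODONS, size=n_codons - 2)
    stop = rng.choice(["TAA", "TAG", "TGA"])
    return "ATG" + "".join(body) + stop


def _pick(rng: np.random.Generator, weights: dict) -> int:
    keys = sorted(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    return int(rng.choice(keys, p=p / p.sum()))


def generate_genome(
    spec: FixtureSpec,
) -> tuple[Genome, list[TranscriptModel], pd.DataFrame]:
    """Generate a genome of multi-exon genes each carrying one microexon.

    Every gene has ``n_exons`` coding exons (the middle one is the
    microexon) separated by canonical GT..AG introns; the single ORF spans
    all exons with the microexon at its requested phase. Returns the
    genome, transcript models (CDS == exons), and a ground-truth table.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.n_exons < 3 or spec.n_exons % 2 == 0:
        raise ValueError("n_exons must be odd and >= 3")
    chrom = "chr1"
    pieces: list[str] = []
    pos = 0
    models = []
    truth_rows = []
    k_flank = spec.n_exons // 2
    for g in range(spec.n_genes):
        me_size = _pick(rng, spec.me_size_weights)
        me_phase = _pick(rng, spec.me_phase_weights)
        exon_lens = list(
            rng.integers(spec.exon_len_range[0], spec.exon_len_range[1] + 1, spec.n_exons - 1)
        )
        up_lens = [int(x) for x in exon_lens[:k_flank]]
        down_lens = [int(x) for x in exon_lens[k_flank:]]
        # Adjust the last upstream exon so the CDS offset of the microexon
        # matches the requested phase, then the last exon so the total CDS
        # is a whole number of codons.
        delta = (me_phase - sum(up_lens)) % 3
        up_lens[-1] += delta
        total = sum(up_lens) + me_size + sum(down_lens)
        down_lens[-1] += (-total) % 3
        total = sum(up_lens) + me_size + sum(down_lens)
        cds = random_coding(rng, total // 3)
        cuts = np.cumsum(up_lens + [me_size] + down_lens)[:-1]
        exon_seqs = [
            cds[s:e] for s, e in zip([0] + list(cuts), list(cuts) + [total])
        ]
        spacer = random_dna(
            rng, int(rng.integers(*spec.intergenic_len_range)), spec.gc
        )
        pieces.append(spacer)
        pos += len(spacer)
        exons = []
        introns = []
        for i, es in enumerate(exon_seqs):
            exons.append((pos, pos + len(es)))
            pieces.append(es)
            pos += len(es)
            if i < len(exon_seqs) - 1:
                ilen = int(rng.integers(*spec.intron_len_range))
                iseq = random_intron(rng, ilen, spec.gc)
                introns.append((pos, pos + ilen))
                pieces.append(iseq)
                pos += ilen
        gene_id = f"g{g + 1:03d}"
        models.append(
            TranscriptModel(
                transcript_id=gene_id + ".1",
                gene_id=gene_id,
                chrom=chrom,
                strand="+",
                exons=exons,
                cds=list(exons),
            )
        )
        me = exons[k_flank]
        truth_rows.append(
            {
                "gene_id": gene_id,
                "chrom": chrom,
                "strand": "+",
                "me_start": me[0],
                "me_end": me[1],
                "me_size": me_size,
                "me_phase": me_phase,
                "psi": spec.psi,
                "up_intron_start": introns[k_flank - 1][0],
                "up_intron_end": introns[k_flank - 1][1],
                "down_intron_start": introns[k_flank][0],
                "down_intron_end": introns[k_flank][1],
            }
        )
    tail = random_dna(rng, int(rng.integers(*spec.intergenic_len_range)), spec.gc)
    pieces.append(tail)
    genome = Genome.from_sequences([GenomeSequence(chrom, "".join(pieces))])
    truth = pd.DataFrame(truth_rows)
    return genome, models, truth


def layout_to_cigar(
    segments: Sequence[tuple[int, int]], start_offset: int, read_len: int
) -> tuple[int, str]:
    """Map a read placed at a spliced-coordinate offset to (pos, CIGAR).

    ``segments`` are the genomic intervals of the isoform in genomic order.
    """
    remaining = read_len
    t = start_offset
    pos = None
    ops = []
    for s, e in segments:
        ln = e - s
        if t >= ln:
            t -= ln
            continue
        take = min(ln - t, remaining)
        if pos is None:
            pos = s + t
        else:
            ops.append((prev_end, s))  # intron gap
        ops.append(("M", take))
        prev_end = s + t + take
        remaining -= take
        t = 0
        if remaining == 0:
            break
    if remaining > 0 or pos is None:
        raise ValueError("read does not fit the isoform")
    cigar = ""
    for item in ops:
        if item[0] == "M":
            cigar += f"{item[1]}M"
        else:
            cigar += f"{item[1] - item[0]}N"
    return pos, cigar


def _isoform_segments(
    exons: Sequence[tuple[int, int]], drop_exon: Optional[int] = None
) -> list[tuple[int, int]]:
    return [tuple(e) for i, e in enumerate(exons) if i != drop_exon]


def simulate_reads(
    genome: Genome,
    models: Sequence[TranscriptModel],
    spec: FixtureSpec,
    truth: Optional[pd.DataFrame] = None,
    fraction: Optional[str] = None,
    seed_offset: int = 0,
    return_provenance: bool = False,
):
    """Simulate error-free spliced reads as SAM text.

    Molecule classes per gene are the microexon-inclusion isoform (weight
    ``psi``), the skipping isoform (``1 - psi``) and, when ``fraction`` has
    a retention rate, inclusion molecules independently retaining each
    microexon-flanking intron at that rate. Reads sample (molecule,
    position) pairs uniformly over transcribed bases, i.e. classes
    contribute in proportion to abundance x length, as in real RNA-seq.
    CIGARs are exact; all records carry NH:i:1.

    With ``return_provenance`` also returns, per read, the isoform's
    genomic segments and the read's offset along the spliced molecule.
    """
    rng = np.random.default_rng(spec.seed + 104729 + seed_offset)
    retention = spec.retention.get(fraction, 0.0) if fraction else 0.0
    me_index = spec.n_exons // 2
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name, gs in sorted(genome.items()):
        lines.append(f"@SQ\tSN:{name}\tLN:{len(gs)}")
    rid = 0
    provenance = []
    for tx in models:
        exons = tx.exons
        iso_incl = _isoform_segments(exons)
        iso_excl = _isoform_segments(exons, drop_exon=me_index)
        r = retention
        classes: list[tuple[list[tuple[int, int]], float]] = []
        if spec.psi > 0:
            base = list(iso_incl)
            ret_down = _merge_intron(base, me_index)
            ret_up = _merge_intron(base, me_index - 1)
            ret_both = _merge_intron(ret_down, me_index - 1)
            classes += [
                (base, spec.psi * (1 - r) * (1 - r)),
                (ret_up, spec.psi * r * (1 - r)),
                (ret_down, spec.psi * (1 - r) * r),
                (ret_both, spec.psi * r * r),
            ]
        if spec.psi < 1:
            classes.append((list(iso_excl), 1 - spec.psi))
        classes = [
            (segs, w)
            for segs, w in classes
            if w > 0 and sum(e - s for s, e in segs) >= spec.read_length
        ]
        lengths = np.array([sum(e - s for s, e in segs) for segs, _ in classes])
        weights = np.array([w for _, w in classes]) * lengths
        n_reads = int(round(spec.depth * weights.sum() / spec.read_length))
        if n_reads == 0 or not classes:
            continue
        p = weights / weights.sum()
        for _ in range(n_reads):
            ci = int(rng.choice(len(classes), p=p))
            segs = classes[ci][0]
            slen = int(lengths[ci])
            off = int(rng.integers(0, slen - spec.read_length + 1))
            pos, cigar = layout_to_cigar(segs, off, spec.read_length)
            seq = _spliced_read_seq(genome, tx.chrom, segs, off, spec.read_length)
            if spec.error_rate > 0:
                seq = _mutate_read(rng, seq, spec.error_rate)
            rid += 1
            if return_provenance:
                provenance.append(
                    {
                        "qname": f"r{rid:07d}",
                        "gene_id": tx.gene_id,
                        "segments": segs,
                        "offset": off,
                        "read_len": spec.read_length,
                    }
                )
            lines.append(
                "\t".join(
                    [
                        f"r{rid:07d}",
                        "0",
                        tx.chrom,
                        str(pos + 1),
                        "255",
                        cigar,
                        "*",
                        "0",
                        "0",
                        seq,
                        "*",
                        "NH:i:1",
                    ]
                )
            )
    sam = "\n".join(lines) + "\n"
    if return_provenance:
        return sam, provenance
    return sam


def _merge_intron(
    segs: list[tuple[int, int]], intron_index: int
) -> list[tuple[int, int]]:
    """Retain the intron after segment ``intron_index``: merge the two exons."""
    out = [list(s) for s in segs]
    a, b = out[intron_index], out[intron_index + 1]
    out[intron_index : intron_index + 2] = [[a[0], b[1]]]
    return [tuple(s) for s in out]


def _spliced_read_seq(genome, chrom, segs, off, read_len) -> str:
    full = "".join(genome.fetch(chrom, s, e) for s, e in segs)
    return full[off : off + read_len]


def _mutate_read(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = "ACGT"[int(rng.integers(0, 4))]
    return "".join(out)


def mutate_homologs(
    tag: MicroexonTag,
    n_species: int,
    rate: float,
    seed: int = 0,
    synonymous_bias: float = 0.7,
) -> list[MicroexonTag]:
    """Derive a cross-species tag family by seeded point mutation.

    Per-site mutation at the given rate with a synonymous bias: most
    mutated codons are swapped for a synonymous codon, the rest get a
    single random substitution that never creates a stop codon. Frame,
    microexon size/offset and exon boundaries are preserved.
    """
    if not 0.0 <= rate <= 0.3:
        raise ValueError("rate must be in [0, 0.3]")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_species):
        dna = list(tag.dna)
        n_codons = len(dna) // 3
        for c in range(n_codons):
            lo = c * 3
            codon = "".join(dna[lo : lo + 3])
            if codon in ("TAA", "TAG", "TGA"):
                continue
            p_codon = 1 - (1 - rate) ** 3
            if rng.random() >= p_codon:
                continue
            aa = _CODON_TABLE.forward_table.get(codon)
            syn = [c2 for c2 in _SYNONYMS.get(aa, []) if c2 != codon]
            if syn and rng.random() < synonymous_bias:
                new = syn[int(rng.integers(0, len(syn)))]
            else:
                for _ in range(10):
                    j = int(rng.integers(0, 3))
                    b = "ACGT"[int(rng.integers(0, 4))]
                    cand = codon[:j] + b + codon[j + 1 :]
                    if cand not in ("TAA", "TAG", "TGA") and cand != codon:
                        new = cand
                        break
                else:
                    new = codon
            dna[lo : lo + 3] = list(new)
        seq = "".join(dna)
        from .tags import translate

        out.append(
            MicroexonTag(
                species=f"sp{i + 1:02d}",
                gene_id=tag.gene_id,
                transcript_id=tag.transcript_id,
                dna=seq,
                peptide=translate(seq),
                me_size=tag.me_size,
                me_phase=tag.me_phase,
                me_offset=tag.me_offset,
                exon_boundary_offsets=list(tag.exon_boundary_offsets),
            )
        )
    return out


def embed_tag_locus(
    tag: MicroexonTag,
    rng: np.random.Generator,
    intron_len_range: tuple[int, int] = (60, 300),
    with_introns: bool = True,
    gc: float = 0.36,
) -> tuple[str, Optional[tuple[int, int]]]:
    """Render a tag as a genomic locus string.

    With introns, a canonical GT..AG intron is inserted at every exon
    boundary of the tag (so the microexon keeps both flanking introns);
    without, the tag is left contiguous (microexon merged into one exon).
    Returns the locus sequence and the microexon interval within it.
    """
    if not with_introns:
        return tag.dna, (tag.me_offset, tag.me_offset + tag.me_size)
    parts = []
    cuts = [0] + sorted(tag.exon_boundary_offsets) + [len(tag.dna)]
    me_start_local = None
    offset = 0
    for s, e in zip(cuts, cuts[1:]):
        if s == tag.me_offset:
            me_start_local = offset
        parts.append(tag.dna[s:e])
        offset += e - s
        if e < len(tag.dna):
            ilen = int(rng.integers(*intron_len_range))
            parts.append(random_intron(rng, ilen, gc))
            offset += ilen
    me = None
    if me_start_local is not None:
        me = (me_start_local, me_start_local + tag.me_size)
    return "".join(parts), me


def build_scan_fixture(
    tags: Sequence[MicroexonTag],
    seed: int = 0,
    merged: Sequence[bool] | None = None,
    bg_len: int = 3000,
    intron_len_range: tuple[int, int] = (60, 300),
    gc: float = 0.36,
) -> tuple[dict[str, Genome], pd.DataFrame]:
    """One genome per tag species, each embedding that species' tag locus.

    ``merged[i]`` embeds tag i without introns (microexon merged). Returns
    per-species genomes and a truth table of embedded locus coordinates.
    """
    rng = np.random.default_rng(seed)
    merged = list(merged) if merged is not None else [False] * len(tags)
    genomes = {}
    rows = []
    for tag, is_merged in zip(tags, merged):
        locus, me = embed_tag_locus(
            tag, rng, intron_len_range, with_introns=not is_merged, gc=gc
        )
        left = random_dna(rng, bg_len // 2, gc)
        right = random_dna(rng, bg_len // 2, gc)
        seq = left + locus + right
        name = f"chr_{tag.species}"
        genomes[tag.species] = Genome.from_sequences([GenomeSequence(name, seq)])
        rows.append(
            {
                "species": tag.species,
                "chrom": name,
                "locus_start": len(left),
                "locus_end": len(left) + len(locus),
                "merged": is_merged,
                "me_start": None if me is None else len(left) + me[0],
                "me_end": None if me is None else len(left) + me[1],
            }
        )
    return genomes, pd.DataFrame(rows)


def embed_loci(
    tags: Sequence[MicroexonTag],
    merged: Sequence[bool],
    seed: int = 0,
    spacer_len: int = 2000,
    intron_len_range: tuple[int, int] = (60, 300),
    chrom: str = "chr1",
    gc: float = 0.36,
) -> tuple[Genome, pd.DataFrame]:
    """Embed several tag loci on one chromosome, separated by background.

    ``merged[i]`` renders tag i without introns (microexon merged into a
    long exon). Returns the genome and a table of locus coordinates.
    """
    rng = np.random.default_rng(seed)
    pieces = [random_dna(rng, spacer_len, gc)]
    pos = spacer_len
    rows = []
    for tag, is_merged in zip(tags, merged):
        locus, me = embed_tag_locus(
            tag, rng, intron_len_range, with_introns=not is_merged, gc=gc
        )
        rows.append(
            {
                "species": tag.species,
                "locus_start": pos,
                "locus_end": pos + len(locus),
                "merged": is_merged,
                "me_start": None if me is None else pos + me[0],
                "me_end": None if me is None else pos + me[1],
            }
        )
        pieces.append(locus)
        pos += len(locus)
        pieces.append(random_dna(rng, spacer_len, gc))
        pos += spacer_len
    genome = Genome.from_sequences([GenomeSequence(chrom, "".join(pieces))])
    return genome, pd.DataFrame(rows)


def revcomp_fixture(genome: Genome) -> Genome:
    """Reverse-complement every chromosome (for strand-symmetry checks)."""
    return Genome.from_sequences(
        [GenomeSequence(name, reverse_complement(gs.seq)) for name, gs in genome.items()]
    )
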