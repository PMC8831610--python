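"""Readers and writers: FASTA, GTF/GFF3, SAM text, junction tables, call GTF.

This is the single conversion point between file coordinates (1-based
inclusive) and internal coordinates (0-based half-open).
"""

from __future__ import annotations

import logging
import os
import re
import tempfile
from typing import Iterator, Optional

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO

from .models import (
    JUNCTION_COLUMNS,
    AlignmentRecord,
    GenomeSequence,
    JunctionTable,
    TranscriptModel,
)

logger = logging.getLogger("mek")

_NON_ACGTN = re.compile(r"[^ACGTN]")


def read_fasta(path: str) -> list[GenomeSequence]:
    """Read a (multi-)FASTA file into uppercase DNA sequences.

    Characters outside {A,C,G,T,N} (e.g. IUPAC ambiguity codes) are mapped
    to N with a warning. Duplicate names and empty files are hard errors.
    """
    records = []
    names = set()
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in names:
            raise ValueError(f"duplicate sequence name {rec.id!r} in {path}")
        names.add(rec.id)
        seq = str(rec.seq).upper()
        n_bad = len(_NON_ACGTN.findall(seq))
        if n_bad:
            logger.warning(
                "%s: %d non-ACGTN characters in %s mapped to N", path, n_bad, rec.id
            )
            seq = _NON_ACGTN.sub("N", seq)
        records.append(GenomeSequence(rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def _check_gtf_lines(path: str) -> None:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.rstrip("\n").split("\t")) != 9:
                raise ValueError(f"{path}:{i}: malformed GTF/GFF line")


def _transcript_ids(feature) -> list[str]:
    # GTF uses transcript_id; GFF3 uses Parent (possibly multi-valued)
    if "transcript_id" in feature.attributes:
        return list(feature.attributes["transcript_id"])
    if "Parent" in feature.attributes:
        return list(feature.attributes["Parent"])
    return []


def read_gtf(path: str) -> list[TranscriptModel]:
    """Read transcripts (exon + CDS features) from a GTF or GFF3 file.

    File coordinates are 1-based inclusive; intervals are converted to
    0-based half-open. Minus-strand exon lists are kept in genomic order.
    """
    _check_gtf_lines(path)
    db = gffutils.create_db(
        path,
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    exons: dict[str, dict] = {}
    for ftype, slot in (("exon", "exons"), ("CDS", "cds")):
        for feat in db.features_of_type(ftype):
            for tid in _transcript_ids(feat):
                entry = exons.setdefault(
                    tid,
                    {
                        "gene_id": feat.attributes.get("gene_id", [tid])[0],
                        "chrom": feat.seqid,
                        "strand": feat.strand,
                        "exons": [],
                        "cds": [],
                    },
                )
                entry[slot].append((feat.start - 1, feat.end))
    models = []
    for tid, entry in exons.items():
        if not entry["exons"]:
            logger.warning("transcript %s has no exons; skipped", tid)
            continue
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=entry["gene_id"],
                chrom=entry["chrom"],
                strand=entry["strand"],
                exons=sorted(entry["exons"]),
                cds=sorted(entry["cds"]) or None,
            )
        )
    return models


def _cigartuples_to_ops(cigartuples) -> list[tuple[str, int]]:
    # pysam op codes: 0 M, 1 I, 2 D, 3 N, 4 S, 5 H, 7 =, 8 X
    code = "MIDNSHP=X"
    return [(code[op], ln) for op, ln in cigartuples]


def _ensure_header(path: str) -> str:
    """Return a readable SAM path, synthesizing @SQ lines when absent.

    pysam cannot iterate a headerless SAM; reference names are collected
    from the alignment lines and given a large placeholder length.
    """
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("@"):
        return path
    names: list[str] = []
    seen = set()
    with open(path) as fh:
        for line in fh:
            if line.startswith("@") or not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) > 2 and fields[2] != "*" and fields[2] not in seen:
                seen.add(fields[2])
                names.append(fields[2])
    tmp = tempfile.NamedTemporaryFile(
        "w", suffix=".sam", delete=False, dir=os.path.dirname(path) or "."
    )
    with tmp, open(path) as fh:
        for name in names:
            tmp.write(f"@SQ\tSN:{name}\tLN:536870912\n")
        for line in fh:
            tmp.write(line)
    return tmp.name


def read_sam(path: str) -> Iterator[AlignmentRecord]:
    """Stream mapped primary alignments from a SAM text file.

    Unmapped (0x4), secondary (0x100) and supplementary (0x800) records are
    dropped, as are mapped records with a '*' CIGAR (with a warning).
    POS is converted to 0-based.
    """
    real = _ensure_header(path)
    try:
        with pysam.AlignmentFile(real, "r", check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                if rec.cigartuples is None:
                    logger.warning("mapped record %s has no CIGAR; dropped", rec.query_name)
                    continue
                nh: Optional[int] = None
                if rec.has_tag("NH"):
                    nh = int(rec.get_tag("NH"))
                yield AlignmentRecord(
                    qname=rec.query_name,
                    chrom=rec.reference_name,
                    pos=rec.reference_start,
                    mapq=rec.mapping_quality,
                    cigar=_cigartuples_to_ops(rec.cigartuples),
                    nh=nh,
                )
    finally:
        if real != path:
            os.unlink(real)


def write_junction_table(table: JunctionTable, path: str) -> None:
    """Write a tab-separated junction table (1-based inclusive, SJ-style)."""
    out = table.df.copy()
    out["start"] = out["start"] + 1
    out = out[JUNCTION_COLUMNS]
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(JUNCTION_COLUMNS) + "\n")
        out.to_csv(fh, sep="\t", header=False, index=False)


def read_junction_table(path: str, sample_id: Optional[str] = None) -> JunctionTable:
    df = pd.read_csv(
        path, sep="\t", comment="#", names=JUNCTION_COLUMNS,
        dtype={"chrom": str, "strand": str, "motif": str},
    )
    df["start"] = df["start"] - 1
    if sample_id is None:
        sample_id = os.path.splitext(os.path.basename(path))[0]
    return JunctionTable(sample_id, df)


def write_calls_gtf(calls, path: str) -> None:
    """Write microexon calls as GTF exon features.

    Attributes carry microexon_id, size, phase (when known) and psi so the
    output can be merged into existing annotation sets.
    """
    with open(path, "w") as fh:
        fh.write("##gtf: microexon calls\n")
        for i, call in enumerate(calls):
            psi = "NA" if call.psi is None else f"{call.psi:.4f}"
            attrs = (
                f'microexon_id "me{i + 1}"; size "{call.size}"; '
                f'psi "{psi}"; status "{call.annotation_status}";'
            )
            fh.write(
                "\t".join(
                    [
                        call.chrom,
                        "mek",
                        "exon",
                        str(call.start + 1),
                        str(call.end),
                        ".",
                        call.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
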