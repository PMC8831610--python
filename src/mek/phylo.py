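"""Microexon-tag supermatrix construction for phylogenomic inference.

Tags in a cluster share one length, so per-species consensus strings are
already aligned; concatenating the per-cluster consensus blocks end to end
yields a supermatrix in which species missing a cluster carry gaps.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import AlignIO

BASE_ORDER = "ACGT"


@dataclass
class SuperMatrix:
    """Concatenated per-cluster consensus alignment over {A,C,G,T,-}."""

    species: list[str]
    cluster_ids: list[str]
    block_widths: list[int]
    rows: dict[str, str]

    @property
    def width(self) -> int:
        return sum(self.block_widths)

    def to_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for sp in self.species:
                fh.write(f">{sp}\n{self.rows[sp]}\n")

    def to_phylip(self, path: str) -> None:
        """Relaxed PHYLIP (full names, space-separated)."""
        aln = MultipleSeqAlignment(
            [SeqRecord(Seq(self.rows[sp]), id=sp, description="") for sp in self.species]
        )
        AlignIO.write(aln, path, "phylip-relaxed")

    def to_partitions(self, path: str) -> None:
        """Per-cluster block definitions in the common partition text format."""
        with open(path, "w") as fh:
            pos = 1
            for cid, w in zip(self.cluster_ids, self.block_widths):
                fh.write(f"DNA, {cid} = {pos}-{pos + w - 1}\n")
                pos += w


def consensus_string(sequences: Sequence[str]) -> str:
    """Per-site majority base over equal-length sequences.

    Ties are broken by fixed base order A < C < G < T; N is ignored when
    counting (an all-N column yields N).
    """
    if not sequences:
        raise ValueError("need at least one sequence")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"sequences must be equal length, got {sorted(lengths)}")
    out = []
    for col in zip(*[s.upper() for s in sequences]):
        counts = Counter(b for b in col if b in BASE_ORDER)
        if not counts:
            out.append("N")
            continue
        best = max(BASE_ORDER, key=lambda b: (counts.get(b, 0), -BASE_ORDER.index(b)))
        out.append(best)
    return "".join(out)


def build_supermatrix(
    consensus_by_cluster_by_species: dict[str, dict[str, str]]
) -> SuperMatrix:
    """Concatenate per-cluster consensus strings into one matrix.

    Clusters are ordered by ascending cluster id; a species missing from a
    cluster receives '-' across that block. Raises on zero clusters or
    inconsistent widths within a cluster.
    """
    if not consensus_by_cluster_by_species:
        raise ValueError("no clusters given")
    cluster_ids = sorted(consensus_by_cluster_by_species)
    species = sorted(
        {sp for d in consensus_by_cluster_by_species.values() for sp in d}
    )
    widths = []
    for cid in cluster_ids:
        block = consensus_by_cluster_by_species[cid]
        ws = {len(s) for s in block.values()}
        if len(ws) != 1:
            raise ValueError(f"cluster {cid}: inconsistent consensus widths {sorted(ws)}")
        widths.append(ws.pop())
    rows = {}
    for sp in species:
        parts = []
        for cid, w in zip(cluster_ids, widths):
            parts.append(consensus_by_cluster_by_species[cid].get(sp, "-" * w))
        rows[sp] = "".join(parts)
    return SuperMatrix(
        species=species, cluster_ids=cluster_ids, block_widths=widths, rows=rows
    )


def read_phylip(path: str) -> dict[str, str]:
    aln = AlignIO.read(path, "phylip-relaxed")
    return {rec.id: str(rec.seq) for rec in aln}
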