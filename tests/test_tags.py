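"""ORF finding, tag extraction, phase conventions, and clustering."""

import pytest

from mek import (
    Genome,
    GenomeSequence,
    MicroexonTag,
    TranscriptModel,
    assign_protein_motif,
    cluster_tags,
    extract_microexon_tag,
    filter_homolog_sequences,
    find_longest_orf,
    microexon_phase,
    orf_from_transcript,
)
from mek.tags import make_peptide_aligner, read_tags_fasta, translate, write_tags_fasta


class TestFindLongestOrf:
    def test_simple_orf_with_stop(self):
        assert find_longest_orf("AAATGGCCTAAGG") == (2, 11)

    def test_tie_broken_five_prime(self):
        # two 9-nt ORFs in different frames; the 5'-most wins
        seq = "ATGAAATAGCATGAAATAGC"
        assert find_longest_orf(seq) == (0, 9)

    def test_no_atg(self):
        assert find_longest_orf("CCCTTTGGGAAA") is None

    def test_runs_to_transcript_end_without_stop(self):
        assert find_longest_orf("ATGGCCGCC") == (0, 9)

    def test_min_len_filter(self):
        assert find_longest_orf("AAATGGCCTAAGG", min_len=30) is None


def microexon_gene(me_dna, upstream_last, downstream_first2):
    """Build a 3-exon gene whose middle exon is the given microexon.

    The upstream exon ends with ``upstream_last`` (the first nt of the codon
    the microexon interrupts: phase 1) and the downstream exon starts with
    ``downstream_first2``.
    """
    exon1 = "ATG" + "GCT" * 19 + upstream_last  # 61 nt, CDS offset of me = 61
    exon3 = downstream_first2 + "GCT" * 5 + "TAA"
    intron = "GT" + "C" * 96 + "AG"
    pad = "T" * 100
    seq = pad + exon1 + intron + me_dna + intron + exon3 + pad
    s1 = len(pad)
    e1 = s1 + len(exon1)
    s2 = e1 + len(intron)
    e2 = s2 + len(me_dna)
    s3 = e2 + len(intron)
    e3 = s3 + len(exon3)
    genome = Genome.from_sequences([GenomeSequence("c1", seq)])
    tx = TranscriptModel("t1", "g1", "c1", "+",
                         [(s1, e1), (s2, e2), (s3, e3)],
                         cds=[(s1, e1), (s2, e2), (s3, e3)])
    return genome, tx, (s2, e2)


class TestPhaseAndWorkedExamples:
    def test_phase_zero_at_codon_boundary(self, small_fixture):
        spec, genome, models, truth = small_fixture
        for _, row in truth.iterrows():
            tx = [m for m in models if m.gene_id == row.gene_id][0]
            orf = orf_from_transcript(tx, genome)
            assert microexon_phase(orf, (row.me_start, row.me_end)) == row.me_phase

    def test_ap2_microexon_translates_vylg_in_phase_1(self):
        # AP2-type 9-nt microexon: with one upstream nt and two downstream
        # nt it completes the codons for V-Y-L-G.
        genome, tx, me = microexon_gene("TGTACCTGG", "G", "GA")
        orf = orf_from_transcript(tx, genome)
        assert microexon_phase(orf, me) == 1
        tag = extract_microexon_tag(orf, me)
        assert tag.me_phase == 1
        assert "VYLG" in tag.peptide
        lo, hi = tag.me_peptide_interval()
        assert "VYLG" == tag.peptide[lo : hi]

    def test_invertase_microexon_translates_dpng_in_phase_1(self):
        genome, tx, me = microexon_gene("ATCCAAATG", "G", "GA")
        orf = orf_from_transcript(tx, genome)
        assert microexon_phase(orf, me) == 1
        tag = extract_microexon_tag(orf, me)
        assert "DPNG" in tag.peptide


class TestExtractTag:
    def test_full_length_tag_is_108nt_36aa(self, tag_family):
        tag, _ = tag_family
        assert len(tag.dna) == 108
        assert len(tag.peptide) == 36
        assert "*" not in tag.peptide
        assert len(tag.dna) % 3 == 0

    def test_truncated_near_orf_start_stays_in_frame(self):
        genome, tx, me = microexon_gene("TGTACCTGG", "G", "GA")
        orf = orf_from_transcript(tx, genome)
        tag = extract_microexon_tag(orf, me)
        # ORF is only 90 nt (87 coding): the tag must be shorter but in frame
        assert len(tag.dna) < 108
        assert len(tag.dna) % 3 == 0
        assert "*" not in tag.peptide

    def test_exon_boundaries_recorded_around_microexon(self, tag_family):
        tag, _ = tag_family
        assert tag.me_offset in tag.exon_boundary_offsets
        assert tag.me_offset + tag.me_size in tag.exon_boundary_offsets

    def test_microexon_centered(self, tag_family):
        tag, _ = tag_family
        left = tag.me_offset
        right = len(tag.dna) - (tag.me_offset + tag.me_size)
        assert abs(left - right) <= 2


def synth_tag(species, dna, size=9, phase=0, offset=48):
    return MicroexonTag(
        species=species, gene_id="g", transcript_id=f"t_{species}", dna=dna,
        peptide=translate(dna), me_size=size, me_phase=phase, me_offset=offset,
        exon_boundary_offsets=[offset, offset + size],
    )


class TestClusterTags:
    def test_identical_tags_across_four_species_form_one_cluster(self):
        dna = "GCTGAAGTT" * 12
        tags = [synth_tag(f"sp{i}", dna) for i in range(4)]
        clusters = cluster_tags(tags)
        assert len(clusters) == 1
        assert len(clusters[0].members) == 4

    def test_two_species_cluster_discarded(self):
        dna = "GCTGAAGTT" * 12
        tags = [synth_tag("sp1", dna), synth_tag("sp2", dna)]
        assert cluster_tags(tags) == []

    def test_unrelated_families_split_by_score(self):
        a = "GCT" * 36  # poly-Ala peptide
        b = "TGG" * 36  # poly-Trp peptide
        tags = [synth_tag(f"sp{i}", a) for i in range(3)] + [
            synth_tag(f"sp{i}", b) for i in range(3, 6)
        ]
        clusters = cluster_tags(tags)
        assert len(clusters) == 2
        # brute-force check: every within-cluster pair scores >= 50,
        # every cross-cluster pair below
        aligner = make_peptide_aligner()
        for c in clusters:
            for t1 in c.members:
                for t2 in c.members:
                    assert aligner.score(t1.peptide, t2.peptide) >= 50
        s_cross = aligner.score(translate(a), translate(b))
        assert s_cross < 50

    def test_size_phase_homogeneity_and_no_mixing(self):
        dna = "GCTGAAGTT" * 12
        tags = [synth_tag(f"sp{i}", dna, size=9) for i in range(3)] + [
            synth_tag(f"sp{i}", dna, size=6) for i in range(3, 6)
        ]
        clusters = cluster_tags(tags)
        assert len(clusters) == 2
        for c in clusters:
            assert len({t.me_size for t in c.members}) == 1

    def test_order_invariance(self, tag_family):
        _, family = tag_family
        c1 = cluster_tags(family)
        c2 = cluster_tags(list(reversed(family)))
        ids1 = [[t.tag_id for t in c.members] for c in c1]
        ids2 = [[t.tag_id for t in c.members] for c2 in [c2] for c in c2]
        assert ids1 == ids2

    def test_mutated_family_recovered_as_one_cluster(self, tag_cluster, tag_family):
        _, family = tag_family
        assert len(tag_cluster.members) == len(family)
        assert tag_cluster.me_size == 9 and tag_cluster.me_phase == 1


class TestFilterHomologs:
    def test_rules(self, tag_cluster):
        member = tag_cluster.members[0].dna
        with_stop = member[:30] + "TAA" + member[33:]
        short = member[:90]
        long = member + "GCTGCT"
        out = filter_homolog_sequences([with_stop, short, member, long], tag_cluster)
        assert with_stop not in out
        assert short not in out
        assert out.count(member) == 1  # deduplicated against member tags
        assert member + "GCTGCT" not in out  # trimmed to tag length
        assert all(len(s) == tag_cluster.tag_len for s in out)


class TestAssignMotif:
    def tag(self):
        dna = "GCTGAAGTT" * 12
        return synth_tag("sp1", dna, offset=48)  # residues [16, 19)

    def test_within_margin_assigned(self):
        # motif starting 3 aa after the microexon residues end
        hit = ("PF1", (20, 30), 1e-10)
        assert assign_protein_motif(self.tag(), [hit]) == ("PF1", 1e-10)

    def test_outside_margin_not_assigned(self):
        hit = ("PF1", (25, 30), 1e-10)
        assert assign_protein_motif(self.tag(), [hit]) is None

    def test_smallest_evalue_wins(self):
        hits = [("PF1", (10, 25), 1e-5), ("PF2", (12, 26), 1e-30)]
        assert assign_protein_motif(self.tag(), hits) == ("PF2", 1e-30)


def test_tag_fasta_round_trip(tmp_path, tag_family):
    _, family = tag_family
    p = tmp_path / "tags.fa"
    write_tags_fasta(family, str(p))
    back = read_tags_fasta(str(p))
    assert [t.tag_id for t in back] == [t.tag_id for t in family]
    assert [t.dna for t in back] == [t.dna for t in family]
    assert [t.exon_boundary_offsets for t in back] == [
        t.exon_boundary_offsets for t in family
    ]
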