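import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agios.seqio import (
    GeneRecord,
    Genome,
    NucSeq,
    find_orfs,
    gc_stats,
    load_genome,
    read_fasta,
    reverse_complement,
    translate_cds,
    write_fasta,
    write_gff,
)
from agios.simulate import EvolutionParams, generate_ancestor
from agios.utils import pct

from _oracles import brute_force_orfs, resolve_overlaps

nuc_text = st.text(alphabet="ACGTN", min_size=0, max_size=60)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadFasta:
    def test_single_record(self, tmp_path):
        recs = read_fasta(_write(tmp_path, "a.fa", ">a\nACGT\n"))
        assert [(r.id, r.seq) for r in recs] == [("a", "ACGT")]

    def test_multiline_and_case_folding(self, tmp_path):
        recs = read_fasta(_write(tmp_path, "a.fa", ">a\nac\ngt\n>b\nTT\n"))
        assert [(r.id, r.seq) for r in recs] == [("a", "ACGT"), ("b", "TT")]

    def test_duplicate_id_is_error(self, tmp_path):
        with pytest.raises(ValueError, match="'a'"):
            read_fasta(_write(tmp_path, "a.fa", ">a\nACGT\n>a\nTT\n"))

    def test_empty_file_is_error(self, tmp_path):
        with pytest.raises(ValueError, match="no FASTA records"):
            read_fasta(_write(tmp_path, "a.fa", ""))

    def test_u_and_ambiguity_normalisation(self, tmp_path):
        (rec,) = read_fasta(_write(tmp_path, "a.fa", ">a\nacgu\nRYN\n"))
        assert rec.seq == "ACGTNNN"

    def test_invalid_character_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="invalid nucleotide"):
            read_fasta(_write(tmp_path, "a.fa", ">a\nAC!T\n"))

    @given(seqs=st.lists(nuc_text.filter(bool), min_size=1, max_size=5, unique=True))
    @settings(max_examples=25, derandomize=True)
    def test_write_read_roundtrip(self, tmp_path_factory, seqs):
        tmp = tmp_path_factory.mktemp("fa")
        recs = [NucSeq(f"s{i}", s) for i, s in enumerate(seqs)]
        path = tmp / "round.fa"
        write_fasta(recs, path)
        back = read_fasta(path)
        assert [(r.id, r.seq) for r in back] == [(r.id, r.seq) for r in recs]


@given(nuc_text)
@settings(derandomize=True)
def test_reverse_complement_roundtrip(s):
    assert reverse_complement(reverse_complement(s)) == s


class TestTranslate:
    @pytest.mark.parametrize(
        "nuc,prot",
        [("ATGAAATAA", "MK"), ("ATGANA", "MX"), ("GTGAAA", "VK"), ("ATGAAA", "MK")],
    )
    def test_translation(self, nuc, prot):
        assert translate_cds(NucSeq("g", nuc)).seq == prot

    def test_internal_stop_is_error(self):
        with pytest.raises(ValueError, match="internal stop"):
            translate_cds(NucSeq("g", "ATGTAAAAA"))

    def test_length_not_codon_multiple_is_error(self):
        with pytest.raises(ValueError, match="codon multiple"):
            translate_cds(NucSeq("g", "ATGA"))


class TestGcStats:
    def test_published_chromosome_counts_give_printed_percentage(self):
        # count-level reproduction of the G+C table cell
        assert pct(2_794_611, 5_546_433) == 50.39

    @pytest.mark.parametrize(
        "seqs,expect",
        [(["GGCC"], (4, 4, 100.00)), (["ATAT"], (4, 0, 0.00)),
         (["ACGTN"], (5, 2, 40.00))],
    )
    def test_small_examples(self, seqs, expect):
        assert gc_stats([NucSeq(str(i), s) for i, s in enumerate(seqs)]) == expect

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError):
            gc_stats([])

    @given(st.lists(nuc_text, min_size=1, max_size=6))
    @settings(max_examples=50, derandomize=True)
    def test_bounds_and_concatenation_invariance(self, seqs):
        seqs = [s for s in seqs if s] or ["A"]
        recs = [NucSeq(str(i), s) for i, s in enumerate(seqs)]
        total, gc, p = gc_stats(recs)
        assert 0 <= gc <= total
        assert gc_stats([NucSeq("cat", "".join(seqs))]) == (total, gc, p)


class TestLoadGenome:
    def _gff(self, tmp_path, body):
        return _write(tmp_path, "g.gff", "##gff-version 3\n" + body)

    def test_plus_strand_cds(self, tmp_path):
        fa = _write(tmp_path, "g.fa", ">c1\nATGAAATAA\n")
        gff = self._gff(tmp_path, "c1\t.\tCDS\t1\t9\t.\t+\t0\tID=g1\n")
        genome = load_genome(fa, gff)
        (g,) = genome.genes
        assert (g.nuc.seq, g.prot.seq, g.start, g.end) == ("ATGAAATAA", "MK", 0, 9)

    def test_minus_strand_reverse_complements(self, tmp_path):
        fa = _write(tmp_path, "g.fa", ">c1\nATGAAATAA\n")
        gff = self._gff(tmp_path, "c1\t.\tCDS\t1\t9\t.\t-\t0\tID=g1\n")
        (g,) = load_genome(fa, gff).genes
        assert g.nuc.seq == "TTATTTCAT"

    def test_out_of_bounds_cds_is_error(self, tmp_path):
        fa = _write(tmp_path, "g.fa", ">c1\nATGAA\n")
        gff = self._gff(tmp_path, "c1\t.\tCDS\t1\t9\t.\t+\t0\tID=g1\n")
        with pytest.raises(ValueError, match="outside"):
            load_genome(fa, gff)

    def test_bad_frame_flagged_not_fatal(self, tmp_path):
        fa = _write(tmp_path, "g.fa", ">c1\nATGAAATAAC\n")
        gff = self._gff(tmp_path, "c1\t.\tCDS\t1\t10\t.\t+\t0\tID=g1\n")
        with pytest.warns(UserWarning, match="not divisible by 3"):
            genome = load_genome(fa, gff)
        assert genome.genes[0].frame_ok is False
        assert genome.valid_genes == []

    def test_cds_fasta_only(self, tmp_path):
        cds = _write(tmp_path, "cds.fa", ">g1\nATGAAATAA\n>g2\nATGTTTTAA\n")
        genome = load_genome(cds_fasta=cds)
        assert [g.prot.seq for g in genome.genes] == ["MK", "MF"]
        assert genome.genes[0].start is None

    def test_orf_fallback_when_unannotated(self, tmp_path):
        fa = _write(tmp_path, "g.fa", ">c1\n" + "ATG" + "AAA" * 100 + "TAA\n")
        genome = load_genome(fa, min_orf_nt=300)
        assert len(genome.genes) == 1

    def test_duplicate_gene_ids_rejected(self):
        nuc = NucSeq("g1", "ATGAAATAA")
        rec = GeneRecord("g1", "c", 0, 9, "+", nuc)
        with pytest.raises(ValueError, match="duplicate gene ids"):
            Genome("G", [], [rec, rec])

    def test_gff_roundtrip_reproduces_gene_sequences(self, tmp_path):
        """Writing a simulated genome as FASTA+GFF3 and loading it back must
        reproduce every gene's extracted nucleotide sequence exactly."""
        genome = generate_ancestor(EvolutionParams(n_genes=8, seed=3))
        fa, gff = tmp_path / "g.fa", tmp_path / "g.gff"
        write_fasta(genome.contigs, fa)
        write_gff(genome, gff)
        back = load_genome(fa, gff)
        assert [(g.gene_id, g.nuc.seq) for g in back.genes] == [
            (g.gene_id, g.nuc.seq) for g in genome.genes
        ]


class TestFindOrfs:
    def test_single_constructed_orf(self):
        seq = "ATG" + "AAA" * 100 + "TAA"
        (orf,) = find_orfs(NucSeq("c", seq), min_nt=300)
        assert (orf.start, orf.end, orf.strand) == (0, len(seq), "+")
        assert orf.prot.seq == "M" + "K" * 100

    def test_all_n_contig_gives_nothing(self):
        assert find_orfs(NucSeq("c", "N" * 500)) == []

    def test_min_nt_validation(self):
        with pytest.raises(ValueError):
            find_orfs(NucSeq("c", "ACGT"), min_nt=10)

    def test_n_run_filter_drops_gap_spanning_orf(self):
        seq = "ATG" + "AAA" * 20 + "N" * 12 + "AAA" * 80 + "TAA"
        # the N run sits inside the only ORF-like span; default filter drops it
        assert find_orfs(NucSeq("c", seq), min_nt=300) == []

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_agrees_with_positional_enumeration_oracle(self, seed):
        import random

        r = random.Random(seed)
        seq = "".join(r.choice("ACGT") for _ in range(3000))
        got = [(g.start, g.end, g.strand) for g in
               find_orfs(NucSeq("c", seq), min_nt=90, max_n_run=None)]
        expected = resolve_overlaps(brute_force_orfs(seq, 90))
        assert sorted(got) == expected
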