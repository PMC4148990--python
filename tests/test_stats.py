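import random

import pytest

from agios.seqio import NucSeq
from agios.stats import (
    NEW_GENUS,
    NEW_SPECIES,
    SAME_SPECIES,
    AnnotationSummary,
    HomologyHit,
    classify_orfans,
    cog_table,
    delineate_rank,
    mean_read_length_bp,
    merged_interval_length,
    rank_report,
    sixteen_s_identity,
)
from agios.utils import round_half_up


class TestAnnotationSummary:
    def test_interval_union_arithmetic(self):
        assert merged_interval_length([(0, 100), (50, 150)]) == 150

    def test_from_counts_percentages(self):
        s = AnnotationSummary.from_counts(
            genome_size_bp=1000, gc_bp=400, coding_bp=150,
            total_genes=10, rna_genes=2, protein_coding_genes=8,
            genes_with_function=6, genes_in_cogs=5, n_orfans=1, n_hypothetical=2,
        )
        assert (s.gc_pct, s.coding_pct) == (40.0, 15.0)
        assert (s.rna_pct, s.protein_coding_pct) == (20.0, 80.0)
        assert (s.function_pct, s.cogs_pct) == (75.0, 62.5)
        assert (s.orfan_pct, s.hypothetical_pct) == (12.5, 25.0)
        s.self_check()

    def test_inconsistent_gene_totals_rejected(self):
        with pytest.raises(ValueError, match="total_genes"):
            AnnotationSummary.from_counts(1000, 400, 100, 10, 3, 8)

    def test_coding_exceeding_genome_rejected(self):
        with pytest.raises(ValueError, match="coding_bp"):
            AnnotationSummary.from_counts(100, 40, 200, 2, 1, 1)


class TestCogTable:
    def test_category_percentages_against_published_counts(self):
        rows = cog_table(
            {f"g{i}": ["G"] for i in range(560)}, n_protein_coding=5145
        )
        by_code = {r.code: r for r in rows}
        assert by_code["G"].pct == 10.88
        assert by_code["-"].count == 5145 - 560
        assert by_code["-"].pct == round_half_up(100 * (5145 - 560) / 5145)

    def test_empty_assignments_all_unassigned(self):
        rows = cog_table({}, n_protein_coding=10)
        by_code = {r.code: r for r in rows}
        assert by_code["-"].count == 10 and by_code["-"].pct == 100.0
        assert all(r.count == 0 for r in rows if r.code != "-")

    def test_multi_category_gene_increments_each(self):
        rows = cog_table({"g1": ["G", "E"], "g2": []}, n_protein_coding=2)
        by_code = {r.code: r for r in rows}
        assert by_code["G"].count == by_code["E"].count == 1
        assert by_code["-"].count == 1

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError, match="unknown COG"):
            cog_table({"g1": ["X"]}, n_protein_coding=1)

    def test_canonical_row_order(self):
        codes = [r.code for r in cog_table({}, 1)]
        assert codes[:5] == ["J", "A", "K", "L", "B"]
        assert codes[-1] == "-"
        assert len(codes) == 26


class TestClassifyOrfans:
    def test_no_hits_is_orfan(self):
        assert classify_orfans([], gene_ids=["g1"]) == {"g1": "ORFan"}

    def test_long_alignment_moderate_evalue_is_known(self):
        calls = classify_orfans([HomologyHit("g1", "s", 1e-4, 100)])
        assert calls["g1"] == "known"

    def test_short_alignment_needs_stricter_evalue(self):
        assert classify_orfans([HomologyHit("g1", "s", 1e-4, 50)])["g1"] == "ORFan"
        assert classify_orfans([HomologyHit("g1", "s", 1e-6, 50)])["g1"] == "known"

    def test_boundary_length_uses_short_tier(self):
        # exactly 80 aa falls in the stricter tier
        assert classify_orfans([HomologyHit("g1", "s", 1e-4, 80)])["g1"] == "ORFan"
        assert classify_orfans([HomologyHit("g1", "s", 1e-4, 81)])["g1"] == "known"

    def test_adding_hits_is_monotone(self):
        """Adding a hit can turn an ORFan into known, never the reverse."""
        r = random.Random(3)
        hits = []
        prev = "ORFan"
        for i in range(50):
            hits.append(
                HomologyHit("g", f"s{i}", 10 ** -r.uniform(0, 8), r.randint(10, 200))
            )
            call = classify_orfans(hits)["g"]
            assert not (prev == "known" and call == "ORFan")
            prev = call

    def test_nonpositive_evalue_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            HomologyHit("g", "s", 0.0, 50)


class TestDelineateRank:
    @pytest.mark.parametrize(
        "identity,call",
        [
            (93.72, NEW_GENUS),       # the published strain-vs-nearest value
            (94.99, NEW_GENUS),
            (95.0, NEW_SPECIES),      # genus boundary inclusive upward
            (98.69, NEW_SPECIES),
            (98.7, SAME_SPECIES),     # species boundary inclusive upward
            (100.0, SAME_SPECIES),
        ],
    )
    def test_threshold_logic(self, identity, call):
        assert delineate_rank(identity).call == call

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            delineate_rank(101.0)


class TestSixteenS:
    def _random_16s(self, seed, n=1500):
        r = random.Random(seed)
        return "".join(r.choice("ACGT") for _ in range(n))

    def test_self_identity_100(self):
        s = NucSeq("s", self._random_16s(1))
        assert sixteen_s_identity(s, s) == 100.0

    def test_five_substitutions_in_1500(self, nuc_scheme):
        """Planting 5 substitutions gives 1495/1500 = 99.67% under the
        gap-free optimum (confirmed gap-free by the alignment itself)."""
        from agios.align import global_align

        s = self._random_16s(2)
        r = random.Random(3)
        mutated = list(s)
        for i in r.sample(range(1500), 5):
            mutated[i] = r.choice([c for c in "ACGT" if c != mutated[i]])
        a, b = NucSeq("a", s), NucSeq("b", "".join(mutated))
        res = global_align(a, b, nuc_scheme)
        assert "-" not in res.aligned_a + res.aligned_b
        assert round_half_up(sixteen_s_identity(a, b), 2) == 99.67

    def test_auto_orientation_recovers_reversed_strand(self):
        s = NucSeq("s", self._random_16s(4))
        assert sixteen_s_identity(s, s.reverse_complement()) == 100.0

    def test_short_sequence_warns(self):
        s = NucSeq("s", "ACGTACGTACGT")
        with pytest.warns(UserWarning, match="16S range"):
            sixteen_s_identity(s, s)

    def test_rank_report_sorted_and_called(self):
        q = NucSeq("q", self._random_16s(5))
        r = random.Random(6)
        near = list(q.seq)
        for i in r.sample(range(1500), 30):  # 2% divergence -> ~98%
            near[i] = r.choice([c for c in "ACGT" if c != near[i]])
        refs = [NucSeq("far", self._random_16s(7)), NucSeq("near", "".join(near))]
        table, call = rank_report(q, refs)
        assert [t[0] for t in table] == ["near", "far"]
        assert call.nearest_taxon == "near"
        assert call.call == NEW_SPECIES

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError, match="empty reference"):
            rank_report(NucSeq("q", self._random_16s(8)), [])


class TestReadStats:
    def test_run_arithmetic(self):
        # 142.7 Mb over 387,157 reads -> 369 bp average
        assert mean_read_length_bp(142.7e6, 387_157) == 369

    def test_zero_reads_rejected(self):
        with pytest.raises(ValueError):
            mean_read_length_bp(100.0, 0)
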