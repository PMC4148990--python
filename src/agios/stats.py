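"""Genome-annotation summary statistics, COG category tabulation, ORFan
classification and 16S-identity rank delineation.

All percentages use round-half-up to 2 decimals. Gene-class percentages are
taken over total genes; the COG, function-assigned, ORFan and hypothetical
percentages over protein-coding genes; base-pair percentages over genome
size — the denominators under which every reproduced annotation-table cell
checks out exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .align import ScoringScheme, identity_between, nucleotide_scheme
from .seqio import Genome, NucSeq
from .utils import pct, round_half_up

GENE_CLASSES = ("protein_coding", "rRNA_16S", "rRNA_23S", "rRNA_5S", "tRNA")

# canonical report order of the 25 single-letter COG functional categories,
# then "-" for genes outside any category
COG_CATEGORIES: list[tuple[str, str]] = [
    ("J", "Translation, ribosomal structure and biogenesis"),
    ("A", "RNA processing and modification"),
    ("K", "Transcription"),
    ("L", "Replication, recombination and repair"),
    ("B", "Chromatin structure and dynamics"),
    ("D", "Cell cycle control, mitosis and meiosis"),
    ("Y", "Nuclear structure"),
    ("V", "Defense mechanisms"),
    ("T", "Signal transduction mechanisms"),
    ("M", "Cell wall/membrane biogenesis"),
    ("N", "Cell motility"),
    ("Z", "Cytoskeleton"),
    ("W", "Extracellular structures"),
    ("U", "Intracellular trafficking and secretion"),
    ("O", "Posttranslational modification, protein turnover, chaperones"),
    ("C", "Energy production and conversion"),
    ("G", "Carbohydrate transport and metabolism"),
    ("E", "Amino acid transport and metabolism"),
    ("F", "Nucleotide transport and metabolism"),
    ("H", "Coenzyme transport and metabolism"),
    ("I", "Lipid transport and metabolism"),
    ("P", "Inorganic ion transport and metabolism"),
    ("Q", "Secondary metabolites biosynthesis, transport and catabolism"),
    ("R", "General function prediction only"),
    ("S", "Function unknown"),
    ("-", "Not in COGs"),
]
COG_LETTERS = {code for code, _ in COG_CATEGORIES if code != "-"}


@dataclass
class AnnotationSummary:
    genome_size_bp: int
    gc_bp: int
    gc_pct: float
    coding_bp: int
    coding_pct: float
    total_genes: int
    rna_genes: int
    rna_pct: float
    protein_coding_genes: int
    protein_coding_pct: float
    genes_with_function: int
    function_pct: float
    genes_in_cogs: int
    cogs_pct: float
    n_orfans: int
    orfan_pct: float
    n_hypothetical: int
    hypothetical_pct: float

    @classmethod
    def from_counts(
        cls,
        genome_size_bp: int,
        gc_bp: int,
        coding_bp: int,
        total_genes: int,
        rna_genes: int,
        protein_coding_genes: int,
        genes_with_function: int = 0,
        genes_in_cogs: int = 0,
        n_orfans: int = 0,
        n_hypothetical: int = 0,
    ) -> "AnnotationSummary":
        if total_genes != rna_genes + protein_coding_genes:
            raise ValueError("total_genes must equal rna + protein-coding genes")
        if coding_bp > genome_size_bp:
            raise ValueError("coding_bp exceeds genome size")
        pc = protein_coding_genes
        return cls(
            genome_size_bp=genome_size_bp,
            gc_bp=gc_bp,
            gc_pct=pct(gc_bp, genome_size_bp),
            coding_bp=coding_bp,
            coding_pct=pct(coding_bp, genome_size_bp),
            total_genes=total_genes,
            rna_genes=rna_genes,
            rna_pct=pct(rna_genes, total_genes),
            protein_coding_genes=pc,
            protein_coding_pct=pct(pc, total_genes),
            genes_with_function=genes_with_function,
            function_pct=pct(genes_with_function, pc) if pc else 0.0,
            genes_in_cogs=genes_in_cogs,
            cogs_pct=pct(genes_in_cogs, pc) if pc else 0.0,
            n_orfans=n_orfans,
            orfan_pct=pct(n_orfans, pc) if pc else 0.0,
            n_hypothetical=n_hypothetical,
            hypothetical_pct=pct(n_hypothetical, pc) if pc else 0.0,
        )

    def self_check(self) -> None:
        """Every reported percentage must recompute from its counts."""
        assert self.gc_pct == pct(self.gc_bp, self.genome_size_bp)
        assert self.coding_pct == pct(self.coding_bp, self.genome_size_bp)
        assert self.rna_pct == pct(self.rna_genes, self.total_genes)
        assert self.protein_coding_pct == pct(
            self.protein_coding_genes, self.total_genes
        )
        pc = self.protein_coding_genes
        assert self.function_pct == pct(self.genes_with_function, pc)
        assert self.cogs_pct == pct(self.genes_in_cogs, pc)
        assert self.orfan_pct == pct(self.n_orfans, pc)
        assert self.hypothetical_pct == pct(self.n_hypothetical, pc)


def merged_interval_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total length of the union of half-open intervals (overlaps merged)."""
    ivs = sorted(intervals)
    total = 0
    cur_s = cur_e = None
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"empty interval ({s}, {e})")
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def summarize_annotation(
    genome: Genome,
    gene_classes: Mapping[str, str],
    coding_intervals: Iterable[tuple[int, int]],
    genes_with_function: int = 0,
    genes_in_cogs: int = 0,
    n_orfans: int = 0,
    n_hypothetical: int = 0,
) -> AnnotationSummary:
    """Annotation summary from a genome, per-gene class labels and the
    coding intervals (genome coordinates, half-open; union taken)."""
    for gid, cls in gene_classes.items():
        if cls not in GENE_CLASSES:
            raise ValueError(f"unknown gene class {cls!r} for {gid!r}")
    total = len(gene_classes)
    pc = sum(1 for c in gene_classes.values() if c == "protein_coding")
    return AnnotationSummary.from_counts(
        genome_size_bp=genome.total_bp,
        gc_bp=genome.gc_bp,
        coding_bp=merged_interval_length(coding_intervals),
        total_genes=total,
        rna_genes=total - pc,
        protein_coding_genes=pc,
        genes_with_function=genes_with_function,
        genes_in_cogs=genes_in_cogs,
        n_orfans=n_orfans,
        n_hypothetical=n_hypothetical,
    )


@dataclass(frozen=True)
class CogRow:
    code: str
    count: int
    pct: float
    description: str


def cog_table(
    assignments: Mapping[str, Iterable[str]], n_protein_coding: int
) -> list[CogRow]:
    """Per-category gene counts in canonical order.

    A gene with several category letters increments each (lettered counts may
    therefore exceed the gene total); genes with no letter fall under "-".
    Percentages are over protein-coding genes.
    """
    counts = {code: 0 for code, _ in COG_CATEGORIES}
    n_assigned = 0
    for gid, codes in assignments.items():
        codes = set(codes)
        bad = codes - COG_LETTERS
        if bad:
            raise ValueError(f"unknown COG code(s) {sorted(bad)} for gene {gid!r}")
        if codes:
            n_assigned += 1
            for c in codes:
                counts[c] += 1
    if n_assigned > n_protein_coding:
        raise ValueError("more assigned genes than protein-coding genes")
    counts["-"] = n_protein_coding - n_assigned
    return [
        CogRow(code, counts[code], pct(counts[code], n_protein_coding), desc)
        for code, desc in COG_CATEGORIES
    ]


@dataclass(frozen=True)
class HomologyHit:
    """One database hit for a predicted protein."""

    gene_id: str
    subject_id: str
    e_value: float
    aln_len_aa: int

    def __post_init__(self):
        if self.e_value <= 0:
            raise ValueError("e_value must be positive")


def classify_orfans(
    hits: Iterable[HomologyHit],
    gene_ids: Optional[Iterable[str]] = None,
    e_long: float = 1e-3,
    e_short: float = 1e-5,
    len_cut_aa: int = 80,
) -> dict[str, str]:
    """Two-tier ORFan call: a gene is an ORFan iff it has no qualifying hit.

    A hit qualifies when its alignment is longer than ``len_cut_aa`` amino
    acids with E-value below ``e_long``, or at most ``len_cut_aa`` with the
    stricter ``e_short``. Genes listed in ``gene_ids`` with no hits at all are
    ORFans by definition.
    """
    by_gene: dict[str, list[HomologyHit]] = {}
    for h in hits:
        by_gene.setdefault(h.gene_id, []).append(h)
    ids = set(by_gene)
    if gene_ids is not None:
        ids |= set(gene_ids)
    out = {}
    for gid in sorted(ids):
        qualifying = any(
            (h.aln_len_aa > len_cut_aa and h.e_value < e_long)
            or (h.aln_len_aa <= len_cut_aa and h.e_value < e_short)
            for h in by_gene.get(gid, ())
        )
        out[gid] = "known" if qualifying else "ORFan"
    return out


SAME_SPECIES = "same-species-candidate"
NEW_SPECIES = "new-species-candidate"
NEW_GENUS = "new-genus-candidate"


@dataclass(frozen=True)
class RankCall:
    identity_pct: float
    nearest_taxon: str
    call: str


def delineate_rank(
    identity_pct: float,
    nearest_taxon: str = "",
    genus_threshold: float = 95.0,
    species_threshold: float = 98.7,
) -> RankCall:
    """Taxonomic-rank proposal from 16S rRNA percent identity.

    Below the genus threshold (95%, the classical new-genus cut-off) the
    isolate is a new-genus candidate; between the thresholds a new species
    within the genus; at or above the species threshold (98.7% conventional)
    the same species. Boundaries are inclusive upward.
    """
    if not 0 <= identity_pct <= 100:
        raise ValueError(f"identity {identity_pct} outside [0, 100]")
    if identity_pct < genus_threshold:
        call = NEW_GENUS
    elif identity_pct < species_threshold:
        call = NEW_SPECIES
    else:
        call = SAME_SPECIES
    return RankCall(identity_pct, nearest_taxon, call)


def sixteen_s_identity(
    a: NucSeq,
    b: NucSeq,
    scheme: Optional[ScoringScheme] = None,
    auto_orient: bool = True,
) -> float:
    """Percent identity between two 16S rRNA genes by global alignment.

    Tries both strands of ``b`` when ``auto_orient`` and keeps the higher
    identity, since deposited rRNA sequences are not consistently oriented.
    """
    for s in (a, b):
        if not 1200 <= len(s.seq) <= 1800:
            warnings.warn(
                f"sequence {s.id!r} length {len(s.seq)} outside the typical "
                "16S range (1200-1800 nt)"
            )
    if scheme is None:
        scheme = nucleotide_scheme()
    ident = identity_between(a, b, scheme)
    if auto_orient:
        ident = max(ident, identity_between(a, b.reverse_complement(), scheme))
    return ident


def rank_report(
    query: NucSeq,
    references: Sequence[NucSeq],
    genus_threshold: float = 95.0,
    species_threshold: float = 98.7,
) -> tuple[list[tuple[str, float]], RankCall]:
    """Identity of the query against each reference (sorted descending) and
    the rank call against the best hit."""
    if not references:
        raise ValueError("empty reference set")
    table = sorted(
        ((r.id, sixteen_s_identity(query, r)) for r in references),
        key=lambda t: (-t[1], t[0]),
    )
    best_id, best_pct = table[0]
    return table, delineate_rank(
        round_half_up(best_pct, 2), best_id, genus_threshold, species_threshold
    )


def mean_read_length_bp(total_sequenced_bp: float, n_reads: int) -> int:
    """Average read length, rounded half-up to the nearest base."""
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    return int(round_half_up(total_sequenced_bp / n_reads, 0))
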