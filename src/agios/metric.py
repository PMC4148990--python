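"""The AGIOS statistic: mean nucleotide identity over orthologous ORFs.

For a genome pair, every RBH ortholog pair's nucleotide ORFs are globally
aligned and the per-alignment percent identities are averaged (unweighted
across gene pairs; a length-weighted mean is also carried for verbose
output). Across several genomes the results assemble into a square matrix in
the conventional comparison layout: the diagonal holds each genome's valid
gene count, the upper triangle the mean identities, the lower triangle the
ortholog counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .align import ScoringScheme, global_align, nucleotide_scheme, protein_scheme
from .orthologs import OrthologSet, reciprocal_best_hits
from .seqio import Genome
from .utils import round_half_up


@dataclass
class AgiosResult:
    """AGIOS between one genome pair."""

    genome_a_id: str
    genome_b_id: str
    n_orthologs: int
    mean_identity_pct: Optional[float]  # None (reported NA) when no orthologs
    per_pair_identities: list[float] = field(default_factory=list)
    length_weighted_mean_pct: Optional[float] = None

    def __post_init__(self):
        if self.n_orthologs != len(self.per_pair_identities):
            raise ValueError("n_orthologs inconsistent with per-pair identities")


def agios_pair(
    genome_a: Genome,
    genome_b: Genome,
    orthologs: Optional[OrthologSet] = None,
    nuc_scheme: Optional[ScoringScheme] = None,
    **rbh_kwargs,
) -> AgiosResult:
    """Mean percent nucleotide identity over the orthologous ORFs of a pair.

    ``orthologs`` may be precomputed (it must join these two genomes);
    otherwise reciprocal best hits are detected first. Symmetric in genome
    order.
    """
    if orthologs is None:
        orthologs = reciprocal_best_hits(genome_a, genome_b, **rbh_kwargs)
    ids = {orthologs.genome_a_id, orthologs.genome_b_id}
    if ids != {genome_a.genome_id, genome_b.genome_id}:
        raise ValueError("ortholog set does not join these genomes")
    if orthologs.genome_a_id != genome_a.genome_id:
        orthologs = orthologs.transposed()
    if nuc_scheme is None:
        nuc_scheme = nucleotide_scheme()

    nuc_a = {g.gene_id: g.nuc for g in genome_a.genes}
    nuc_b = {g.gene_id: g.nuc for g in genome_b.genes}
    identities = []
    weighted_num = weighted_den = 0.0
    for ida, idb, _hit in orthologs.pairs:
        res = global_align(nuc_a[ida], nuc_b[idb], nuc_scheme)
        identities.append(res.identity_pct)
        weighted_num += res.n_identical
        weighted_den += res.length
    n = len(identities)
    mean = sum(identities) / n if n else None
    wmean = 100.0 * weighted_num / weighted_den if n else None
    return AgiosResult(
        genome_a.genome_id, genome_b.genome_id, n, mean, identities, wmean
    )


@dataclass
class AgiosMatrix:
    """Multi-genome comparison: diagonal gene counts, upper-triangle mean
    identities, lower-triangle ortholog counts (indices follow genome_ids)."""

    genome_ids: list[str]
    diagonal: list[int]
    mean_identity: dict[tuple[int, int], Optional[float]]  # i < j
    ortholog_counts: dict[tuple[int, int], int]  # i < j

    def result_for(self, i: int, j: int) -> tuple[int, Optional[float]]:
        i, j = min(i, j), max(i, j)
        return self.ortholog_counts[(i, j)], self.mean_identity[(i, j)]


def agios_matrix(
    genomes: list[Genome],
    nuc_scheme: Optional[ScoringScheme] = None,
    prot_scheme: Optional[ScoringScheme] = None,
    **rbh_kwargs,
) -> tuple[AgiosMatrix, dict[tuple[str, str], AgiosResult]]:
    """All-pairs AGIOS over >= 2 genomes; each unordered pair computed once.

    Returns the matrix plus the per-pair results keyed by (id_a, id_b) in
    input order.
    """
    if len(genomes) < 2:
        raise ValueError("agios_matrix requires at least 2 genomes")
    ids = [g.genome_id for g in genomes]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate genome ids")
    if prot_scheme is None:
        prot_scheme = protein_scheme()

    diag = [len(g.valid_genes) for g in genomes]
    means: dict[tuple[int, int], Optional[float]] = {}
    counts: dict[tuple[int, int], int] = {}
    results: dict[tuple[str, str], AgiosResult] = {}
    for i in range(len(genomes)):
        for j in range(i + 1, len(genomes)):
            orth = reciprocal_best_hits(
                genomes[i], genomes[j], scheme=prot_scheme, **rbh_kwargs
            )
            res = agios_pair(genomes[i], genomes[j], orth, nuc_scheme)
            means[(i, j)] = res.mean_identity_pct
            counts[(i, j)] = res.n_orthologs
            results[(ids[i], ids[j])] = res
    return AgiosMatrix(ids, diag, means, counts), results


def matrix_to_tsv(matrix: AgiosMatrix) -> str:
    """Full-precision TSV of the comparison matrix (rounding is for render
    time only, so the TSV round-trips losslessly)."""
    n = len(matrix.genome_ids)
    lines = ["\t".join(["genome"] + matrix.genome_ids)]
    for i in range(n):
        row = [matrix.genome_ids[i]]
        for j in range(n):
            if i == j:
                row.append(str(matrix.diagonal[i]))
            elif i < j:
                m = matrix.mean_identity[(i, j)]
                row.append("NA" if m is None else repr(m))
            else:
                row.append(str(matrix.ortholog_counts[(j, i)]))
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def matrix_from_tsv(text: str) -> AgiosMatrix:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    ids = header[1:]
    n = len(ids)
    diag: list[int] = []
    means: dict[tuple[int, int], Optional[float]] = {}
    counts: dict[tuple[int, int], int] = {}
    for i, ln in enumerate(lines[1 : n + 1]):
        cells = ln.split("\t")
        if cells[0] != ids[i]:
            raise ValueError(f"matrix row order mismatch at {cells[0]!r}")
        for j, cell in enumerate(cells[1:]):
            if i == j:
                diag.append(int(cell))
            elif i < j:
                means[(i, j)] = None if cell == "NA" else float(cell)
            else:
                counts[(j, i)] = int(cell)
    return AgiosMatrix(ids, diag, means, counts)


@dataclass(frozen=True)
class GenomeMetadata:
    """Per-genome descriptors for the metadata table."""

    genome_id: str
    size_bp: int
    gc_pct: float
    strain: str = ""
    accession: str = ""


def render_table6(
    matrix: AgiosMatrix, metadata: Optional[list[GenomeMetadata]] = None
) -> str:
    """Aligned-text report: a metadata block (genome size in Mb to 2 dp,
    round-half-up; G+C percent) and the comparison matrix with identities to
    1 dp, ortholog counts with thousands separators, gene counts on the
    diagonal, NA for pairs without orthologs."""
    n = len(matrix.genome_ids)
    if n < 2:
        raise ValueError("report requires at least 2 genomes")
    out = []
    if metadata is not None:
        meta_ids = [m.genome_id for m in metadata]
        if meta_ids != matrix.genome_ids:
            raise ValueError(
                f"metadata ids {meta_ids} do not match matrix ids {matrix.genome_ids}"
            )
        out.append("Genome\tStrain\tAccession\tGenome size (Mb)\tG+C content")
        for m in metadata:
            size_mb = round_half_up(m.size_bp / 1e6, 2)
            out.append(
                f"{m.genome_id}\t{m.strain}\t{m.accession}\t{size_mb:.2f}\t"
                f"{round_half_up(m.gc_pct, 2):g}"
            )
        out.append("")

    cells = [[""] + matrix.genome_ids]
    for i in range(n):
        row = [matrix.genome_ids[i]]
        for j in range(n):
            if i == j:
                row.append(f"{matrix.diagonal[i]:,}")
            elif i < j:
                m = matrix.mean_identity[(i, j)]
                row.append("NA" if m is None else f"{round_half_up(m, 1):.1f}")
            else:
                row.append(f"{matrix.ortholog_counts[(j, i)]:,}")
        cells.append(row)
    widths = [max(len(r[c]) for r in cells) for c in range(n + 1)]
    for r in cells:
        out.append("  ".join(c.ljust(w) for c, w in zip(r, widths)).rstrip())
    out.append(
        "\nDiagonal: gene count; upper triangle: mean % nucleotide identity of"
        "\northologous ORFs (AGIOS); lower triangle: number of ortholog pairs."
    )
    return "\n".join(out) + "\n"
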