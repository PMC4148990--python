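"""Reciprocal-best-hit (RBH) ortholog detection between two genomes.

Orthology here is pairwise: a gene pair (a, b) is orthologous when b is a's
highest-scoring protein match in genome B and vice versa, with minimum
identity and coverage thresholds (25% / 50%, the published defaults of the
Proteinortho BLAST stage) applied before best-hit selection. Alignments are
full-DP global protein alignments, so the procedure is deterministic and
self-contained. A shared-k-mer prefilter keeps the all-vs-all step desk-scale
and can be disabled.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .align import ScoringScheme, global_align, protein_scheme
from .seqio import Genome, ProtSeq

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HitScore:
    query_id: str
    subject_id: str
    score: int  # doubled-scale protein global-alignment score
    identity_pct: float
    coverage_pct: float  # non-gap aligned residues over the shorter protein


@dataclass
class OrthologSet:
    genome_a_id: str
    genome_b_id: str
    pairs: list[tuple[str, str, HitScore]] = field(default_factory=list)

    def __post_init__(self):
        a_ids = [p[0] for p in self.pairs]
        b_ids = [p[1] for p in self.pairs]
        if len(a_ids) != len(set(a_ids)) or len(b_ids) != len(set(b_ids)):
            raise ValueError("OrthologSet is not one-to-one")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def transposed(self) -> "OrthologSet":
        return OrthologSet(
            self.genome_b_id,
            self.genome_a_id,
            [
                (b, a, HitScore(b, a, h.score, h.identity_pct, h.coverage_pct))
                for a, b, h in self.pairs
            ],
        )

    def to_tsv(self) -> str:
        lines = [f"#genome_a={self.genome_a_id}\tgenome_b={self.genome_b_id}"]
        lines.append("gene_a\tgene_b\tscore\tidentity_pct\tcoverage_pct")
        for a, b, h in self.pairs:
            lines.append(f"{a}\t{b}\t{h.score}\t{h.identity_pct!r}\t{h.coverage_pct!r}")
        return "\n".join(lines) + "\n"


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def candidate_pairs(
    prots_a: Sequence[ProtSeq],
    prots_b: Sequence[ProtSeq],
    k: int = 5,
    min_shared: int = 2,
) -> list[tuple[str, str]]:
    """Protein pairs sharing >= ``min_shared`` distinct amino-acid k-mers.

    A recall heuristic, not a guarantee: near-identical orthologs share many
    exact k-mers, unrelated proteins almost none. Disable the prefilter for
    exhaustive comparison.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    index: dict[str, list[int]] = defaultdict(list)
    for j, p in enumerate(prots_b):
        for kmer in _kmer_set(p.seq, k):
            index[kmer].append(j)
    out = []
    for a in prots_a:
        shared: dict[int, int] = defaultdict(int)
        for kmer in _kmer_set(a.seq, k):
            for j in index.get(kmer, ()):
                shared[j] += 1
        for j in sorted(shared):
            if shared[j] >= min_shared:
                out.append((a.id, prots_b[j].id))
    return out


def _coverage_pct(aligned_a: str, aligned_b: str, la: int, lb: int) -> float:
    both = sum(1 for x, y in zip(aligned_a, aligned_b) if x != "-" and y != "-")
    return 100.0 * both / min(la, lb)


def _align_pairs(
    prots_a: Sequence[ProtSeq],
    prots_b: Sequence[ProtSeq],
    scheme: ScoringScheme,
    pairs: list[tuple[str, str]],
) -> dict[tuple[str, str], HitScore]:
    amap = {p.id: p for p in prots_a}
    bmap = {p.id: p for p in prots_b}
    scores: dict[tuple[str, str], HitScore] = {}
    for ida, idb in pairs:
        a, b = amap[ida], bmap[idb]
        res = global_align(a.seq, b.seq, scheme)
        scores[(ida, idb)] = HitScore(
            ida, idb, res.score, res.identity_pct,
            _coverage_pct(res.aligned_a, res.aligned_b, len(a), len(b)),
        )
    return scores


def _best_per_query(
    scores: dict[tuple[str, str], HitScore],
    min_identity: float,
    min_coverage: float,
) -> dict[str, HitScore]:
    best: dict[str, HitScore] = {}
    for (ida, idb), h in sorted(scores.items()):
        if h.identity_pct < min_identity or h.coverage_pct < min_coverage:
            continue
        cur = best.get(ida)
        if cur is None or h.score > cur.score:
            best[ida] = h
        elif h.score == cur.score and idb < cur.subject_id:
            log.info("best-hit score tie for %s: %s vs %s", ida, cur.subject_id, idb)
            best[ida] = h
    return best


def best_hits(
    prots_a: Sequence[ProtSeq],
    prots_b: Sequence[ProtSeq],
    scheme: Optional[ScoringScheme] = None,
    min_identity: float = 25.0,
    min_coverage: float = 50.0,
    prefilter: bool = True,
    k: int = 5,
    min_shared: int = 2,
) -> dict[str, HitScore]:
    """Best passing subject per query; queries with no passing hit absent.

    Score ties resolve to the lexicographically smallest subject id (logged).
    """
    if scheme is None:
        scheme = protein_scheme()
    if prefilter:
        pairs = candidate_pairs(prots_a, prots_b, k=k, min_shared=min_shared)
    else:
        pairs = [(a.id, b.id) for a in prots_a for b in prots_b]
    scores = _align_pairs(prots_a, prots_b, scheme, pairs)
    return _best_per_query(scores, min_identity, min_coverage)


def reciprocal_best_hits(
    genome_a: Genome,
    genome_b: Genome,
    scheme: Optional[ScoringScheme] = None,
    min_identity: float = 25.0,
    min_coverage: float = 50.0,
    prefilter: bool = True,
    k: int = 5,
    min_shared: int = 2,
) -> OrthologSet:
    """RBH ortholog pairs between two genomes.

    Each candidate protein pair is aligned once (the global score is
    symmetric) and best hits are derived in both directions from the shared
    scores, so the result is exactly transposed under genome swap.
    """
    if scheme is None:
        scheme = protein_scheme()
    prots_a = [g.prot for g in genome_a.valid_genes]
    prots_b = [g.prot for g in genome_b.valid_genes]
    if not prots_a or not prots_b:
        raise ValueError("both genomes need at least one valid protein")

    if prefilter:
        pairs = candidate_pairs(prots_a, prots_b, k=k, min_shared=min_shared)
    else:
        pairs = [(a.id, b.id) for a in prots_a for b in prots_b]
    scores = _align_pairs(prots_a, prots_b, scheme, pairs)
    fwd = _best_per_query(scores, min_identity, min_coverage)
    rev_scores = {
        (idb, ida): HitScore(idb, ida, h.score, h.identity_pct, h.coverage_pct)
        for (ida, idb), h in scores.items()
    }
    rev = _best_per_query(rev_scores, min_identity, min_coverage)

    out = []
    for ida, h in sorted(fwd.items()):
        back = rev.get(h.subject_id)
        if back is not None and back.subject_id == ida:
            out.append((ida, h.subject_id, h))
    return OrthologSet(genome_a.genome_id, genome_b.genome_id, out)
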