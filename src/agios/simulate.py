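"""Truth-known synthetic genome pairs for exercising the whole pipeline.

An ancestor genome of random intact CDS is generated, then "evolved" into a
derived genome by per-site substitutions (uniform across the three
alternative bases — the simplest null, no transition bias), optional
codon-multiple indels (frames stay intact because the downstream statistic
consumes CDS), gene loss, gene gain and order shuffling. Every mutation is
recorded, so ortholog detection and identity estimates can be scored against
exact truth. All outputs are pure functions of the parameter set including
its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .seqio import GeneRecord, Genome, NucSeq, translate_cds
from .utils import round_half_up

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class EvolutionParams:
    """Knobs of the ancestor generator and the evolver.

    Lengths in nucleotides (codon multiples); rates are probabilities.
    ``indel_len_codons`` is the mean of the geometric codon-count
    distribution for one indel.
    """

    n_genes: int = 50
    gene_len_range: tuple[int, int] = (300, 900)
    sub_rate: float = 0.05
    indel_rate: float = 0.0
    indel_len_codons: int = 2
    loss_frac: float = 0.0
    gain_frac: float = 0.0
    gc_target: float = 0.5
    intergenic_range: tuple[int, int] = (20, 200)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        lo, hi = self.gene_len_range
        if lo < 9 or hi < lo or lo % 3 or hi % 3:
            raise ValueError("gene_len_range must be codon multiples with min >= 9")
        for name in ("sub_rate", "loss_frac", "gain_frac"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if not 0 <= self.indel_rate <= 1:
            raise ValueError("indel_rate must be in [0, 1]")
        if not 0 < self.gc_target < 1:
            raise ValueError("gc_target must be in (0, 1)")
        if self.indel_len_codons < 1:
            raise ValueError("indel_len_codons must be >= 1")


@dataclass
class TruthRecord:
    """Exact bookkeeping of what the evolver did, per ancestor gene."""

    ortholog_map: dict[str, str] = field(default_factory=dict)
    realized_subs: dict[str, int] = field(default_factory=dict)
    realized_indels: dict[str, list[tuple[int, int, str]]] = field(
        default_factory=dict
    )  # (codon-boundary position in ancestor gene, nt length, "ins"/"del")
    expected_identity: dict[str, float] = field(default_factory=dict)

    def mean_expected_identity_pct(self) -> float:
        vals = list(self.expected_identity.values())
        return 100.0 * sum(vals) / len(vals)


def _random_codon(rng: np.random.Generator, p: np.ndarray) -> str:
    while True:
        codon = "".join(rng.choice(list(_BASES), size=3, p=p))
        if codon not in _STOPS:
            return codon


def _random_gene(rng: np.random.Generator, length: int, p: np.ndarray) -> str:
    n_codons = length // 3
    body = [_random_codon(rng, p) for _ in range(n_codons - 2)]
    stop = ["TAA", "TAG", "TGA"][rng.integers(3)]
    return "ATG" + "".join(body) + stop


def _spacer(rng: np.random.Generator, lo: int, hi: int, p: np.ndarray) -> str:
    ln = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list(_BASES), size=ln, p=p))


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _assemble(genome_id: str, prefix: str, seqs: list[str],
              rng: np.random.Generator, params: EvolutionParams) -> Genome:
    p = _base_probs(params.gc_target)
    lo, hi = params.intergenic_range
    parts = [_spacer(rng, lo, hi, p)]
    genes = []
    pos = len(parts[0])
    contig_id = f"{prefix}_contig1"
    for i, seq in enumerate(seqs, start=1):
        gid = f"{prefix}_g{i:04d}"
        nuc = NucSeq(gid, seq)
        genes.append(
            GeneRecord(gid, contig_id, pos, pos + len(seq), "+", nuc,
                       prot=translate_cds(nuc))
        )
        parts.append(seq)
        pos += len(seq)
        sp = _spacer(rng, lo, hi, p)
        parts.append(sp)
        pos += len(sp)
    contig = NucSeq(contig_id, "".join(parts))
    gc = contig.seq.count("G") + contig.seq.count("C")
    return Genome(genome_id, [contig], genes, len(contig.seq), gc)


def generate_ancestor(
    params: EvolutionParams, genome_id: str = "ancestor"
) -> Genome:
    """One-contig genome of ``n_genes`` intact random CDS (ATG start, no
    internal stop, terminal stop) at the target GC, separated by random
    intergenic spacers. Deterministic for a fixed seed."""
    params.validate()
    rng = np.random.default_rng([params.seed, 0])
    p = _base_probs(params.gc_target)
    lo, hi = params.gene_len_range
    lengths = 3 * rng.integers(lo // 3, hi // 3 + 1, size=params.n_genes)
    seqs = [_random_gene(rng, int(L), p) for L in lengths]
    return _assemble(genome_id, "A", seqs, rng, params)


def _mutate_gene(
    seq: str, rng: np.random.Generator, sub_rate: float
) -> tuple[str, int]:
    """Site-wise substitution, uniform among the 3 alternatives; codons that
    mutate into stops are re-rolled; the terminal stop codon is left alone so
    every derived gene stays a complete CDS."""
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    out = []
    n_subs = 0
    for ci, codon in enumerate(codons):
        if ci == len(codons) - 1:  # terminal stop
            out.append(codon)
            continue
        hit = rng.random(3) < sub_rate
        if not hit.any():
            out.append(codon)
            continue
        while True:
            new = list(codon)
            for k in range(3):
                if hit[k]:
                    alts = [b for b in _BASES if b != codon[k]]
                    new[k] = alts[rng.integers(3)]
            cand = "".join(new)
            if cand not in _STOPS:
                break
        out.append(cand)
        n_subs += int(hit.sum())
    return "".join(out), n_subs


def _apply_indel(
    seq: str, rng: np.random.Generator, params: EvolutionParams, p: np.ndarray
) -> tuple[str, Optional[tuple[int, int, str]]]:
    n_codons = len(seq) // 3
    if n_codons < 4:
        return seq, None
    length = 3 * int(rng.geometric(1.0 / params.indel_len_codons))
    is_del = rng.random() < 0.5
    if is_del:
        max_del = 3 * (n_codons - 3)  # keep start, one body codon, stop
        length = min(length, max_del)
        if length <= 0:
            return seq, None
        start_codon = int(rng.integers(1, n_codons - 1 - length // 3 + 1))
        pos = 3 * start_codon
        return seq[:pos] + seq[pos + length :], (pos, length, "del")
    start_codon = int(rng.integers(1, n_codons - 1 + 1))
    pos = 3 * start_codon
    insert = "".join(_random_codon(rng, p) for _ in range(length // 3))
    return seq[:pos] + insert + seq[pos:], (pos, length, "ins")


def evolve_pair(
    ancestor: Genome, params: EvolutionParams, derived_id: str = "derived"
) -> tuple[Genome, TruthRecord]:
    """Evolve ``ancestor`` into a derived genome, recording complete truth.

    Order of events per retained gene: substitutions, then at most one indel.
    ``loss_frac``/``gain_frac`` fix the deleted/novel gene counts exactly
    (round half-up). The expected identity per gene is that of the
    truth-constructed alignment trace: with S substitutions on a gene of
    ancestral length L, (L-S)/L when indel-free, (L-S-D)/L after a D-nt
    deletion, (L-S)/(L+I) after an I-nt insertion.
    """
    params.validate()
    rng = np.random.default_rng([params.seed, 1])
    p = _base_probs(params.gc_target)
    genes = list(ancestor.genes)
    n = len(genes)
    n_loss = int(round_half_up(params.loss_frac * n, 0))
    lost_idx = set(rng.choice(n, size=n_loss, replace=False).tolist())

    truth = TruthRecord()
    derived_seqs: list[tuple[str, str]] = []  # (ancestor gene id, derived seq)
    for idx, gene in enumerate(genes):
        if idx in lost_idx:
            continue
        seq = gene.nuc.seq
        L = len(seq)
        mutated, n_subs = _mutate_gene(seq, rng, params.sub_rate)
        indel = None
        if rng.random() < params.indel_rate:
            mutated2, indel = _apply_indel(mutated, rng, params, p)
            if indel is not None:
                mutated = mutated2
        truth.realized_subs[gene.gene_id] = n_subs
        truth.realized_indels[gene.gene_id] = [indel] if indel else []
        if indel is None:
            ident = (L - n_subs) / L
        elif indel[2] == "del":
            pos, ln, _ = indel
            # substitutions landing inside the deleted window do not subtract
            # twice; count subs on retained sites by direct comparison
            kept_anc = seq[:pos] + seq[pos + ln :]
            subs_retained = sum(1 for x, y in zip(kept_anc, mutated) if x != y)
            ident = (L - ln - subs_retained) / L
        else:
            ident = (L - n_subs) / (L + indel[1])
        truth.expected_identity[gene.gene_id] = ident
        derived_seqs.append((gene.gene_id, mutated))

    n_gain = int(round_half_up(params.gain_frac * n, 0))
    lo, hi = params.gene_len_range
    for _ in range(n_gain):
        L = 3 * int(rng.integers(lo // 3, hi // 3 + 1))
        derived_seqs.append((None, _random_gene(rng, L, p)))

    order = rng.permutation(len(derived_seqs))
    shuffled = [derived_seqs[i] for i in order]
    derived = _assemble(derived_id, "B", [s for _, s in shuffled], rng, params)
    for (anc_id, _), rec in zip(shuffled, derived.genes):
        if anc_id is not None:
            truth.ortholog_map[anc_id] = rec.gene_id
    return derived, truth


def expected_identity(truth: TruthRecord, gene_id: str) -> float:
    """Truth-trace identity fraction for one ancestor gene; lost genes are
    an error."""
    if gene_id not in truth.ortholog_map:
        raise ValueError(f"gene {gene_id!r} was lost in the derived genome")
    return truth.expected_identity[gene_id]
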