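"""Sequence data model and input/output.

Holds the nucleotide/protein sequence types, the gene and genome containers,
FASTA and GFF3 readers, bacterial-code translation, composition statistics and
a deliberately naive six-frame ORF finder used only when no annotation is
supplied (it is plumbing, not a gene caller of Prodigal quality).

Coordinate convention: internal coordinates are 0-based half-open throughout;
GFF3 input/output converts from/to the format's 1-based inclusive coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import gffutils
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUC_ALPHABET = set("ACGTN")
# IUPAC ambiguity letters collapse to N on ingest (alignment treats N as
# neutral, never identical), anything else is rejected.
IUPAC_AMBIGUOUS = set("RYSWKMBDHVN")
PROT_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class NucSeq:
    """A named nucleotide sequence over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self):
        bad = set(self.seq) - NUC_ALPHABET
        if bad:
            raise ValueError(
                f"invalid nucleotide characters in {self.id!r}: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "NucSeq":
        return NucSeq(self.id, reverse_complement(self.seq))


@dataclass(frozen=True)
class ProtSeq:
    """A named amino-acid sequence (20 letters + X); terminal stop stripped."""

    id: str
    seq: str

    def __post_init__(self):
        bad = set(self.seq) - PROT_ALPHABET
        if bad:
            raise ValueError(
                f"invalid protein characters in {self.id!r}: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GeneRecord:
    """One CDS: coordinates on its contig (0-based half-open) plus sequences.

    ``start``/``end`` are ``None`` for genes loaded from a CDS FASTA, where no
    genomic coordinates exist. ``frame_ok`` is False for CDS whose length is
    not a codon multiple or whose translation hits an internal stop; such
    genes are kept for bookkeeping but excluded from ortholog detection.
    """

    gene_id: str
    contig_id: str
    start: Optional[int]
    end: Optional[int]
    strand: str
    nuc: NucSeq
    prot: Optional[ProtSeq] = None
    frame_ok: bool = True


@dataclass
class Genome:
    """A genome: contigs plus ordered gene records; the unit AGIOS compares."""

    genome_id: str
    contigs: list[NucSeq] = field(default_factory=list)
    genes: list[GeneRecord] = field(default_factory=list)
    total_bp: int = 0
    gc_bp: int = 0

    def __post_init__(self):
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene ids in genome {self.genome_id!r}: {dup}")

    @property
    def valid_genes(self) -> list[GeneRecord]:
        """Genes eligible for ortholog detection (in frame, translatable)."""
        return [g for g in self.genes if g.frame_ok and g.prot is not None]

    @property
    def gc_pct(self) -> float:
        from .utils import pct

        return pct(self.gc_bp, self.total_bp) if self.total_bp else 0.0


def _clean_nuc(raw: str, rec_id: str) -> str:
    s = raw.upper().replace("U", "T")
    out = []
    for ch in s:
        if ch in "ACGT":
            out.append(ch)
        elif ch in IUPAC_AMBIGUOUS:
            out.append("N")
        else:
            raise ValueError(f"invalid nucleotide character {ch!r} in {rec_id!r}")
    return "".join(out)


def read_fasta(path, alphabet: str = "nucleotide"):
    """Read a FASTA file into NucSeq or ProtSeq records.

    Sequences are uppercased; for nucleotides U→T and IUPAC ambiguity codes
    collapse to N. Duplicate ids and empty files are errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    seen: set[str] = set()
    out = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        raw = str(rec.seq)
        if alphabet == "nucleotide":
            out.append(NucSeq(rec.id, _clean_nuc(raw, rec.id)))
        elif alphabet == "protein":
            out.append(ProtSeq(rec.id, raw.upper().rstrip("*")))
        else:
            raise ValueError(f"unknown alphabet {alphabet!r}")
    return out


def write_fasta(records: Iterable, path, width: int = 60) -> None:
    """Write records (anything with .id/.seq) as FASTA folded at ``width``."""
    seq_records = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


_TABLE_CACHE: dict[int, CodonTable.CodonTable] = {}


def _codon_table(table_id: int) -> CodonTable.CodonTable:
    if table_id not in _TABLE_CACHE:
        _TABLE_CACHE[table_id] = CodonTable.unambiguous_dna_by_id[table_id]
    return _TABLE_CACHE[table_id]


def translate_cds(nuc: NucSeq, table: int = 11) -> ProtSeq:
    """Translate a complete CDS under the bacterial code (NCBI table 11).

    A terminal stop codon is stripped; an internal stop is an error; codons
    containing N translate to X. Non-ATG start codons are rendered as their
    table amino acid, not forced to M (documented simplification).
    """
    seq = nuc.seq
    if len(seq) == 0 or len(seq) % 3 != 0:
        raise ValueError(
            f"CDS length {len(seq)} of {nuc.id!r} is not a positive codon multiple"
        )
    tbl = _codon_table(table)
    aas = []
    n_codons = len(seq) // 3
    for i in range(n_codons):
        codon = seq[3 * i : 3 * i + 3]
        if codon in tbl.stop_codons:
            if i == n_codons - 1:
                break  # terminal stop, stripped
            raise ValueError(
                f"internal stop codon {codon} at codon {i} in {nuc.id!r}"
            )
        aa = tbl.forward_table.get(codon)
        if aa is None:
            if "N" in codon:
                aa = "X"
            else:  # unreachable for the ACGTN alphabet
                raise ValueError(f"untranslatable codon {codon!r} in {nuc.id!r}")
        aas.append(aa)
    return ProtSeq(nuc.id, "".join(aas))


def gc_stats(seqs: Iterable[NucSeq]) -> tuple[int, int, float]:
    """(total_bp, gc_bp, gc_pct) over a list of sequences.

    N counts toward total_bp only; gc_pct is round-half-up to 2 decimals.
    """
    from .utils import pct

    total = 0
    gc = 0
    for s in seqs:
        total += len(s.seq)
        gc += s.seq.count("G") + s.seq.count("C")
    if total == 0:
        raise ValueError("gc_stats over zero total bp")
    return total, gc, pct(gc, total)


START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")


def _scan_frame(seq: str, frame: int, min_nt: int) -> list[tuple[int, int]]:
    """Complete ORFs [start, end) in one forward frame of ``seq``.

    An ORF opens at the first start codon after the previous in-frame stop
    (the sequence 5' end counts as following a stop) and closes at the next
    in-frame stop, which is included in the span.
    """
    orfs = []
    start: Optional[int] = None
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            if start is not None and (i + 3 - start) >= min_nt:
                orfs.append((start, i + 3))
            start = None
        elif start is None and codon in START_CODONS:
            start = i
    return orfs


def _has_n_run(seq: str, k: int) -> bool:
    return "N" * k in seq


def find_orfs(
    contig: NucSeq, min_nt: int = 300, max_n_run: Optional[int] = 10
) -> list[GeneRecord]:
    """Naive six-frame ORF finder used as an annotation fallback.

    Overlapping ORFs on the same strand are resolved by keeping the longer
    (ties go to the leftmost). ORFs spanning a run of >= ``max_n_run`` N's are
    dropped — a stand-in for excluding genes over assembly gaps. This is
    explicitly not a Prodigal-quality gene caller.
    """
    if min_nt < 6 or min_nt % 3 != 0:
        raise ValueError("min_nt must be >= 6 and divisible by 3")
    n = len(contig.seq)
    raw: list[tuple[int, int, str]] = []  # (start, end, strand) forward coords
    for frame in range(3):
        for s, e in _scan_frame(contig.seq, frame, min_nt):
            raw.append((s, e, "+"))
    rc = reverse_complement(contig.seq)
    for frame in range(3):
        for s, e in _scan_frame(rc, frame, min_nt):
            raw.append((n - e, n - s, "-"))

    if max_n_run is not None:
        raw = [
            (s, e, st)
            for s, e, st in raw
            if not _has_n_run(contig.seq[s:e], max_n_run)
        ]

    # keep-longer overlap resolution, per strand; ties leftmost
    raw.sort(key=lambda t: (-(t[1] - t[0]), t[0], t[2]))
    kept: list[tuple[int, int, str]] = []
    for s, e, st in raw:
        if all(st != ks[2] or e <= ks[0] or s >= ks[1] for ks in kept):
            kept.append((s, e, st))
    kept.sort(key=lambda t: (t[0], t[1]))

    genes = []
    for idx, (s, e, st) in enumerate(kept, start=1):
        sub = contig.seq[s:e]
        if st == "-":
            sub = reverse_complement(sub)
        nuc = NucSeq(f"{contig.id}_orf{idx:04d}", sub)
        rec = GeneRecord(nuc.id, contig.id, s, e, st, nuc)
        try:
            rec.prot = translate_cds(nuc)
        except ValueError:
            rec.frame_ok = False
        genes.append(rec)
    return genes


def _genes_from_gff(contigs: dict[str, NucSeq], gff_path) -> list[GeneRecord]:
    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for i, feat in enumerate(db.features_of_type("CDS", order_by="start"), start=1):
        gene_id = feat.attributes.get("ID", [f"cds{i:05d}"])[0]
        if feat.seqid not in contigs:
            raise ValueError(f"CDS {gene_id!r} references unknown contig {feat.seqid!r}")
        contig = contigs[feat.seqid]
        start, end = feat.start - 1, feat.end  # 1-based inclusive -> half-open
        if start < 0 or end > len(contig.seq) or end <= start:
            raise ValueError(
                f"CDS {gene_id!r} coordinates {feat.start}..{feat.end} outside "
                f"contig {feat.seqid!r} (length {len(contig.seq)})"
            )
        sub = contig.seq[start:end]
        strand = feat.strand if feat.strand in "+-" else "+"
        if strand == "-":
            sub = reverse_complement(sub)
        rec = GeneRecord(gene_id, feat.seqid, start, end, strand, NucSeq(gene_id, sub))
        if len(sub) % 3 != 0:
            warnings.warn(
                f"CDS {gene_id!r} length {len(sub)} not divisible by 3; flagged"
            )
            rec.frame_ok = False
        else:
            try:
                rec.prot = translate_cds(rec.nuc)
            except ValueError as exc:
                warnings.warn(f"CDS {gene_id!r} untranslatable ({exc}); flagged")
                rec.frame_ok = False
        genes.append(rec)
    return genes


def load_genome(
    fasta=None,
    gff=None,
    cds_fasta=None,
    genome_id: Optional[str] = None,
    min_orf_nt: int = 300,
) -> Genome:
    """Assemble a Genome from any supported input combination.

    Gene source precedence: GFF3 CDS features over ``fasta`` contigs; a CDS
    FASTA alone (coordinates absent); or, with only a genome FASTA, the
    find_orfs fallback. Exactly one source applies.
    """
    if gff is not None and cds_fasta is not None:
        raise ValueError("supply gff or cds_fasta, not both")
    if fasta is None and cds_fasta is None:
        raise ValueError("no sequence input supplied")

    contigs = read_fasta(fasta) if fasta is not None else []
    cmap = {c.id: c for c in contigs}
    if genome_id is None:
        src = fasta if fasta is not None else cds_fasta
        genome_id = Path(str(src)).stem

    if gff is not None:
        if not contigs:
            raise ValueError("a GFF requires the genome FASTA")
        genes = _genes_from_gff(cmap, gff)
    elif cds_fasta is not None:
        genes = []
        for nuc in read_fasta(cds_fasta):
            rec = GeneRecord(nuc.id, "", None, None, "+", nuc)
            if len(nuc.seq) % 3 != 0:
                warnings.warn(
                    f"CDS {nuc.id!r} length {len(nuc.seq)} not divisible by 3; flagged"
                )
                rec.frame_ok = False
            else:
                try:
                    rec.prot = translate_cds(nuc)
                except ValueError:
                    rec.frame_ok = False
            genes.append(rec)
    else:
        genes = []
        for contig in contigs:
            genes.extend(find_orfs(contig, min_nt=min_orf_nt))

    base_seqs = contigs if contigs else [g.nuc for g in genes]
    if base_seqs:
        total_bp, gc_bp, _ = gc_stats(base_seqs)
    else:
        total_bp = gc_bp = 0
    return Genome(genome_id, contigs, genes, total_bp, gc_bp)


def write_gff(genome: Genome, path) -> None:
    """Write the genome's coordinate-bearing genes as GFF3 CDS features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genome.genes:
            if g.start is None:
                continue
            fh.write(
                f"{g.contig_id}\tagios\tCDS\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t0\tID={g.gene_id}\n"
            )
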