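# Methods

## The AGIOS statistic

AGIOS between two annotated genomes is the unweighted arithmetic mean of
per-pair percent nucleotide identities over their reciprocal-best-hit (RBH)
ortholog pairs, each identity taken from a full global alignment of the two
ORFs. Design choices that needed pinning:

- **Unweighted mean across gene pairs.** The statistic is "mean identity
  among orthologous ORFs", most naturally per ORF. A length-weighted mean
  (identical columns summed over all pairs divided by columns summed) is
  carried alongside in `AgiosResult.length_weighted_mean_pct` for users who
  prefer it; the headline number is the unweighted one.
- **Full ORF-to-ORF alignment**, not trimmed homologous blocks: the method
  retrieves the genes corresponding to orthologous proteins and aligns them
  whole.
- **Zero orthologs** yields `mean_identity_pct = None`, rendered `NA` —
  never 0, which would be a valid (and very different) identity.
- Genomes annotated only as a CDS FASTA (no coordinates) are first-class:
  the statistic needs only the gene sequences.

## Ortholog detection

RBH over protein global alignments stands in for graph-based ortholog
tools: it is deterministic, parameter-light, and exactly pairwise, which is
all a pairwise statistic needs (no multi-genome family clustering).
Thresholds follow the published defaults of Proteinortho's BLAST stage:
minimum 25% identity, minimum 50% coverage, coverage measured as
both-residue alignment columns over the *shorter* protein (symmetric).
Ties on alignment score resolve to the lexicographically smallest subject
id and are logged. A shared-k-mer prefilter (k = 5, ≥ 2 distinct shared
k-mers) keeps all-vs-all alignment desk-scale; it is a recall heuristic,
tested to retain ≥ 99% of the exhaustive result at 5% divergence, and can
be disabled (`prefilter=False` / `--no-prefilter`). Because each candidate
pair is aligned once and both best-hit directions are derived from the same
scores, RBH output is exactly transposed under genome swap.

## Alignment core

Three-state Gotoh recurrence (match state plus one affine gap state per
sequence), end gaps penalized — a true global alignment. A gap of length L
costs `gap_open + L·gap_extend`.

- **Parameters.** The original description names the algorithm but no
  scoring scheme, so the defaults mirror the most widely replicated global
  aligner settings (EMBOSS needle): nucleotide +5/−4, protein BLOSUM62,
  gap open 10, extend 0.5. All configurable.
- **Integer DP.** Half-point penalties are removed by doubling every score
  internally; the reported `score` stays on the doubled scale (documented
  on `AlignmentResult`).
- **Identity denominator** is all alignment columns including gaps (the
  EMBOSS "Identity" convention); a gap-free self-alignment is exactly 100%.
- **Ambiguity.** N (nucleotide) and X (protein) score 0 against everything
  and never count as identical; IUPAC ambiguity letters collapse to N on
  ingest.
- **Determinism.** Tie-break order in traceback: diagonal, then gap-in-b,
  then gap-in-a; opposite-direction gap runs each pay their own opening, and
  the recurrence permits adjacent opposite gaps so the optimum agrees with
  exhaustive path enumeration.
- Verified two independent ways: against a brute-force enumerator of all
  monotone alignment paths (exhaustively for short pairs), and against
  Biopython's `PairwiseAligner` configured with identical parameters.

The O(nm) kernel is JIT-compiled with numba; typical bacterial ORF pairs
(≤ 3 kb) align in well under a millisecond after the one-off compilation.

## Annotation statistics and rank thresholds

All percentages are **round-half-up to 2 decimals**, the convention under
which every reproduced cell of the published *G. massiliense* annotation
tables checks out. Denominators: gene-class percentages over total genes;
COG-assigned, function-assigned, ORFan and hypothetical percentages over
protein-coding genes; base-pair percentages over genome size. Coding bp is
the length of the union of coding intervals (overlaps merged first). A gene
carrying several COG letters increments each category, so lettered counts
may exceed the number of assigned genes.

**ORFan rule.** A predicted protein is an ORFan iff it has *no* qualifying
database hit, where a hit qualifies with E < 1e−3 when its alignment is
longer than 80 aa, or E < 1e−5 at ≤ 80 aa. The source sentence is phrased
as if the thresholds identified ORFans directly; by definition an ORFan
*lacks* such homologs, so the rule is implemented as
absence-of-qualifying-hit. The 80-aa boundary itself is assigned to the
stricter short tier ("greater than 80" being the long-tier condition as
printed).

**Rank delineation.** 16S identity below 95% (the classical
Stackebrandt–Ebers genus cut-off) proposes a new genus; the 98.7% species
threshold is supplied as the conventional default even though only the
genus threshold is exercised by the motivating case (93.72% → new genus).
Boundaries are inclusive upward. 16S comparisons auto-orient by trying both
strands and keeping the higher identity.

## Synthetic genome generator

The generator emulates a pair of diverging bacterial genomes at the level
the pipeline consumes: intact CDS (ATG start, no internal stop, terminal
stop) of 300–900 nt on a single contig at a target GC of 0.50, evolved by
per-site substitutions uniform across the three alternative bases (no
transition bias — the simplest null), optional codon-multiple indels (so
frames stay intact), exact gene-loss and gene-gain fractions, and order
shuffling. Substituted codons that would become stops are re-rolled;
the terminal stop codon is not mutated, so every derived gene remains
translatable. Novel gained genes are generated independently of the
ancestor and should not attract RBH pairs at default thresholds. Everything
is a pure function of the parameter set including its seed, and a
`TruthRecord` logs the ortholog map, per-gene substitution counts, indels
and the identity of the truth-constructed alignment trace: for ancestral
length L with S substitutions, (L−S)/L indel-free, (L−S′−D)/L after a D-nt
deletion (S′ counted on retained sites), (L−S)/(L+I) after an I-nt
insertion.

What it does *not* emulate: codon-usage bias, selection, rearrangements
beyond order shuffling, paralogous families, sequencing error, assembly
gaps, real intergenic structure. Passing tests therefore demonstrate
correctness of the computation under a clean substitution/indel null, not
annotation robustness on real draft assemblies.

A subtlety the tests document: at moderate divergence the optimal alignment
of an indel-free pair occasionally beats the gap-free alignment with a
compensating gap pair, putting measured identity a fraction of a point
*above* the truth trace; the mean stays well within a percentage point.

## Naive ORF finder

`find_orfs` is plumbing for genomes supplied without annotation, explicitly
not a gene caller of Prodigal quality: six-frame scan, ORF from the first
ATG/GTG/TTG after an in-frame stop (the 5′ end counts as following a stop)
to the next in-frame stop inclusive, minimum 300 nt, same-strand overlaps
resolved by keeping the longer (ties leftmost). ORFs spanning a run of ≥ 10
N's are dropped — a configurable stand-in for excluding genes over assembly
gaps, whose original criterion is not further specified. Translation under
NCBI genetic code 11 renders non-ATG starts as their table amino acid
rather than forcing M — a documented simplification that does not affect
identity statistics.

## Problem sizes and numerical conventions

Synthetic checks use 50-gene genomes (300–900 nt genes) across
substitution rates 0.01–0.15, sizes at which ortholog recovery and
identity-error bounds are tight yet the full pipeline runs in seconds.
Alignment-oracle equivalence is exhaustive over all nucleotide pairs up to
length 4 and sampled (500 pairs) up to length 6, where path enumeration is
tractable. Reports render identities to 1 decimal, G+C and other
percentages to 2, genome sizes in Mb to 2 decimals, all round-half-up;
TSV artifacts always carry full precision so they round-trip losslessly.

## Command-line interface

The console script is `agios`; the matrix workflow is the `run` subcommand
(`agios run …`) to avoid the stutter of an `agios agios` spelling.
`--threads` is accepted for interface compatibility but pairs are computed
sequentially in a fixed order, so results can never depend on scheduling.

## Known limitations

- The published four-genome identity matrix (values 65.3–68.7%, ortholog
  counts 1,716–2,336) is not asserted anywhere: it requires the deposited
  assemblies and depends on unpublished ortholog-detection and alignment
  parameters of the original runs. The optional
  `scripts/compare_published_genomes.py` reproduces the workflow for users
  who download the accessions; the qualitative expectation is pairwise
  means in the 60–70% band with *G. massiliense* closest to *P. elgii*.
- Similarly, whether the published 93.72% 16S value came from a global or
  local alignment over which region is unstated; it is treated as an input
  to the rank rule, not a target to recompute.
- One published inconsistency is not chased: the comparison metadata prints
  the G5 genome as 5.54 Mb while its own size in bp (5,546,433) rounds to
  5.55 Mb at 2 decimals; the renderer documents round-half-up and prints
  5.55.
- Coverage/identity thresholds are best-hit filters, not homology
  statistics; no E-values are computed.
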