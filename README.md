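# agios

Ortholog-based genome relatedness for bacterial taxonomy: a self-contained
implementation of **AGIOS** (Average Genomic Identity of Orthologous gene
Sequences), together with the annotation summary statistics, COG category
tabulation, ORFan classification and 16S-identity rank thresholds used in
taxono-genomic descriptions of new prokaryotic taxa.

## The problem and the statistic

When a new bacterial isolate (such as *Gorillibacterium massiliense* G5,
cultured from gorilla feces) falls below the classical 95% 16S rRNA identity
threshold to its nearest named neighbour, genome-scale evidence is needed to
support the proposal of a new genus. AGIOS measures how similar two annotated
genomes are at the level of the genes they share:

1. **Ortholog detection.** Orthologous protein pairs between genomes *A* and
   *B* are found by reciprocal best hits (RBH): genes *a* ∈ *A*, *b* ∈ *B*
   are orthologs iff *b* is *a*'s highest-scoring protein match and vice
   versa, with minimum identity (25%) and coverage (50%) thresholds.
2. **Global alignment.** For each ortholog pair, the *nucleotide* ORFs are
   aligned with the Needleman–Wunsch algorithm under affine gap penalties
   (Gotoh three-state recurrence; EMBOSS-needle-style defaults: match +5,
   mismatch −4, gap open 10, gap extend 0.5; end gaps penalized).
3. **The statistic.** AGIOS(A, B) is the unweighted arithmetic mean of the
   per-alignment percent identities (identical columns over all alignment
   columns, gaps included):

   AGIOS(A, B) = (1/n) Σᵢ 100 · idᵢ / Lᵢ

   over the n ortholog pairs, where idᵢ is the number of identical columns
   and Lᵢ the alignment length of pair i.

Multi-genome comparisons assemble into a square matrix: diagonal = gene
counts, upper triangle = mean identities, lower triangle = ortholog counts.

The package also includes a truth-known synthetic genome evolver (per-site
substitutions, codon-multiple indels, gene loss/gain) so the entire pipeline
is testable without downloading any assembly.

## Worked example

```python
from agios import (EvolutionParams, generate_ancestor, evolve_pair,
                   reciprocal_best_hits, agios_pair)

params = EvolutionParams(n_genes=50, sub_rate=0.05, seed=1)
ancestor = generate_ancestor(params)
derived, truth = evolve_pair(ancestor, params)

orthologs = reciprocal_best_hits(ancestor, derived)
result = agios_pair(ancestor, derived, orthologs)
print(f"ortholog pairs: {result.n_orthologs}")
print(f"mean identity:  {result.mean_identity_pct:.2f}%")
print(f"truth average:  {truth.mean_expected_identity_pct():.2f}%")
```

prints

```
ortholog pairs: 50
mean identity:  94.80%
truth average:  94.80%
```

All 50 true ortholog pairs are recovered by RBH, and the measured mean
nucleotide identity of a genome evolved at 5% per-site substitution matches
the generator's exact mutation bookkeeping to within 0.01 percentage points
(at 5% divergence roughly 95% of sites remain identical, hence ≈94.8%).

The same workflow from a shell:

```sh
agios simulate --n-genes 10 --sub-rate 0.03 --seed 4 --out demo
agios run --genome demo/ancestor.fasta,demo/ancestor.gff \
          --genome demo/derived.fasta,demo/derived.gff --out demo/agios
cat demo/agios/report.txt
```

```
          ancestor  derived
ancestor  10        97.4
derived   10        10

Diagonal: gene count; upper triangle: mean % nucleotide identity of
orthologous ORFs (AGIOS); lower triangle: number of ortholog pairs.
```

Other subcommands: `agios stats` (annotation summary, COG table, ORFan
list), `agios delineate` (16S identity vs references with the 95% genus /
98.7% species thresholds), `agios align` (single-pair debugging).

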