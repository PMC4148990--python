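#!/usr/bin/env python
"""OPTIONAL integration run against the four deposited genomes.

This script is NOT part of the test suite and is never run automatically:
it requires the user to download the deposited assemblies first (they are
not shipped with the package, and the original ortholog-detection and
alignment parameter choices are not fully published, so the printed matrix
cells are not promised to reproduce exactly). The qualitative expectation is
that all pairwise ortholog-identity means land in the 60-70% band, with
G. massiliense closest to P. elgii.

Usage:
  1. Download from GenBank (e.g. with NCBI datasets or efetch) the CDS FASTA
     for the assemblies:
       CBQR000000000  Gorillibacterium massiliense G5
       AFHW00000000   Paenibacillus elgii B69
       AMBZ00000000   Paenibacillus alvei DSM 29
       AP008955       Brevibacillus brevis NBRC 100599
  2. python scripts/compare_published_genomes.py g5_cds.fna elgii_cds.fna \
         alvei_cds.fna brevis_cds.fna --out results/published

Expect hours of CPU time: these are 5-8 Mb genomes with 5-7.6k proteins
each, aligned by full dynamic programming.
"""

import argparse
from pathlib import Path

from agios.metric import agios_matrix, matrix_to_tsv, render_table6
from agios.seqio import load_genome


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("cds_fastas", nargs="+", help="one CDS FASTA per genome")
    ap.add_argument("--out", type=Path, default=Path("results/published"))
    args = ap.parse_args()
    if len(args.cds_fastas) < 2:
        ap.error("need at least two genomes")
    genomes = [load_genome(cds_fasta=p) for p in args.cds_fastas]
    matrix, _ = agios_matrix(genomes)
    args.out.mkdir(parents=True, exist_ok=True)
    (args.out / "matrix.tsv").write_text(matrix_to_tsv(matrix))
    (args.out / "report.txt").write_text(render_table6(matrix))
    print(render_table6(matrix))


if __name__ == "__main__":
    main()
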