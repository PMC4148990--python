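"""Published annotation statistics of the *Gorillibacterium massiliense*
G5 draft genome (GenBank CBQR000000000), shipped as reference inputs for the
statistics calculators.

These are the deposited counts of the original genome description —
chromosome composition, gene tallies and the per-category COG distribution —
from which the summary percentages are recomputed, never stored.
"""

# chromosome-level nucleotide and gene-count attributes
G5_ANNOTATION_COUNTS = dict(
    genome_size_bp=5_546_433,
    gc_bp=2_794_611,
    coding_bp=4_888_209,
    total_genes=5_221,
    rna_genes=76,
    protein_coding_genes=5_145,
    genes_with_function=3_865,
    genes_in_cogs=3_881,
    n_orfans=272,
    n_hypothetical=680,
)

# genes per COG functional category (a gene may carry several letters, so
# the lettered counts sum above the number of COG-assigned genes)
G5_COG_COUNTS = {
    "J": 201, "A": 0, "K": 483, "L": 166, "B": 1, "D": 43, "Y": 0,
    "V": 119, "T": 313, "M": 205, "N": 73, "Z": 5, "W": 0, "U": 50,
    "O": 121, "C": 180, "G": 560, "E": 355, "F": 93, "H": 130, "I": 108,
    "P": 248, "Q": 113, "R": 648, "S": 328,
}

# 16S rRNA identity of strain G5 to its nearest validly published neighbour
# (Paenibacillus turicensis), as deposited
G5_16S_IDENTITY_TO_NEAREST = 93.72
G5_NEAREST_TAXON = "Paenibacillus turicensis"

# pyrosequencing run totals: bases sequenced and passed-filter reads
G5_RUN_TOTAL_BP = 142.7e6
G5_RUN_N_READS = 387_157


def g5_cog_assignments() -> dict[str, list[str]]:
    """Expand the per-category counts into an explicit gene -> letters map
    consistent with the deposited totals: the published number of
    COG-assigned genes with the published per-letter counts, extra letters
    doubling up on already-assigned genes."""
    n_assigned = G5_ANNOTATION_COUNTS["genes_in_cogs"]
    slots = [c for code, n in G5_COG_COUNTS.items() for c in code * n]
    assignments: dict[str, list[str]] = {
        f"gene{i:05d}": [slots[i]] for i in range(n_assigned)
    }
    for k, letter in enumerate(slots[n_assigned:]):
        gid = f"gene{k:05d}"
        if letter in assignments[gid]:
            raise AssertionError("slot layout produced a duplicate letter")
        assignments[gid].append(letter)
    return assignments
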