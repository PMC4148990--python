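"""Independent oracles used by the test suite.

These deliberately avoid the package's dynamic-programming code paths: the
alignment oracle enumerates every monotone alignment path outright, and the
ORF oracle enumerates six-frame ORFs positionally. They exist to check the
real implementations, so they must stay naive.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

START_CODONS = {"ATG", "GTG", "TTG"}
STOP_CODONS = {"TAA", "TAG", "TGA"}

_COMP = str.maketrans("ACGTN", "TGCAN")


@lru_cache(maxsize=None)
def alignment_paths(la: int, lb: int):
    """All monotone alignment paths from (0,0) to (la,lb).

    Each path is (n_gap_opens, n_gap_moves, diag_cells): a gap run of length
    L contributes one open and L gap moves, and runs in opposite directions
    open separately.
    """
    paths = []

    def rec(i, j, prev, opens, gapmoves, diags):
        if i == la and j == lb:
            paths.append((opens, gapmoves, tuple(diags)))
            return
        if i < la and j < lb:
            rec(i + 1, j + 1, "M", opens, gapmoves, diags + ((i, j),))
        if i < la:
            rec(i + 1, j, "U", opens + (prev != "U"), gapmoves + 1, diags)
        if j < lb:
            rec(i, j + 1, "L", opens + (prev != "L"), gapmoves + 1, diags)

    rec(0, 0, "M", 0, 0, ())
    return paths


def brute_force_score(a: str, b: str, scheme) -> int:
    """Optimal global-alignment score by exhaustive path enumeration
    (doubled scale, same gap cost convention: open + L*extend per run)."""
    ea, eb = scheme.encode(a), scheme.encode(b)
    sub, go, ge = scheme.matrix, scheme.gap_open, scheme.gap_extend
    best = None
    for opens, gapmoves, diags in alignment_paths(len(a), len(b)):
        s = -(opens * go + gapmoves * ge)
        for i, j in diags:
            s += sub[ea[i], eb[j]]
        if best is None or s > best:
            best = int(s)
    return best


def all_seqs(max_len: int, alphabet: str = "ACGT"):
    for L in range(1, max_len + 1):
        for t in itertools.product(alphabet, repeat=L):
            yield "".join(t)


def brute_force_orfs(seq: str, min_nt: int):
    """Six-frame complete ORFs by positional enumeration: for every position
    and strand, is it a start codon in whose frame no stop intervenes before
    the closing stop, with no earlier in-frame start after the previous stop?
    Returns (start, end, strand) in forward coordinates."""
    n = len(seq)
    out = []
    for strand in "+-":
        s = seq if strand == "+" else seq.translate(_COMP)[::-1]
        for frame in range(3):
            stops = [
                i for i in range(frame, n - 2, 3) if s[i : i + 3] in STOP_CODONS
            ]
            prev_stop_end = frame
            for stop in stops:
                starts = [
                    i
                    for i in range(prev_stop_end, stop, 3)
                    if s[i : i + 3] in START_CODONS
                ]
                if starts:
                    a, e = starts[0], stop + 3
                    if e - a >= min_nt:
                        if strand == "+":
                            out.append((a, e, "+"))
                        else:
                            out.append((n - e, n - a, "-"))
                prev_stop_end = stop + 3
    return out


def resolve_overlaps(orfs):
    """Keep-longer overlap resolution, ties leftmost, per strand; quadratic
    on purpose."""
    ordered = sorted(orfs, key=lambda t: (-(t[1] - t[0]), t[0], t[2]))
    kept = []
    for s, e, st in ordered:
        if all(st != ks[2] or e <= ks[0] or s >= ks[1] for ks in kept):
            kept.append((s, e, st))
    return sorted(kept)
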