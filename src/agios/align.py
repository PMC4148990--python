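"""Affine-gap global alignment (Needleman–Wunsch / Gotoh) with identity
accounting.

This is the computational core of the ortholog-identity statistic: every
ortholog pair is globally aligned here, and the per-column identity feeds the
genome-pair mean. The dynamic program is the standard three-state Gotoh
recurrence with end gaps penalized (true global alignment).

Scoring convention
------------------
A gap of length L costs ``gap_open + L * gap_extend``. The widely replicated
EMBOSS-needle defaults are used: nucleotide match +5 / mismatch −4, protein
BLOSUM62, gap open 10, gap extend 0.5. Half-point penalties are handled by
doubling every score internally so the DP stays in integers; the reported
``score`` is on that doubled scale (divide by two for the natural scale).

Identity convention: the denominator is the total number of alignment columns
including gap columns (the EMBOSS "Identity" convention); N (nucleotide) and
X (protein) score 0 against everything and never count as identical.
Tie-break in traceback: diagonal, then gap-in-b, then gap-in-a.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

NEG = np.int64(-(10**15))

_GAP = "-"


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties, on the doubled scale.

    ``matrix`` is indexed by encoded symbols; ``ambig_index`` marks the
    neutral symbol (N or X) whose row/column is all zeros and which never
    counts as an identity.
    """

    kind: str  # "nucleotide" | "protein"
    alphabet: str
    matrix: np.ndarray  # int64, doubled scale, symmetric
    gap_open: int  # doubled
    gap_extend: int  # doubled
    ambig_index: int

    def __post_init__(self):
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")

    @property
    def ambig_char(self) -> str:
        return self.alphabet[self.ambig_index]

    def encode(self, seq: str, fallback: bool = True) -> np.ndarray:
        idx = np.empty(len(seq), dtype=np.int64)
        for i, ch in enumerate(seq):
            p = self.alphabet.find(ch)
            if p < 0:
                if not fallback:
                    raise ValueError(f"symbol {ch!r} not in scoring alphabet")
                p = self.ambig_index
            idx[i] = p
        return idx


def _double(x: float, what: str) -> int:
    d = 2 * x
    if abs(d - round(d)) > 1e-9:
        raise ValueError(f"{what}={x} not representable in half-point units")
    return int(round(d))


def nucleotide_scheme(
    match: float = 5, mismatch: float = -4, gap_open: float = 10, gap_extend: float = 0.5
) -> ScoringScheme:
    """EDNAFULL-style nucleotide scheme (defaults mirror EMBOSS needle)."""
    alphabet = "ACGTN"
    m = np.full((5, 5), _double(mismatch, "mismatch"), dtype=np.int64)
    np.fill_diagonal(m, _double(match, "match"))
    m[4, :] = 0
    m[:, 4] = 0
    return ScoringScheme(
        "nucleotide", alphabet, m,
        _double(gap_open, "gap_open"), _double(gap_extend, "gap_extend"), 4,
    )


def protein_scheme(
    matrix_name: str = "BLOSUM62", gap_open: float = 10, gap_extend: float = 0.5
) -> ScoringScheme:
    """BLOSUM-family protein scheme; X is neutral (0 vs everything)."""
    from Bio.Align import substitution_matrices

    sub = substitution_matrices.load(matrix_name)
    alphabet = "ACDEFGHIKLMNPQRSTVWYX"
    n = len(alphabet)
    m = np.zeros((n, n), dtype=np.int64)
    for i, a in enumerate(alphabet[:-1]):
        for j, b in enumerate(alphabet[:-1]):
            m[i, j] = _double(float(sub[a][b]), f"{a}/{b}")
    # X row/column forced neutral regardless of the published matrix
    return ScoringScheme(
        "protein", alphabet, m,
        _double(gap_open, "gap_open"), _double(gap_extend, "gap_extend"), n - 1,
    )


@dataclass(frozen=True)
class AlignmentResult:
    """One global alignment: gapped rows, doubled-scale score, identity."""

    aligned_a: str
    aligned_b: str
    score: int
    length: int
    n_identical: int
    identity_pct: float


@njit(cache=False)
def _gotoh(a, b, sub, go, ge):  # pragma: no cover - exercised via global_align
    n, m = a.size, b.size
    M = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    X = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in b (consumes a)
    Y = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in a (consumes b)
    pm = np.zeros((n + 1, m + 1), dtype=np.uint8)
    px = np.zeros((n + 1, m + 1), dtype=np.uint8)
    py = np.zeros((n + 1, m + 1), dtype=np.uint8)
    M[0, 0] = 0
    for i in range(1, n + 1):
        X[i, 0] = -(go + i * ge)
        px[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = -(go + j * ge)
        py[0, j] = 0 if j == 1 else 2
    open_cost = go + ge
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = sub[ai, b[j - 1]]
            # match/mismatch state; tie-break M > X > Y
            best = M[i - 1, j - 1]
            st = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                st = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                st = 2
            M[i, j] = best + s
            pm[i, j] = st
            # gap in b
            best = M[i - 1, j] - open_cost
            st = 0
            if X[i - 1, j] - ge > best:
                best = X[i - 1, j] - ge
                st = 1
            if Y[i - 1, j] - open_cost > best:
                best = Y[i - 1, j] - open_cost
                st = 2
            X[i, j] = best
            px[i, j] = st
            # gap in a
            best = M[i, j - 1] - open_cost
            st = 0
            if X[i, j - 1] - open_cost > best:
                best = X[i, j - 1] - open_cost
                st = 1
            if Y[i, j - 1] - ge > best:
                best = Y[i, j - 1] - ge
                st = 2
            Y[i, j] = best
            py[i, j] = st

    state = 0
    score = M[n, m]
    if X[n, m] > score:
        score = X[n, m]
        state = 1
    if Y[n, m] > score:
        score = Y[n, m]
        state = 2

    moves = np.empty(n + m, dtype=np.uint8)  # 0 diag, 1 up(gap in b), 2 left
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            moves[k] = 0
            state = pm[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            moves[k] = 1
            state = px[i, j]
            i -= 1
        else:
            moves[k] = 2
            state = py[i, j]
            j -= 1
        k += 1
    return score, moves[:k][::-1]


def _seq_str(x) -> str:
    return x if isinstance(x, str) else x.seq


def global_align(a, b, scheme: ScoringScheme | None = None) -> AlignmentResult:
    """Optimal global alignment of two sequences under affine gap penalties.

    Accepts raw strings or NucSeq/ProtSeq. End gaps are penalized; the
    returned score is the global optimum on the doubled integer scale.
    """
    if scheme is None:
        scheme = nucleotide_scheme()
    sa, sb = _seq_str(a), _seq_str(b)
    if not sa or not sb:
        raise ValueError("global_align requires non-empty sequences")
    ea, eb = scheme.encode(sa), scheme.encode(sb)
    score, moves = _gotoh(ea, eb, scheme.matrix, scheme.gap_open, scheme.gap_extend)
    rows_a, rows_b = [], []
    i = j = 0
    for mv in moves:
        if mv == 0:
            rows_a.append(sa[i])
            rows_b.append(sb[j])
            i += 1
            j += 1
        elif mv == 1:
            rows_a.append(sa[i])
            rows_b.append(_GAP)
            i += 1
        else:
            rows_a.append(_GAP)
            rows_b.append(sb[j])
            j += 1
    aligned_a, aligned_b = "".join(rows_a), "".join(rows_b)
    n_id = count_identities(aligned_a, aligned_b, scheme.ambig_char)
    length = len(aligned_a)
    return AlignmentResult(
        aligned_a, aligned_b, int(score), length, n_id, 100.0 * n_id / length
    )


def count_identities(aligned_a: str, aligned_b: str, ambig: str = "N") -> int:
    """Identical columns; gaps and the neutral symbol never count."""
    return sum(
        1
        for x, y in zip(aligned_a, aligned_b)
        if x == y and x != _GAP and x != ambig
    )


def identity_between(a, b, scheme: ScoringScheme | None = None) -> float:
    """Percent identity of the optimal global alignment (gap-inclusive
    denominator); symmetric in its arguments."""
    return global_align(a, b, scheme).identity_pct


def rescore_alignment(aligned_a: str, aligned_b: str, scheme: ScoringScheme) -> int:
    """Re-derive the doubled-scale score of a gapped alignment column by
    column, with affine gap-run bookkeeping. Used to validate tracebacks."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned rows differ in length")
    score = 0
    prev = "M"
    for x, y in zip(aligned_a, aligned_b):
        if x == _GAP and y == _GAP:
            raise ValueError("column with gap in both rows")
        if x == _GAP:
            state = "Y"
        elif y == _GAP:
            state = "X"
        else:
            state = "M"
        if state == "M":
            ia = scheme.encode(x)[0]
            ib = scheme.encode(y)[0]
            score += int(scheme.matrix[ia, ib])
        else:
            score -= scheme.gap_extend
            if state != prev:
                score -= scheme.gap_open
        prev = state
    return score
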