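"""Exact optimal global pairwise alignment.

:func:`nw_align` implements Needleman–Wunsch with a fixed per-column gap
penalty; :func:`gotoh_align` implements Gotoh's three-matrix recurrence for
affine gap penalties.  Both fill integer score matrices row by row with
numpy (the within-row dependency on the left neighbour is resolved with a
max-plus prefix scan) and reconstruct one optimal alignment by backtracking
over the stored matrices.

Tie-breaking is deterministic: in the fixed recurrence the precedence is
diagonal > up > left, and in the affine recurrence F (diagonal) > P
(vertical gap) > Q (horizontal gap).  Any optimal path would be an equally
valid answer — scores are what downstream consumers compare — but a fixed
precedence keeps runs reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError
from .scoring import (
    GAP,
    AffineScoring,
    FixedScoring,
    Scoring,
    rescore_alignment,
    validate_dna,
)

__all__ = ["PairwiseAlignment", "nw_align", "gotoh_align", "exact_align"]


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment: two equal-length gapped rows and their score."""

    row_a: str
    row_b: str
    score: int

    def __post_init__(self) -> None:
        if len(self.row_a) != len(self.row_b):
            raise ContractError("alignment rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.row_a)

    def degapped(self) -> tuple[str, str]:
        """The two original (gap-free) sequences."""
        return self.row_a.replace(GAP, ""), self.row_b.replace(GAP, "")


def _seq_str(seq) -> str:
    """Accept either a plain string or an object with a ``seq`` attribute."""
    return seq.seq if hasattr(seq, "seq") else seq


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def nw_align(a, b, scheme: FixedScoring = FixedScoring()) -> PairwiseAlignment:
    """Optimal global alignment under a fixed gap penalty.

    The (n+1)x(m+1) score matrix is initialised with F[0,0]=0,
    F[i,0]=i*gap, F[0,j]=j*gap and filled with the classic three-way max
    over diagonal (substitution), up (gap in b) and left (gap in a).
    """
    a, b = _seq_str(a), _seq_str(b)
    validate_dna(a)
    validate_dna(b)
    n, m = len(a), len(b)
    gap = scheme.gap

    if n == 0 or m == 0:
        return PairwiseAlignment(GAP * m + a, b + GAP * n, gap * (n + m))

    av, bv = _encode(a), _encode(b)
    F = np.empty((n + 1, m + 1), dtype=np.int64)
    jg = gap * np.arange(m + 1, dtype=np.int64)
    F[0] = jg
    for i in range(1, n + 1):
        prev = F[i - 1]
        sub = np.where(bv == av[i - 1], scheme.match, scheme.mismatch)
        cand = np.maximum(prev[:-1] + sub, prev[1:] + gap)
        # F[i,j] = max(cand[j-1], F[i,j-1] + gap): a max-plus prefix scan.
        e = np.empty(m + 1, dtype=np.int64)
        e[0] = i * gap
        e[1:] = cand - jg[1:]
        F[i] = np.maximum.accumulate(e) + jg

    # Backtrack with precedence diagonal > up > left.
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 and j > 0:
        here = F[i, j]
        if here == F[i - 1, j - 1] + scheme.c(a[i - 1], b[j - 1]):
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif here == F[i - 1, j] + gap:
            out_a.append(a[i - 1])
            out_b.append(GAP)
            i -= 1
        else:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            j -= 1
    out_a.append(GAP * j + a[:i][::-1])
    out_b.append(b[:j][::-1] + GAP * i)
    return PairwiseAlignment(
        "".join(out_a)[::-1], "".join(out_b)[::-1], int(F[n, m])
    )


def gotoh_align(a, b, scheme: AffineScoring = AffineScoring()) -> PairwiseAlignment:
    """Optimal global alignment under an affine gap penalty g(L).

    Three matrices are maintained: F (best score ending in a substitution
    column or the overall best), P (ending with a gap in b, a vertical
    step) and Q (ending with a gap in a, a horizontal step).  Boundaries:
    F[i,0]=g(i), F[0,j]=g(j); the impossible boundary states of P and Q
    hold a finite sentinel more negative than any reachable score (chosen
    as -(|gap_open|+|gap_extend|+|mismatch|+match)*(n+m+2)-1 so integer
    arithmetic never wraps).  Backtracking may switch between matrices.
    """
    a, b = _seq_str(a), _seq_str(b)
    validate_dna(a)
    validate_dna(b)
    n, m = len(a), len(b)
    go, ge = scheme.gap_open, scheme.gap_extend

    if n == 0 and m == 0:
        return PairwiseAlignment("", "", 0)
    if n == 0 or m == 0:
        return PairwiseAlignment(GAP * m + a, b + GAP * n, scheme.g(n + m))

    neg = -(abs(go) + abs(ge) + abs(scheme.mismatch) + scheme.match) * (n + m + 2) - 1
    jg = ge * np.arange(m + 1, dtype=np.int64)

    F = np.empty((n + 1, m + 1), dtype=np.int64)
    P = np.empty((n + 1, m + 1), dtype=np.int64)
    Q = np.empty((n + 1, m + 1), dtype=np.int64)
    F[0] = go + jg
    F[0, 0] = 0
    F[1:, 0] = go + ge * np.arange(1, n + 1, dtype=np.int64)
    P[0] = neg
    P[:, 0] = neg
    Q[0] = neg
    Q[:, 0] = neg

    av, bv = _encode(a), _encode(b)
    for i in range(1, n + 1):
        P[i, 1:] = np.maximum(F[i - 1, 1:] + go + ge, P[i - 1, 1:] + ge)
        sub = np.where(bv == av[i - 1], scheme.match, scheme.mismatch)
        best = np.maximum(F[i - 1, :-1] + sub, P[i, 1:])  # j = 1..m, sans Q
        # Q[i,j] = max(F[i,j-1]+go+ge, Q[i,j-1]+ge) with
        # F[i,j-1] = max(best[j-1], Q[i,j-1]) collapses (go <= 0) to
        # Q[i,j] = max(d[j], Q[i,j-1]+ge): a max-plus prefix scan.
        d = np.empty(m + 1, dtype=np.int64)
        d[0] = neg
        d[1] = F[i, 0] + go + ge
        if m >= 2:
            d[2:] = best[:-1] + go + ge
        Q[i] = np.maximum.accumulate(d - jg) + jg
        F[i, 1:] = np.maximum(best, Q[i, 1:])

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    state = "F"
    while i > 0 or j > 0:
        if state == "F":
            if i == 0:
                out_a.append(GAP)
                out_b.append(b[j - 1])
                j -= 1
            elif j == 0:
                out_a.append(a[i - 1])
                out_b.append(GAP)
                i -= 1
            elif F[i, j] == F[i - 1, j - 1] + scheme.c(a[i - 1], b[j - 1]):
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i -= 1
                j -= 1
            elif F[i, j] == P[i, j]:
                state = "P"
            elif F[i, j] == Q[i, j]:
                state = "Q"
            else:  # pragma: no cover - recurrence guarantees one case
                raise ContractError("inconsistent backtrack state in F")
        elif state == "P":
            out_a.append(a[i - 1])
            out_b.append(GAP)
            if P[i, j] == F[i - 1, j] + go + ge:
                state = "F"
            i -= 1
        else:  # Q
            out_a.append(GAP)
            out_b.append(b[j - 1])
            if Q[i, j] == F[i, j - 1] + go + ge:
                state = "F"
            j -= 1
    row_a, row_b = "".join(out_a)[::-1], "".join(out_b)[::-1]
    score = int(F[n, m])
    # Backtrack validity is cheap to assert and guards the whole package.
    if rescore_alignment(row_a, row_b, scheme) != score:
        raise ContractError("backtracked rows do not rescore to F[n,m]")
    return PairwiseAlignment(row_a, row_b, score)


def exact_align(a, b, scheme: Scoring) -> PairwiseAlignment:
    """Dispatch to the optimal aligner matching the gap model."""
    if isinstance(scheme, AffineScoring):
        return gotoh_align(a, b, scheme)
    return nw_align(a, b, scheme)
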