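"""Independent brute-force oracles used to validate the aligners.

Everything here enumerates complete global alignments explicitly and
scores them by walking columns — no dynamic programming, no code shared
with the package — so a test agreeing with these functions checks the DP
implementations against an independent definition of optimality.
"""

from __future__ import annotations

GAP = "-"


def enumerate_alignments(a: str, b: str):
    """Yield every global alignment of a and b as a (row_a, row_b) pair.

    Alignments are built right-to-left from the three possible final
    columns (substitution, gap in b, gap in a); no column is a double gap.
    """
    if not a and not b:
        yield "", ""
        return
    if a and b:
        for ra, rb in enumerate_alignments(a[:-1], b[:-1]):
            yield ra + a[-1], rb + b[-1]
    if a:
        for ra, rb in enumerate_alignments(a[:-1], b):
            yield ra + a[-1], rb + GAP
    if b:
        for ra, rb in enumerate_alignments(a, b[:-1]):
            yield ra + GAP, rb + b[-1]


def score_fixed(row_a: str, row_b: str, match: int, mismatch: int, gap: int) -> int:
    total = 0
    for x, y in zip(row_a, row_b):
        if x == GAP or y == GAP:
            total += gap
        elif x == y:
            total += match
        else:
            total += mismatch
    return total


def score_affine(
    row_a: str, row_b: str, match: int, mismatch: int, open_: int, extend: int
) -> int:
    total = 0
    run_row = None
    for x, y in zip(row_a, row_b):
        if x == GAP or y == GAP:
            row = "a" if x == GAP else "b"
            if row != run_row:
                total += open_
            total += extend
            run_row = row
        else:
            total += match if x == y else mismatch
            run_row = None
    return total


def best_fixed_score(a: str, b: str, match: int, mismatch: int, gap: int) -> int:
    return max(
        score_fixed(ra, rb, match, mismatch, gap)
        for ra, rb in enumerate_alignments(a, b)
    )


def best_affine_score(
    a: str, b: str, match: int, mismatch: int, open_: int, extend: int
) -> int:
    return max(
        score_affine(ra, rb, match, mismatch, open_, extend)
        for ra, rb in enumerate_alignments(a, b)
    )


def best_scores_both(a, b, fixed_params, affine_params):
    """Optimal fixed and affine scores from one enumeration pass."""
    best_f = best_g = None
    for ra, rb in enumerate_alignments(a, b):
        f = score_fixed(ra, rb, *fixed_params)
        g = score_affine(ra, rb, *affine_params)
        best_f = f if best_f is None else max(best_f, f)
        best_g = g if best_g is None else max(best_g, g)
    return best_f, best_g
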