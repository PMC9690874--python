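"""Scoring schemes for global pairwise alignment.

Two gap models are supported:

* **fixed** — every gap column costs the same constant ``gap``;
* **affine** — a contiguous gap run of length ``L`` costs
  ``gap_open + L * gap_extend``, favouring one long indel over many short
  ones, which matches how single mutational events behave.

:func:`rescore_alignment` scores an already-gapped alignment from its rows
alone.  It is deliberately independent of the dynamic-programming aligners
and serves as the arbiter for every reported alignment score in the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

from .errors import ContractError

GAP = "-"
DNA_ALPHABET = frozenset("ACGT")


@dataclass(frozen=True)
class FixedScoring:
    """Match/mismatch scores plus a constant per-gap-column penalty.

    Defaults are the common 1 / -1 / -2 scheme.
    """

    match: int = 1
    mismatch: int = -1
    gap: int = -2

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch >= 0:
            raise ValueError("mismatch score must be negative")
        if self.gap >= 0:
            raise ValueError("gap score must be negative")

    def c(self, x: str, y: str) -> int:
        """Column score for a pair of characters (bases or a gap symbol)."""
        if x == GAP or y == GAP:
            if x == GAP and y == GAP:
                raise ContractError("two gap symbols are never aligned")
            return self.gap
        return self.match if x == y else self.mismatch


@dataclass(frozen=True)
class AffineScoring:
    """Match/mismatch scores plus an affine gap-run penalty g(L).

    ``g(L) = gap_open + L * gap_extend`` for a run of L >= 1 gap columns.
    ``gap_open == 0`` is permitted: the model then degenerates to a fixed
    penalty of ``gap_extend`` per column.
    """

    match: int = 1
    mismatch: int = -1
    gap_open: int = -3
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch >= 0:
            raise ValueError("mismatch score must be negative")
        if self.gap_open > 0:
            raise ValueError("gap_open must be <= 0")
        if self.gap_extend >= 0:
            raise ValueError("gap_extend must be negative")

    def g(self, length: int) -> int:
        """Cost of a maximal gap run of ``length`` columns."""
        if length < 0:
            raise ValueError("gap run length must be non-negative")
        if length == 0:
            return 0
        return self.gap_open + length * self.gap_extend

    def c(self, x: str, y: str) -> int:
        """Column score for a base-base column (gaps are priced per run)."""
        if x == GAP or y == GAP:
            raise ContractError("affine gap columns are scored per run via g()")
        return self.match if x == y else self.mismatch


Scoring = Union[FixedScoring, AffineScoring]


def validate_dna(seq: str) -> None:
    """Raise if ``seq`` contains characters outside A/C/G/T."""
    from .errors import InvalidSequenceError

    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise InvalidSequenceError(
            f"sequence contains non-DNA characters: {sorted(bad)!r} "
            "(only A/C/G/T are accepted; N is not supported)"
        )


def rescore_alignment(row_a: str, row_b: str, scheme: Scoring) -> int:
    """Score a gapped alignment directly from its two rows.

    Fixed scheme: sum of the column scores.  Affine scheme: sum of the
    base-base column scores plus ``g(L)`` for each maximal contiguous run of
    L gap columns in either row.

    Raises :class:`ContractError` on unequal row lengths or a column that is
    a gap in both rows.
    """
    if len(row_a) != len(row_b):
        raise ContractError("alignment rows must have equal length")

    if isinstance(scheme, FixedScoring):
        score = 0
        for x, y in zip(row_a, row_b):
            score += scheme.c(x, y)  # raises on the double-gap column
        return score

    score = 0
    run_row: str | None = None  # which row the current gap run lives in
    run_len = 0
    for x, y in zip(row_a, row_b):
        if x == GAP and y == GAP:
            raise ContractError("two gap symbols are never aligned")
        if x == GAP or y == GAP:
            row = "a" if x == GAP else "b"
            if row == run_row:
                run_len += 1
            else:
                if run_row is not None:
                    score += scheme.g(run_len)
                run_row, run_len = row, 1
        else:
            if run_row is not None:
                score += scheme.g(run_len)
                run_row, run_len = None, 0
            score += scheme.c(x, y)
    if run_row is not None:
        score += scheme.g(run_len)
    return score
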