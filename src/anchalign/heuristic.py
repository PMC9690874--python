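"""Lookup-anchored heuristic global alignment.

Given a lookup table of stored subalignments, aligning a new sequence pair
proceeds in five steps:

1. :func:`find_occurrences` — locate every stored gapless string in each
   sequence (all occurrences, overlaps included);
2. :func:`pair_candidates` — join occurrence pairs against the lookup
   table (in both orientations — a stored row is usable with its two rows
   swapped, since alignment is symmetric) and rank by score;
3. :func:`distance_filter` — drop candidates whose start offsets are so far
   apart that bridging them would cost more gap penalty than the
   subalignment scores;
4. :func:`greedy_select` — walk candidates best-first and accept each one
   whose base intervals are free in both sequences *and* colinear with the
   anchors accepted so far;
5. :func:`align_residuals` — align the regions between consecutive anchors
   (and the prefix/suffix) exactly, splice everything together, and rescore
   the full rows under the global scheme.

If no anchor survives, the exact aligner's result is returned unchanged,
so the heuristic can never fail — only fall back.  Its score is always a
lower bound on the optimum because the reconstructed rows are themselves a
valid global alignment.

All coordinates are 0-based, half-open intervals.
"""

from __future__ import annotations

from bisect import bisect_left, insort
from dataclasses import dataclass

from .errors import ContractError
from .pairwise import PairwiseAlignment, exact_align
from .scoring import GAP, AffineScoring, FixedScoring, Scoring, rescore_alignment
from .store import LookupRow, SubalignmentStore

__all__ = [
    "OccurrenceHit",
    "Candidate",
    "AnchorBlock",
    "HeuristicResult",
    "LookupIndex",
    "find_occurrences",
    "pair_candidates",
    "distance_filter",
    "greedy_select",
    "align_residuals",
    "heuristic_align",
]


@dataclass(frozen=True)
class OccurrenceHit:
    """One occurrence of a stored gapless string: table id + 0-based start."""

    subseq_id: int
    start: int


@dataclass(frozen=True)
class Candidate:
    """A located, score-ranked subalignment hit for a concrete pair.

    ``ind1``/``ind2`` are the starts of the gapless strings in sequences A
    and B.  ``swapped`` marks the mirrored orientation: the stored row pair
    is used with its rows exchanged.
    """

    lookup: LookupRow
    ind1: int
    ind2: int
    swapped: bool = False

    @property
    def score(self) -> int:
        return self.lookup.score

    @property
    def row_a(self) -> str:
        return self.lookup.aligned_b if self.swapped else self.lookup.aligned_a

    @property
    def row_b(self) -> str:
        return self.lookup.aligned_a if self.swapped else self.lookup.aligned_b

    @property
    def r_a(self) -> int:
        return len(self.row_a) - self.row_a.count(GAP)

    @property
    def r_b(self) -> int:
        return len(self.row_b) - self.row_b.count(GAP)


@dataclass(frozen=True)
class AnchorBlock:
    """An accepted anchor: disjoint, colinear base intervals in both
    sequences plus the stored subalignment rows spliced in verbatim.

    ``[p_a, p_a + r_a)`` and ``[p_b, p_b + r_b)`` are the occupied base
    intervals; ``r`` is the gapless length of each row (r <= k)."""

    p_a: int
    p_b: int
    r_a: int
    r_b: int
    aligned_a: str
    aligned_b: str
    score: int


@dataclass(frozen=True)
class HeuristicResult:
    alignment: PairwiseAlignment
    utilized: bool
    n_anchors: int


class LookupIndex:
    """In-memory search index over a store's lookup tables.

    Building the index fetches aligned_subseq and lookup once; afterwards
    occurrence search and the candidate join run without touching the
    backend, so one index serves many alignments against the same tables.
    The occurrence search is naive multi-pattern scanning (``str.find``),
    which is adequate at the scale this package targets; it is isolated
    here so a suffix-automaton index could replace it.
    """

    def __init__(self, subseqs: list[tuple[int, str]], rows: list[LookupRow]) -> None:
        self.subseqs: dict[int, str] = dict(subseqs)
        self.rows = rows
        self.rows_by_a: dict[int, list[LookupRow]] = {}
        self.rows_by_b: dict[int, list[LookupRow]] = {}
        for row in rows:
            self.rows_by_a.setdefault(row.subseq_a_id, []).append(row)
            self.rows_by_b.setdefault(row.subseq_b_id, []).append(row)

    @classmethod
    def from_store(cls, store: SubalignmentStore) -> "LookupIndex":
        return cls(store.subseqs(), store.lookup_rows())

    def find_occurrences(self, seq) -> list[OccurrenceHit]:
        seq = seq.seq if hasattr(seq, "seq") else seq
        hits: list[OccurrenceHit] = []
        for sid in sorted(self.subseqs):
            pattern = self.subseqs[sid]
            start = seq.find(pattern)
            while start != -1:
                hits.append(OccurrenceHit(sid, start))
                start = seq.find(pattern, start + 1)
        return hits


def _as_index(source) -> LookupIndex:
    if isinstance(source, LookupIndex):
        return source
    return LookupIndex.from_store(source)


def find_occurrences(source, seq) -> list[OccurrenceHit]:
    """All (possibly overlapping) occurrences of every stored gapless
    string in ``seq``, sorted by subseq id then start.  ``source`` is a
    store or a prebuilt :class:`LookupIndex`."""
    return _as_index(source).find_occurrences(seq)


def pair_candidates(
    source, hits_a: list[OccurrenceHit], hits_b: list[OccurrenceHit]
) -> list[Candidate]:
    """Join occurrence pairs against the lookup table.

    A lookup row matches in forward orientation when its a-side string
    occurs in A and its b-side string in B, and in swapped orientation for
    the mirror case (skipped when both sides reference the same string, to
    avoid duplicates).  Result is ordered by score descending, ties broken
    by (ind1, ind2, lookup id) ascending.
    """
    index = _as_index(source)
    occ_a: dict[int, list[int]] = {}
    for h in hits_a:
        occ_a.setdefault(h.subseq_id, []).append(h.start)
    occ_b: dict[int, list[int]] = {}
    for h in hits_b:
        occ_b.setdefault(h.subseq_id, []).append(h.start)

    out: list[Candidate] = []
    for sid, starts_a in occ_a.items():
        for row in index.rows_by_a.get(sid, ()):
            starts_b = occ_b.get(row.subseq_b_id)
            if starts_b:
                for i1 in starts_a:
                    for i2 in starts_b:
                        out.append(Candidate(row, i1, i2, swapped=False))
        for row in index.rows_by_b.get(sid, ()):
            if row.subseq_a_id == row.subseq_b_id:
                continue  # forward orientation already covered it
            starts_b = occ_b.get(row.subseq_a_id)
            if starts_b:
                for i1 in starts_a:
                    for i2 in starts_b:
                        out.append(Candidate(row, i1, i2, swapped=True))
    out.sort(key=lambda c: (-c.score, c.ind1, c.ind2, c.lookup.id))
    return out


def distance_filter(candidate: Candidate, scheme: Scoring) -> bool:
    """Keep a candidate only if its start offsets are close enough.

    A start-index offset of d forces at least d bridging gap columns, so a
    candidate is kept when that minimum bridging penalty stays below its
    score: fixed scheme ``-d*gap < score``; affine scheme
    ``-(d*gap_extend + gap_open) < score``.  Zero offset needs no bridging
    gap and is always kept.
    """
    d = abs(candidate.ind1 - candidate.ind2)
    if d == 0:
        return True
    if isinstance(scheme, AffineScoring):
        return -(d * scheme.gap_extend + scheme.gap_open) < candidate.score
    return -d * scheme.gap < candidate.score


def greedy_select(
    candidates: list[Candidate], len_a: int, len_b: int
) -> list[AnchorBlock]:
    """Best-first anchor selection under occupancy and colinearity.

    Candidates are scanned in their given (score-descending) order.  One is
    accepted iff its base intervals are unoccupied in both sequences and it
    is colinear with every anchor accepted so far, i.e. both of its
    intervals fall into the same inter-anchor region.  Accepted anchors
    mark their positions; the result is sorted by position.
    """
    occ_a = bytearray(len_a)
    occ_b = bytearray(len_b)
    starts_a: list[int] = []
    starts_b: list[int] = []
    blocks: list[AnchorBlock] = []
    for cand in candidates:
        ia, ib = cand.ind1, cand.ind2
        ra, rb = cand.r_a, cand.r_b
        if ia + ra > len_a or ib + rb > len_b:
            continue
        if any(occ_a[ia : ia + ra]) or any(occ_b[ib : ib + rb]):
            continue
        # Intervals are disjoint from all accepted anchors, so rank in the
        # anchor order is well defined; equal ranks <=> colinear.
        if bisect_left(starts_a, ia) != bisect_left(starts_b, ib):
            continue
        occ_a[ia : ia + ra] = b"\x01" * ra
        occ_b[ib : ib + rb] = b"\x01" * rb
        insort(starts_a, ia)
        insort(starts_b, ib)
        blocks.append(
            AnchorBlock(ia, ib, ra, rb, cand.row_a, cand.row_b, cand.score)
        )
    blocks.sort(key=lambda blk: blk.p_a)
    return blocks


def align_residuals(
    a, b, blocks: list[AnchorBlock], scheme: Scoring
) -> PairwiseAlignment:
    """Splice anchors into a full global alignment.

    Regions between consecutive anchors (plus the prefix and suffix) are
    aligned exactly under the same scheme; anchor rows are inserted
    verbatim.  The final score is obtained by rescoring the concatenated
    rows — not by summing part scores, which under affine penalties would
    re-charge the opening of a gap run spanning a part boundary.
    """
    a = a.seq if hasattr(a, "seq") else a
    b = b.seq if hasattr(b, "seq") else b
    blocks = sorted(blocks, key=lambda blk: blk.p_a)
    parts_a: list[str] = []
    parts_b: list[str] = []
    pos_a = pos_b = 0
    for blk in blocks:
        if blk.p_a < pos_a or blk.p_b < pos_b:
            raise ContractError("anchor blocks overlap or are not colinear")
        if a[blk.p_a : blk.p_a + blk.r_a] != blk.aligned_a.replace(GAP, ""):
            raise ContractError("anchor row does not match sequence A at p_a")
        if b[blk.p_b : blk.p_b + blk.r_b] != blk.aligned_b.replace(GAP, ""):
            raise ContractError("anchor row does not match sequence B at p_b")
        gap_a = a[pos_a : blk.p_a]
        gap_b = b[pos_b : blk.p_b]
        if gap_a or gap_b:
            sub = exact_align(gap_a, gap_b, scheme)
            parts_a.append(sub.row_a)
            parts_b.append(sub.row_b)
        parts_a.append(blk.aligned_a)
        parts_b.append(blk.aligned_b)
        pos_a = blk.p_a + blk.r_a
        pos_b = blk.p_b + blk.r_b
    tail_a, tail_b = a[pos_a:], b[pos_b:]
    if tail_a or tail_b:
        sub = exact_align(tail_a, tail_b, scheme)
        parts_a.append(sub.row_a)
        parts_b.append(sub.row_b)
    row_a = "".join(parts_a)
    row_b = "".join(parts_b)
    return PairwiseAlignment(row_a, row_b, rescore_alignment(row_a, row_b, scheme))


def heuristic_align(
    a,
    b,
    store,
    scheme: Scoring = FixedScoring(),
    index: LookupIndex | None = None,
    hits_a: list[OccurrenceHit] | None = None,
    hits_b: list[OccurrenceHit] | None = None,
) -> HeuristicResult:
    """Full anchored-alignment pipeline for one sequence pair.

    ``index`` (and per-sequence ``hits_a``/``hits_b``) may be precomputed
    and shared across pairs — the all-vs-all harness does this so each
    sequence is scanned once.  When no anchor survives filtering, the exact
    aligner's result is returned with ``utilized=False``.
    """
    if index is None:
        index = _as_index(store)
    a_str = a.seq if hasattr(a, "seq") else a
    b_str = b.seq if hasattr(b, "seq") else b
    if index.rows:
        if hits_a is None:
            hits_a = index.find_occurrences(a_str)
        if hits_b is None:
            hits_b = index.find_occurrences(b_str)
        candidates = pair_candidates(index, hits_a, hits_b)
        candidates = [c for c in candidates if distance_filter(c, scheme)]
        blocks = greedy_select(candidates, len(a_str), len(b_str))
    else:
        blocks = []
    if not blocks:
        return HeuristicResult(exact_align(a_str, b_str, scheme), False, 0)
    alignment = align_residuals(a_str, b_str, blocks, scheme)
    return HeuristicResult(alignment, True, len(blocks))
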