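# Methods

## Problem and model

`anchalign` targets the all-vs-all global alignment of a family of
*similar* DNA sequences (alphabet A/C/G/T; degenerate bases such as N are
rejected at load). Scores are maximised; two gap models are supported:

* **fixed** — every gap column scores `gap` (< 0); optimum by
  Needleman–Wunsch dynamic programming over an (n+1)×(m+1) matrix;
* **affine** — a maximal gap run of length L scores
  `g(L) = gap_open + L·gap_extend` (`gap_open ≤ 0`, `gap_extend < 0`);
  optimum by Gotoh's three-matrix recurrence. `gap_open = 0` is allowed
  and reduces the model to a fixed penalty of `gap_extend`, which the
  tests exploit as a cross-check between the two aligners.

Defaults: match/mismatch/gap = 1/−1/−2, gap_open/gap_extend = −3/−1 — a
widely used DNA scoring choice.

The heuristic assumes family members are similar enough that optimal
alignments of sampled pairs contain windows that recur (possibly shifted)
in other pairs. Under high divergence the lookup table simply stops
matching and the method degrades gracefully to the exact aligner.

## Numerical and algorithmic choices

* **Integer scores throughout**; the DP matrices are int64 and no floating
  point enters any alignment score.
* **Tie-breaking** in the DP maxima is fixed: diagonal > up > left, and in
  the affine backtrack F > P > Q. Any optimal path is acceptable — all
  consumers compare scores — but a fixed precedence makes runs
  byte-reproducible.
* **Affine boundary sentinel**: the impossible P/Q boundary states hold a
  finite value `-(|gap_open|+|gap_extend|+|mismatch|+match)·(n+m+2) − 1`,
  strictly below any reachable path score, so ordinary integer max/plus
  arithmetic applies without overflow or IEEE infinities.
* **Row-vectorised fill**: the within-row dependency on the left
  neighbour (and, in Gotoh, on the horizontal-gap matrix Q of the same
  row) is an associative max-plus recurrence, solved per row with
  `numpy.maximum.accumulate` after subtracting the linear gap ramp. This
  keeps a 300×300 alignment under a millisecond without any compiled
  extension.
* **Empty inputs**: the empty-vs-empty alignment is two empty rows with
  score 0; empty-vs-sequence is all gaps, scored `m·gap` or `g(m)`.
* **Alignment scores are always re-derived** from the rows by
  `rescore_alignment`, an independent column/run-walking scorer; the Gotoh
  backtrack asserts this agreement on every call.

## The lookup table

* Windows are **k alignment columns** (so stored gap-free strings have
  length r ≤ k); one window per column offset. A window is stored iff its
  (window-local) score ≥ `threshold` (default `ceil(k/2)·match`;
  inclusive, with a `strict` flag for `>`), and neither de-gapped row is
  empty.
* Lookup rows are **deduplicated on the gapped row pair** — duplicates
  carry no information and would only widen the candidate join — and each
  row is stored once, in sample-pair order; the search phase matches both
  orientations instead of storing mirrored rows, halving the table.
* The gap-free strings live in their own table (`aligned_subseq`,
  unique), bounded by `4·(4^k−1)/3` possible strings and in practice by
  the number of windows the sample produces (~`z²·h_avg`).
* Rebuilding clears both tables first, so a rebuild with the same sample
  and config is bit-identical.
* Storage is a small contract; the default backend is embedded SQLite
  (`:memory:` or a file), with a dict-based backend that must — and is
  tested to — produce identical tables. The candidate join runs over an
  in-memory index (`LookupIndex`) built once per table and shared across
  pairs; per-pair SQL round-trips would dominate runtime at no benefit at
  this scale. Occurrence search is naive `str.find` multi-pattern
  scanning behind the same index, swappable for a suffix-automaton
  should table sizes grow by orders of magnitude.

## The anchoring phase

* Coordinates are 0-based half-open everywhere.
* The distance filter keeps a candidate iff the minimal bridging penalty
  of its start offset d = |ind1−ind2| stays below its score:
  `−d·gap < score` (fixed), `−(d·gap_extend + gap_open) < score`
  (affine). Candidates with d = 0 are always kept — a zero offset needs
  no bridging gap, so applying the affine formula (which would charge a
  phantom opening) makes no sense there.
* Greedy selection scans candidates by descending score (ties: smaller
  ind1, ind2, table id first) and accepts one iff its base intervals are
  unoccupied in both sequences **and colinear** with every accepted
  anchor — both intervals must fall into the same inter-anchor region.
  Occupancy alone would admit order-crossing anchors, from which no
  single global alignment can be reconstructed; rejecting them is a
  correctness requirement, though it can slightly lower the utilization
  rate compared with occupancy-only counting.
* Residual regions (before, between and after anchors) are aligned
  exactly under the same scheme with standard boundary initialisation; no
  gap-run context is carried across region borders (conservative: a run
  spanning a border may be charged one extra opening, never undercharged).
  The final score is obtained by rescoring the spliced rows under the
  global scheme rather than summing part scores, which under affine
  penalties would double-charge openings at part boundaries.
* With no surviving anchor the exact aligner's result is returned
  unchanged (`utilized = False`), so the heuristic score is always ≤ the
  optimum and equals it whenever anchoring was consistent with an optimal
  path.

## Synthetic families

The generator emulates data sets produced by evolving a root sequence
under a Jukes–Cantor-style process along a **star topology**: one uniform
random root of `avg_length`, each member derived independently with
`round(avg_distance/2)` mutation events, so two members are separated by
≈ `avg_distance` events. "Average distance" is thus mapped to expected
mutation-event count on the inter-leaf path — an approximation chosen
because the original data generator's parameterisation (guide tree,
site rates) is not specified; the parameter is exposed. Each event is a
substitution (probability `1 − indel_prob`; uniform position, uniform
different base) or an indel (insertion/deletion with equal odds,
geometric length). Defaults `indel_prob = 0.05`, `indel_len_mean = 2`
keep gaps rare and short — the similar-sequence regime the heuristic
assumes. Deletions are clamped so a sequence never becomes empty.
Presets d50/h100/h200/h300 carry the standard study conditions
(100 sequences; lengths 100/200/300; distances 50/100).

What the generator does **not** emulate: site-specific rate variation,
transition/transversion bias, guide-tree topology, long structural
indels, or N bases. Metrics measured on these families therefore
reproduce the *trends* of real benchmarks (utilization falling and sd
shrinking as k grows; affine sd below fixed sd) but not any particular
published numeric value.

## Benchmark metrics

Per repeat (fresh sample, rebuilt table, all n(n−1)/2 pairs aligned both
ways): **sd** = sqrt(mean((scoreH − scoreO)²)) over utilized pairs only;
**utilization rate** = % of pairs with ≥ 1 anchor; **exact-match rate** =
% of utilized pairs with scoreH = scoreO (also reported over all pairs,
where fallback pairs are trivially exact, to remove any ambiguity about
the denominator). With zero utilized pairs, sd and the exact-match rate
are reported as undefined (`None`) rather than 0. Because sampling is
random the harness repeats each setting (5 repeats by default in the CLI)
and averages; wall-clock timings are logged per phase but are
informational only — they depend on hardware and are never asserted.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run generated families of 20
sequences (length 100) for trend checks and 100 sequences (length 100,
distance 50; 4950 pairs) for the full benchmark, with 3–5 repeats per
setting — sizes at which every exact-vs-heuristic comparison is fast
enough to run routinely while still exercising the whole pipeline.
Oracle tests enumerate all global alignments explicitly for sequences up
to length 6.

## Known limitations

* The lookup build aligns all z(z−1)/2 sample pairs eagerly; incremental
  updates when the family grows are not implemented.
* Anchors are accepted greedily; a dynamic-programming chaining step
  could pick a better-scoring compatible subset.
* Degenerate bases (N) are rejected rather than expanded or specially
  scored.
* Local-alignment harvesting, protein alphabets and similarity matrices
  (PAM/BLOSUM) are out of scope.
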