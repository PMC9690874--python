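"""Anchored heuristic alignment of a new sequence pair.

Stored subalignments found in both sequences become anchors (best score
first, kept only if non-overlapping and colinear); the leftover regions
between anchors are aligned exactly and everything is spliced together.
The heuristic score can never exceed the optimum — equality means the
anchors were consistent with an optimal alignment.
"""

from anchalign import (
    FamilyParams,
    FixedScoring,
    LookupConfig,
    SubalignmentStore,
    generate_family,
    heuristic_align,
    nw_align,
)

family = generate_family(FamilyParams(n_sequences=12, avg_length=80,
                                      avg_distance=30, seed=7))
store = SubalignmentStore()
store.load_sequences(family)
store.draw_sample(z=6, seed=1)
store.build_lookup(LookupConfig(k=8, z=6))

scheme = FixedScoring()
a, b = family[10], family[11]  # two sequences outside the sample
res = heuristic_align(a.seq, b.seq, store, scheme)
opt = nw_align(a.seq, b.seq, scheme)

print(f"pair {a.id} vs {b.id}")
print(f"  heuristic score : {res.alignment.score}")
print(f"  optimal score   : {opt.score}")
print(f"  anchors used    : {res.n_anchors} (utilized={res.utilized})")
print(res.alignment.row_a)
print(res.alignment.row_b)
# utilized=True means at least one stored subalignment was anchored; with
# an empty lookup table the result would be exactly the optimal alignment.
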