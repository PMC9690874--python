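"""Exact global alignment under fixed and affine gap penalties.

Aligns two short DNA sequences with Needleman-Wunsch (every gap column
costs the same) and with Gotoh's algorithm (a gap run of length L costs
gap_open + L*gap_extend, so one long indel is cheaper than many short
ones), and prints both alignments.
"""

from anchalign import AffineScoring, FixedScoring, gotoh_align, nw_align

a = "ACGTACGTTACG"
b = "ACGTTACGTACG"

fixed = nw_align(a, b, FixedScoring(match=1, mismatch=-1, gap=-2))
print("fixed gap penalty (1/-1/-2):")
print(" ", fixed.row_a)
print(" ", fixed.row_b)
print("  score =", fixed.score)

affine = gotoh_align(a, b, AffineScoring(1, -1, gap_open=-3, gap_extend=-1))
print("affine gap penalty (open -3, extend -1):")
print(" ", affine.row_a)
print(" ", affine.row_b)
print("  score =", affine.score)

# Both scores are optimal for their scheme; the affine aligner will group
# gap columns into runs where the fixed aligner is indifferent.
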