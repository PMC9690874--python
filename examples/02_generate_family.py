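"""Generate a synthetic family of similar DNA sequences.

Families emulate a star-shaped evolutionary history: one random root, each
member derived independently by substitutions (Jukes-Cantor style) and
rare short indels, so two members are separated by ~avg_distance mutation
events.  The presets (d50, h100, h200, h300) name the standard study
conditions; d50 is the least diverse (length 100, distance 50).
"""

from anchalign import FamilyParams, generate_family, write_fasta

params = FamilyParams(
    n_sequences=6, avg_length=80, avg_distance=30, indel_prob=0.05, seed=7
)
family = generate_family(params)
for s in family:
    print(f"{s.id}  len={len(s.seq)}  {s.seq[:50]}...")

write_fasta(family, "family.fasta")
print("wrote family.fasta")
# Lengths vary slightly because ~5% of mutation events are indels; the
# sequences agree at most positions, which is what the anchored heuristic
# exploits.
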