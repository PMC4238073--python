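"""Tour the canonical 29-character description schema.

Prints every character with its body region, value kind and coded
states, then exercises two of the measurement rules.  The letters (a, b,
...) are the codes stored in the species-by-character matrix.
"""

from megakey import canonical_schema, classify_labellum, compute_costal_index

for d in canonical_schema():
    states = ", ".join(f"{s.code}={s.label}" for s in d.states)
    print(f"{d.region:<10} {d.id:<26} {d.kind:<18} {states}")

print()
print("costal index for a 1.014 mm costa on a 1.56 mm wing:",
      compute_costal_index(1.014, 1.56))
print("labellum with 29 scattered spinose setulae:",
      classify_labellum(29, True).label)
print("labellum with 30:", classify_labellum(30, True).label)
# The costal index is the costa's fraction of the wing length (always <= 1);
# 30 setulae per labellum is where 'sparse' tips over into 'dense'.
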