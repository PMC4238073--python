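"""Identify a partially-known specimen against a matrix, with tolerance.

A query answers any subset of characters.  Numeric characters carry a
relative tolerance window (default 10%, anchored on each species'
recorded value) so re-measurement noise does not eliminate the right
species; every species is ranked, never deleted.
"""

from megakey import (
    GeneratorConfig,
    ToleranceConfig,
    build_description,
    build_matrix,
    generate_species,
    match,
    next_best_character,
)
from megakey.datasets import shadeae_description

fauna = generate_species(GeneratorConfig(n_species=15, seed=3))
m = build_matrix([shadeae_description(), *fauna])

query = build_description("unknown specimen", {
    "wing_length_mm": 1.60,       # measured 2.6% off the recorded 1.56
    "r2_3": "present",
    "labellum": "dense",
    "posterior_setation": "T6~E~H<C",
})
results = match(query, m, ToleranceConfig(relative_tolerance=0.10))
print(f"{'rank':>4} {'mismatch':>8} {'unknown':>7}  taxon")
for r in results[:5]:
    print(f"{r.rank:>4} {r.mismatch_count:>8} {r.unknown_count:>7}  {r.taxon_name}")
# Rank 1 with mismatch 0 means every answered character is compatible;
# 'unknown' counts characters skipped because either side is unscored.

survivors = {r.taxon_name for r in results if r.mismatch_count == 0}
if len(survivors) > 1:
    answered = set(query.known_ids())
    print("most discriminating next character:",
          next_best_character(m, survivors, answered))
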