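"""Build a coded matrix and find a rare character by keyword.

Extremely rare characters (like a pigmented wing spot) are kept out of
the coded columns and live in free-text remarks; the matrix indexes
every remark token so such species are found instantly by keyword.
"""

from megakey import (
    GeneratorConfig,
    build_matrix,
    generate_species,
    keyword_search,
    load_matrix,
    save_matrix,
)
from megakey.datasets import shadeae_description

fauna = generate_species(GeneratorConfig(n_species=10, seed=7))
m = build_matrix([shadeae_description(), *fauna])
print("matrix:", len(m), "species x", len(m.columns), "characters")

print("search 'wing spot'   ->", keyword_search(m, "wing spot"))
print("search 'LARGE FORK'  ->", keyword_search(m, "LARGE FORK"))
print("search 'scaled spot' ->", keyword_search(m, "scaled spot"))
# Only the species whose remarks contain every query token is returned;
# the synthetic species carry no remarks, so they never match.

text = save_matrix(m)
print("persisted and reloaded identically:", load_matrix(text) == m)
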