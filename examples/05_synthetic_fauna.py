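"""Generate a synthetic fauna and measure identification recovery.

50 schema-valid species are drawn with a pairwise coded-separation floor
of 3 characters; each is then 're-measured' with +-5% numeric noise and
identified against the matrix at the default 10% tolerance.
"""

from megakey import (
    GeneratorConfig,
    ToleranceConfig,
    build_matrix,
    coded_hamming,
    generate_species,
    match,
    perturb_description,
)

cfg = GeneratorConfig(n_species=50, seed=42, min_pairwise_separation=3)
fauna = generate_species(cfg)
m = build_matrix(fauna)

dmin = min(coded_hamming(a, b)
           for i, a in enumerate(fauna) for b in fauna[i + 1:])
print("species:", len(fauna), "| minimum pairwise coded distance:", dmin)

tol = ToleranceConfig(relative_tolerance=0.10)
recovered = 0
for i, d in enumerate(fauna):
    q = perturb_description(d, numeric_noise=0.05, flip_count=0, seed=1000 + i)
    recovered += match(q, m, tol)[0].taxon_name == d.taxon_name
print(f"rank-1 recovery under +-5% noise: {recovered}/{len(fauna)}")
# 50/50 shows the tolerance window absorbs measurement noise when the
# fauna is separable; near-cryptic faunas (separation 1) need not recover.
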