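# megakey

Table-based morphological descriptions, coded character matrices and
tolerance-aware multi-access identification keys for ***Megaselia***
(Diptera: Phoridae).

*Megaselia* is an "open-ended taxon": a single genus holding roughly half
of all phorid species, most of them undescribed. Traditional verbose
descriptions ("light brown" vs "brown", "medium long" vs "medium short")
make both describing and identifying this fauna painfully slow. The
streamlined alternative is a fixed table of 29 well-defined characters —
5 head, 5 thorax, 6 leg, 10 wing, 3 male-genitalia — with every
categorical state coded by a letter for matrix storage, every
quantitative character reduced to an objective rule, and everything rare
or subjective routed to free-text remarks that are keyword-searchable.

`megakey` implements that system as a reusable format and library:

- **`megakey.schema`** — the canonical 29-character schema with its coded
  states and every classification rule, e.g. the supra-antennal (SA)
  setae ratio (ventral/dorsal, to 2 decimals), the labellum spinosity
  classes (not spinose / sparse `< 30` setulae / dense `≥ 30`), the hair
  at the base of vein R (minute ≤ width < short ≤ 2·width < long), the
  costal index CI = costa length / wing length, and the costal ratios
  C1:C2:C3 normalised to C3 = 1.
- **`megakey.description`** — parse, validate and write single-taxon
  description documents in a human-facing TSV dialect (the printed
  three-column table layout) and a machine-facing JSON dialect, including
  the posterior-setation ordering grammar (`T6~E~H<C` over tergite 6,
  epandrium, cerci, hypoproct with `<`, `=`, `~`).
- **`megakey.matrix`** — assemble descriptions into a species × character
  coded matrix with JSON persistence, a lossy CSV export, and an inverted
  keyword index over remarks.
- **`megakey.identify`** — the multi-access key: score a partial query
  against every species with built-in tolerance (relative windows on
  numerics, exact codes on categoricals, an open `4+` bin on counts,
  constraint-consistency on setation orderings), rank candidates
  deterministically, and suggest the most discriminating next character
  by Shannon entropy.
- **`megakey.synth`** — generate schema-valid synthetic faunas with a
  controlled pairwise coded-separation floor, and perturb descriptions
  into realistic noisy queries.

A thin CLI (`megakey schema|validate|convert|matrix|search|identify|synth`)
wraps the same API, and `examples/` holds one short narrative script per
capability.

## Worked example

The package ships the table-based description of *Megaselia shadeae*
Hartop, a cloud-forest species instantly recognisable by a bubbled,
pigmented central wing spot — a character so rare it lives in the
remarks, not in the coded columns.

```python
>>> from megakey.datasets import shadeae_description
>>> d = shadeae_description()
>>> d.value_of("wing_length_mm"), d.value_of("costal_index")
(1.56, 0.65)
>>> d.value_of("costal_ratios")
(1.25, 1.0, 1)
>>> str(d.value_of("posterior_setation"))
'T6~E~H<C'
>>> d.character_remarks["r2_3"]
'large fork'

>>> from megakey import build_matrix, keyword_search, match
>>> m = build_matrix([d])
>>> keyword_search(m, "wing spot")
['Megaselia shadeae']
>>> match(d, m)[0].mismatch_count
0
```

The wing is 1.56 mm long; the costa spans 65% of it, its three sections
in ratio 1.25 : 1.00 : 1. The setae of tergite 6, epandrium and hypoproct
are subequal, all shorter than those of the cerci. Searching the two
keywords "wing spot" retrieves exactly this species, and matching its own
description against the matrix returns it at rank 1 with zero mismatches.

Running `python examples/05_synthetic_fauna.py` prints

```
species: 50 | minimum pairwise coded distance: 5
rank-1 recovery under +-5% noise: 50/50
```

— a 50-species synthetic fauna (seed 42, coded separation ≥ 3) in which
every species is recovered at rank 1 after ±5% re-measurement noise under
the default 10% tolerance.

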