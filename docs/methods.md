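# Methods

## The description system

A species description under this system is a fixed-schema table: 29
characters in a fixed order (5 head, 5 thorax, 6 leg, 10 wing, 3 male
genitalia), each either a coded categorical state (single letters `a`,
`b`, ... in the matrix), a quantitative value, or one of two structured
values (a tarsomere interval, an ordering expression). Free text is
confined to remarks — a per-character remark column and a general-remarks
block — which are never coded but are tokenized into the matrix's keyword
index. Characters that are definable but not practically usable (absolute
colors) are excluded by design; relative coloration (halter knob vs
scutum) replaces them. Rare characters enter the coded columns only when
a positive state is unambiguous and definitive on its own (e.g. loss of
vein R2+3); extremely rare diagnostic features (a pigmented wing spot)
are deliberately kept in remarks, where keyword search finds them.

### Quantitative rules

All ratios, proportions and lengths are reported to two decimals,
rounded half-up once at encoding time; ratios are computed on the raw
measurements before rounding. The rules, with their boundary semantics:

| character | rule |
|---|---|
| SA ratio | ventral / dorsal supra-antennal seta length; may exceed 1.00 (no warning — relative seta lengths are not bounded in principle) |
| palpal setae | "long" only if **strictly** longer than the palp width; equality is "short" |
| labellum | spinose setulae scattered and **fewer than 30** per labellum = "sparse"; 30 or more = "dense" |
| hair at base of R | ≤ vein width "minute"; ≤ 2× width "short"; beyond "long" (both boundaries inclusive on the lower class) |
| costal index | costa length / wing length, in (0, 1] |
| costal ratios | (C1/C3, C2/C3, 1); the third element is identically 1 and scale invariance holds by construction |
| alular setae | counts coded 1/2/3/4+; "4+" is an open lower bound — any two counts ≥ 4 are equivalent under comparison; 0 has no code and is rejected rather than guessed |

One documented discrepancy: the prose definition of the costal index
("wing length divided by costa length") is inverted relative to its own
worked value (0.65) and to the classical Schmitz convention; the package
implements costa/wing, which is the direction every published value
satisfies.

The halter-color states are lettered `a` (lighter) and `c` (darker) in
the source material with "same" left unlettered; we assign `b` to "same"
to keep codes contiguous. The labellum state list is {not spinose,
sparse, dense}, but printed tables use "spinose" for the dense state;
the parser accepts "spinose" as an alias for "dense" and flags it with a
warning, since the equivalence is inferred rather than stated.

### The setation grammar

Relative lengths of posterior setae on T6, E, C and H are an expression
over the four tokens joined by `<`, `=` or `~` (subequal). `=` and `~`
both merge tokens into one equivalence group; the distinction is kept
only so rendering reproduces the input exactly. Parsing is strict: each
token exactly once, errors carry the failing character position.

## File dialects

Two serializations, both deterministic and schema-ordered, chosen
because the artifact is simultaneously a printed table and a database
row: a TSV mirroring the printed three-column layout (label, value,
remark) with section headers and figure labels, and a JSON object keyed
by stable character ids with every value in canonical cell text. TSV
labels match case-insensitively after whitespace normalization; ids are
authoritative in JSON. Parsing is strict by default (all invalid cells
aggregated into one error); lenient mode converts bad cells to unknowns
and records warnings, for legacy material with gaps. The unknown
sentinel `?` is accepted for every character and is never auto-filled.
Remarks survive round trips byte-for-byte provided they contain no tab
or newline (the TSV cell separator); the general-remarks block may span
lines.

## Identification engine

Per-character verdicts: unknown on either side skips the character;
categoricals must share a code; numerics are compatible when
|q − r| ≤ t·r with the window anchored on the **reference** (matrix)
value r, so a species' recorded measurement defines its own window;
counts use absolute slack with the `4+` equivalence; tarsomere ranges
must be identical; ordering expressions are compatible unless they
impose opposite strict orders on some token pair (so `T6~E~H<C` and
`E~T6~H<C`, the same ordering spelled differently, match). A small
epsilon (1e-12) absorbs binary-float representation error in the window
test.

Defaults — 10% relative tolerance, 0 count slack, 0 categorical
mismatch budget — are deliberate placeholders: the appropriate
magnitudes for real interspecific variation require expert calibration,
per character, via the override map or a YAML/JSON config.

Ranking keeps every species (the table narrows candidates; figures
finish the identification): candidates (within budget, no numeric/count/
range/order failure) first, then by (mismatch count, unknown count,
taxon name), ranks 1..n without gaps — fully deterministic.

`next_best_character` scores unanswered characters by the Shannon
entropy of the survivors' state distribution. Numeric values are binned
into tolerance-width windows (width = relative tolerance × median
survivor value) anchored at the smallest survivor value — anchoring at
zero would place 1/tolerance, an integer, at a bin boundary and split
within-tolerance clusters. Ties break in schema order; if no remaining
character separates any survivors the key is exhausted and says so.

## Synthetic faunas

The generator stands in for a real specimen stream: it draws schema-valid
descriptions with numeric characters uniform on ranges bracketing a
plausible small phorid (wing 0.8–3.0 mm, costal index 0.4–0.9, SA ratio
0.3–1.2, t2 palisade 0.3–0.9, costal setae 0.02–0.20 mm, alular setae
0.05–0.30 mm, C1 and C2 ratios 0.5–2.5), uniform coded states unless
weighted, alular counts 1–6, palisade on tarsomeres 1–k (k in 2..5), and
a uniformly random setation ordering. Rejection sampling enforces a
pairwise coded-Hamming separation floor (default 3 of the 19 coded
columns) so the fauna is identifiable by construction; 10,000 failed
placements abort with advice. All randomness flows from one integer
seed; generation is reproducible and descriptions round-trip both
dialects.

`perturb_description` models re-measurement: numerics multiplied by
factors uniform in [1−noise, 1+noise] then re-rounded, and exactly
`flip_count` coded characters switched to a different valid state.

What this does and does not show: passing the recovery check (50
species, separation ≥ 3, ±5% noise, 10% tolerance, 50/50 at rank 1)
demonstrates that the tolerance window absorbs measurement noise on a
separable fauna. Real faunas contain near-cryptic species; the tests
also exercise separation 1 without asserting perfect recovery. The
generator draws characters independently — no phylogenetic or
ecological trait correlation — and covers males only, as does the
schema.

## Numerical choices and degenerate inputs

- Rounding: decimal half-up at schema precision (2 for all ratios,
  proportions and mm lengths), applied once at encoding.
- Non-positive measurements, a costa longer than its wing, negative
  counts and 0 alular setae are rejected as errors; a proportion above 1
  (t2 palisade) is a warning, not an error, since transcription noise
  can produce it while the value remains interpretable.
- Matrices with zero species are valid, searchable and match nothing;
  duplicate taxon names are a build error.
- Keyword search is exact token AND (lowercased, punctuation stripped,
  no stemming): predictable retrieval, no NLP surprises.

## Problem sizes

The default test suite and the acceptance script use the worked example
(1 species × 29 characters), faunas of 50–200 synthetic species, a
100-count classifier scan, the 648-case exhaustive setation grammar
sweep, and 20 randomized oracle-comparison cases — sizes chosen so the
whole suite completes in seconds while exercising every code path.

## Known limitations

- The TSV dialect cannot represent tabs or newlines inside per-character
  remarks, or a general-remark line that exactly matches a section
  header.
- Tolerance semantics for segment ranges are all-or-nothing (identical
  intervals); a justified notion of "close" palisade extents would need
  expert input.
- Female morphology, occurrence/type-material records (Darwin Core) and
  the hosted online guide's service layer are out of scope.
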