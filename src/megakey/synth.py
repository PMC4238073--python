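"""Synthetic species descriptions for exercising the matrix and the key.

Real *Megaselia* descriptions accumulate slowly; the generator produces
faunas of schema-valid Descriptions with controlled statistical
structure so the pipeline is testable end to end.  Numeric characters
are sampled uniformly from ranges bracketing a plausible small phorid
(wing length 0.8-3.0 mm, costal index 0.4-0.9, ...); coded characters
are sampled from their states with configurable weights; a
rejection-sampling floor on pairwise coded Hamming distance guarantees
the fauna is separable, which real near-cryptic faunas need not be.
:func:`perturb_description` then manufactures realistic queries:
re-measurement noise on numerics and outright state flips on coded
characters.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .description import Description, build_description, validate_description
from .errors import GenerationError, UsageError
from .schema import (
    CODED_KINDS,
    NUMERIC_KINDS,
    CharacterValue,
    SegmentRange,
    canonical_schema,
    coded_letter,
    round_half_up,
)
from .setation import OPERATORS, TOKENS, SetationOrder

#: Default sampling intervals for numeric characters, bracketing the
#: single worked example rather than claiming genus-wide realism.
DEFAULT_NUMERIC_RANGES: dict[str, tuple[float, float]] = {
    "sa_ratio": (0.30, 1.20),
    "t2_palisade": (0.30, 0.90),
    "wing_length_mm": (0.80, 3.00),
    "costal_index": (0.40, 0.90),
    "costal_ratios": (0.50, 2.50),  # applied to C1 and C2 independently
    "costal_setae_length_mm": (0.02, 0.20),
    "alular_setae_length_mm": (0.05, 0.30),
}

_CODED_IDS = tuple(d.id for d in canonical_schema() if d.kind in CODED_KINDS)
_COUNT_REPRESENTATIVE = {"a": 1, "b": 2, "c": 3, "d": 4}


@dataclass(frozen=True)
class GeneratorConfig:
    """Conditions under which a synthetic fauna is drawn.

    ``min_pairwise_separation`` is the minimum number of coded characters
    on which any two species must differ (default 3, a comfortably
    separable fauna; set 1 for a near-cryptic one).  ``unknown_rate`` is
    the per-cell probability of an unscored "?".
    """

    n_species: int = 50
    seed: int = 42
    numeric_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_NUMERIC_RANGES))
    categorical_weights: dict[str, dict[str, float]] = field(default_factory=dict)
    min_pairwise_separation: int = 3
    unknown_rate: float = 0.0

    def __post_init__(self):
        if self.n_species < 0:
            raise UsageError("n_species must be non-negative")
        for cid, (lo, hi) in self.numeric_ranges.items():
            if not (0 < lo <= hi):
                raise UsageError(f"range for {cid!r} must be positive and ordered")
        for cid, weights in self.categorical_weights.items():
            if any(w < 0 for w in weights.values()) or sum(weights.values()) <= 0:
                raise UsageError(f"weights for {cid!r} must be non-negative "
                                 "with positive sum")
        if not 0 <= self.unknown_rate < 1:
            raise UsageError("unknown_rate must be in [0, 1)")
        if self.min_pairwise_separation < 0:
            raise UsageError("min_pairwise_separation must be non-negative")


def coded_hamming(a: Description, b: Description) -> int:
    """Number of coded characters on which two taxa definitely differ
    (cells unknown on either side do not count)."""
    dist = 0
    for cid in _CODED_IDS:
        va, vb = a.values[cid].value, b.values[cid].value
        if va is None or vb is None:
            continue
        if coded_letter(cid, va) != coded_letter(cid, vb):
            dist += 1
    return dist


def _sample_description(cfg: GeneratorConfig, rng: random.Random,
                        name: str) -> Description:
    raw: dict[str, object] = {}
    for defn in canonical_schema():
        if defn.kind == "coded_categorical":
            weights = cfg.categorical_weights.get(defn.id)
            codes = [st.code for st in defn.states]
            if weights:
                w = [weights.get(c, 0.0) for c in codes]
                raw[defn.id] = rng.choices(codes, weights=w, k=1)[0]
            else:
                raw[defn.id] = rng.choice(codes)
        elif defn.kind == "count":
            raw[defn.id] = rng.randint(1, 6)
        elif defn.id == "costal_ratios":
            lo, hi = cfg.numeric_ranges["costal_ratios"]
            raw[defn.id] = (rng.uniform(lo, hi), rng.uniform(lo, hi), 1)
        elif defn.kind in NUMERIC_KINDS:
            lo, hi = cfg.numeric_ranges[defn.id]
            raw[defn.id] = rng.uniform(lo, hi)
        elif defn.kind == "segment_range":
            raw[defn.id] = SegmentRange(1, rng.randint(2, 5))
        else:  # order_expression
            toks = list(TOKENS)
            rng.shuffle(toks)
            ops = tuple(rng.choice(OPERATORS) for _ in range(3))
            raw[defn.id] = SetationOrder(tuple(toks), ops)
    if cfg.unknown_rate > 0:
        for cid in list(raw):
            if rng.random() < cfg.unknown_rate:
                raw[cid] = None
    return build_description(name, raw)


def generate_species(cfg: GeneratorConfig) -> list[Description]:
    """Draw ``cfg.n_species`` schema-valid Descriptions, reproducibly.

    Rejection sampling enforces the pairwise coded-separation floor; if a
    new species cannot be placed within 10,000 attempts a
    :class:`~megakey.errors.GenerationError` advises a smaller fauna or a
    lower separation.
    """
    rng = random.Random(cfg.seed)
    out: list[Description] = []
    for i in range(cfg.n_species):
        name = f"Megaselia synthetica-{i + 1:03d}"
        for attempt in range(10_000):
            cand = _sample_description(cfg, rng, name)
            if all(coded_hamming(cand, prev) >= cfg.min_pairwise_separation
                   for prev in out):
                out.append(cand)
                break
        else:
            raise GenerationError(
                f"could not place species {i + 1} with pairwise coded "
                f"separation >= {cfg.min_pairwise_separation} in 10000 "
                f"attempts; reduce n_species or the separation floor")
    for d in out:
        errors = [f for f in validate_description(d) if f.level == "error"]
        if errors:  # invariant of the generator, not of user input
            raise GenerationError(f"generated invalid description: {errors}")
    return out


def perturb_description(d: Description, numeric_noise: float = 0.0,
                        flip_count: int = 0, seed: int = 0) -> Description:
    """Manufacture a query: multiply every known numeric value by a factor
    drawn uniformly from [1-noise, 1+noise] (then re-round), and switch
    exactly ``flip_count`` known coded characters to a different valid
    state chosen uniformly.  The result still validates.
    """
    if numeric_noise < 0:
        raise UsageError("numeric_noise must be non-negative")
    known_coded = [cid for cid in _CODED_IDS if not d.values[cid].is_unknown]
    if not 0 <= flip_count <= len(known_coded):
        raise UsageError(
            f"flip_count must be between 0 and {len(known_coded)}")
    rng = random.Random(seed)
    values: dict[str, CharacterValue] = {}
    for defn in canonical_schema():
        v = d.values[defn.id]
        if v.is_unknown or defn.kind not in NUMERIC_KINDS or numeric_noise == 0:
            values[defn.id] = v
            continue
        if defn.id == "costal_ratios":
            c1, c2, _ = v.value
            newval = (round_half_up(c1 * rng.uniform(1 - numeric_noise,
                                                     1 + numeric_noise), 2),
                      round_half_up(c2 * rng.uniform(1 - numeric_noise,
                                                     1 + numeric_noise), 2),
                      1)
        else:
            factor = rng.uniform(1 - numeric_noise, 1 + numeric_noise)
            newval = round_half_up(float(v.value) * factor, defn.precision)
        values[defn.id] = CharacterValue(defn.id, newval, v.remark)
    for cid in rng.sample(sorted(known_coded), flip_count):
        v = values[cid]
        current = coded_letter(cid, v.value)
        defn = next(x for x in canonical_schema() if x.id == cid)
        alternatives = [st.code for st in defn.states if st.code != current]
        new_code = rng.choice(alternatives)
        if defn.kind == "count":
            values[cid] = CharacterValue(cid, _COUNT_REPRESENTATIVE[new_code],
                                         v.remark)
        else:
            values[cid] = CharacterValue(cid, new_code, v.remark)
    return Description(d.taxon_name, values, d.general_remarks,
                       dict(d.figure_refs))
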