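"""The canonical 29-character *Megaselia* description schema.

The table-based description system replaces verbose prose descriptions of
this hyperdiverse phorid genus with a fixed set of 29 well-defined
characters grouped by body region — 5 head, 5 thorax, 6 leg, 10 wing and
3 male-genitalia characters.  Categorical characters carry single-letter
coded states (``a``, ``b``, ...) for storage in a searchable character
matrix; quantitative characters are ratios, proportions, counts or
millimetre lengths reported to two decimals.

This module defines the schema itself (:func:`canonical_schema`), the
measurement/classification rules that turn raw observations into values
(:func:`compute_sa_ratio`, :func:`classify_labellum`, ...), and the
generic dispatcher :func:`encode_value`.

Abbreviations follow standard phorid usage: SA supra-antennal setae,
VIF ventral interfrontal setae, VFO ventral fronto-orbital setae,
SPS subcuticular pit sensilla, NP notopleuron, ts1 foretarsus,
t2/t3 mid/hind tibia, f3 hind femur, Sc subcosta, R radial vein,
CI costal index, C1-C3 costal sections, AT anal tube, E epandrium,
T6 tergite 6, C cerci, H hypoproct, B basal, AV anteroventral,
PD posterodorsal, AD anterodorsal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple, Union

from .errors import (
    InvalidMeasurementError,
    SchemaError,
    UnknownStateError,
    UnsupportedStateError,
)
from .setation import SetationOrder, parse_setation_order

REGIONS = ("head", "thorax", "leg", "wing", "genitalia")
KINDS = (
    "ratio",
    "proportion",
    "length_mm",
    "count",
    "coded_categorical",
    "segment_range",
    "order_expression",
)

#: Sentinel accepted everywhere for a character that was not observed.
UNKNOWN = "?"

SCHEMA_FORMAT = "megaselia-character-schema"
SCHEMA_VERSION = 1


class StateCode(NamedTuple):
    """One coded categorical state: ``(character_id, code letter, display label)``."""

    character_id: str
    code: str
    label: str


@dataclass(frozen=True)
class SegmentRange:
    """Inclusive run of tarsomere numbers bearing a setal palisade, within 1..5."""

    lo: int
    hi: int

    def __post_init__(self):
        if not (1 <= self.lo <= self.hi <= 5):
            raise InvalidMeasurementError(
                f"segment range must satisfy 1 <= lo <= hi <= 5, got {self.lo}-{self.hi}"
            )

    def __str__(self) -> str:
        return str(self.lo) if self.lo == self.hi else f"{self.lo}-{self.hi}"


#: A character's stored value: a coded letter, a rounded number, a raw
#: count (or the open-ended "4+" bound), a tarsomere interval, an
#: ordering expression, or None for unknown.
ValueType = Union[None, str, float, int, tuple, SegmentRange, SetationOrder]


@dataclass(frozen=True)
class CharacterValue:
    """A species' value for one character, with an optional free-text remark.

    Remarks are never coded; they feed the keyword index of the matrix.
    """

    character_id: str
    value: ValueType = None
    remark: str = ""

    @property
    def is_unknown(self) -> bool:
        return self.value is None


@dataclass(frozen=True)
class CharacterDefinition:
    """Schema entry for one character.

    ``states`` is the ordered tuple of coded states (empty for purely
    numeric kinds); ``precision`` is the number of decimals for numeric
    kinds; ``aliases`` maps accepted non-canonical input labels to codes,
    with those in ``flagged_aliases`` producing a validation warning when
    used (e.g. the printed "spinose" for a densely spinose labellum).
    """

    id: str
    label: str
    region: str
    kind: str
    states: tuple[StateCode, ...] = ()
    units: str = ""
    precision: int = 2
    aliases: dict = field(default_factory=dict)
    flagged_aliases: frozenset = frozenset()

    def __post_init__(self):
        if self.region not in REGIONS:
            raise SchemaError(f"unknown region {self.region!r}")
        if self.kind not in KINDS:
            raise SchemaError(f"unknown kind {self.kind!r}")

    def state_for_code(self, code: str) -> StateCode:
        for st in self.states:
            if st.code == code:
                return st
        raise UnknownStateError(
            f"{self.id!r} has no state {code!r}",
            valid_labels=[st.label for st in self.states],
        )

    def state_label(self, code: str) -> str:
        return self.state_for_code(code).label


def _states(cid: str, *pairs: tuple[str, str]) -> tuple[StateCode, ...]:
    return tuple(StateCode(cid, code, label) for code, label in pairs)


def _coded(cid, label, region, *pairs, aliases=None, flagged=()):
    return CharacterDefinition(
        id=cid,
        label=label,
        region=region,
        kind="coded_categorical",
        states=_states(cid, *pairs),
        precision=0,
        aliases=dict(aliases or {}),
        flagged_aliases=frozenset(flagged),
    )


_SCHEMA: tuple[CharacterDefinition, ...] = (
    # -- Head ---------------------------------------------------------------
    CharacterDefinition("sa_ratio", "SA ratio", "head", "ratio"),
    _coded("vif_position", "VIF position", "head",
           ("a", "normal"), ("b", "VFO adjacent")),
    _coded("sps_vesicles", "SPS vesicles", "head",
           ("a", "absent"), ("b", "present")),
    _coded("palpal_setae", "Palpal setae length", "head",
           ("a", "long"), ("b", "short")),
    _coded("labellum", "Labellum spinosity", "head",
           ("a", "not spinose"), ("b", "sparse"), ("c", "dense"),
           aliases={"spinose": "c", "not": "a"}, flagged={"spinose"}),
    # -- Thorax -------------------------------------------------------------
    _coded("anepisternum", "Anepisternum", "thorax",
           ("a", "bare"), ("b", "hairs only"), ("c", "hairs + bristles"),
           aliases={"hairs + bristle(s)": "c"}),
    _coded("halter_color", "Relative halter color", "thorax",
           ("a", "lighter"), ("b", "same"), ("c", "darker")),
    _coded("np_setae_count", "# NP setae", "thorax",
           ("a", "2"), ("b", "3")),
    _coded("np_cleft", "NP cleft", "thorax",
           ("a", "absent"), ("b", "present")),
    _coded("scutellar_setae", "Scutellar setae", "thorax",
           ("a", "4 ="), ("b", "4 /="), ("c", "2+2"),
           aliases={"4=": "a", "4/=": "b"}),
    # -- Leg ----------------------------------------------------------------
    CharacterDefinition("ts1_palisade", "ts1 palisade", "leg", "segment_range",
                        precision=0),
    CharacterDefinition("t2_palisade", "t2 palisade", "leg", "proportion"),
    _coded("t3_comb_bifurcate", "t3 comb bifurcate", "leg",
           ("a", "absent"), ("b", "present")),
    _coded("t3_setulae", "t3 setulae", "leg",
           ("a", "PD only"), ("b", "PD + AD"),
           aliases={"pd": "a", "pd+ad": "b"}),
    _coded("f3_basal_setae", "f3 basal setae", "leg",
           ("a", "B<AV"), ("b", "B=AV"), ("c", "B>AV")),
    _coded("f3_basal_differentiation", "f3 basal setae differentiation", "leg",
           ("a", "absent"), ("b", "present")),
    # -- Wing ---------------------------------------------------------------
    CharacterDefinition("wing_length_mm", "Wing Length (mm)", "wing",
                        "length_mm", units="mm"),
    _coded("subcosta", "Subcosta", "wing",
           ("a", "complete"), ("b", "incomplete")),
    _coded("hair_at_base_r", "Hair at base of R", "wing",
           ("a", "absent"), ("b", "minute"), ("c", "short"), ("d", "long")),
    _coded("r2_3", "R_2+3", "wing",
           ("a", "present"), ("b", "absent")),
    CharacterDefinition("costal_index", "Costal index", "wing", "ratio"),
    CharacterDefinition("costal_ratios", "Costal ratios", "wing", "ratio"),
    CharacterDefinition("costal_setae_length_mm", "Costal setae length (mm)",
                        "wing", "length_mm", units="mm"),
    CharacterDefinition(
        "alular_setae_count", "Number alular setae", "wing", "count",
        states=_states("alular_setae_count",
                       ("a", "1"), ("b", "2"), ("c", "3"), ("d", "4+")),
        precision=0),
    CharacterDefinition("alular_setae_length_mm", "Alular setae length (mm)",
                        "wing", "length_mm", units="mm"),
    _coded("wing_color", "Wing color", "wing",
           ("a", "lightly infuscated/clear"), ("b", "strongly infuscated"),
           aliases={"lightly infuscated": "a", "clear": "a"}),
    # -- Genitalia ----------------------------------------------------------
    _coded("at_length", "AT length", "genitalia",
           ("a", "AT<E"), ("b", "AT=E"), ("c", "AT>E")),
    _coded("e_setation", "E setation", "genitalia",
           ("a", "hairs only"), ("b", "hairs + bristles"),
           aliases={"hairs + bristle(s)": "b"}),
    CharacterDefinition("posterior_setation", "Relative posterior setation",
                        "genitalia", "order_expression", precision=0),
)

_BY_ID: dict[str, CharacterDefinition] = {d.id: d for d in _SCHEMA}

NUMERIC_KINDS = frozenset({"ratio", "proportion", "length_mm"})
#: Characters whose stored form is a single-letter code (categoricals plus
#: the binned alular count) — the columns over which coded Hamming
#: distances and state flips are defined.
CODED_KINDS = frozenset({"coded_categorical", "count"})


def canonical_schema() -> tuple[CharacterDefinition, ...]:
    """The 29 character definitions in table order (head -> genitalia)."""
    return _SCHEMA


def get_definition(character_id: str) -> CharacterDefinition:
    try:
        return _BY_ID[character_id]
    except KeyError:
        raise SchemaError(f"unknown character id {character_id!r}") from None


def character_ids() -> tuple[str, ...]:
    return tuple(d.id for d in _SCHEMA)


def schema_index(character_id: str) -> int:
    """Position of a character in table order (0-based)."""
    get_definition(character_id)
    return next(i for i, d in enumerate(_SCHEMA) if d.id == character_id)


def round_half_up(x: float, places: int) -> float:
    """Decimal round-half-up, applied once at encoding time."""
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Measurement / classification rules
# ---------------------------------------------------------------------------

def compute_sa_ratio(ventral_length: float, dorsal_length: float) -> float:
    """Ventral supra-antennal seta length as a fraction of the dorsal one.

    Equal setae give 1.00; a ventral seta half as long gives 0.50.  Both
    lengths must be positive and in the same unit; the ratio is computed
    on the raw measurements and rounded to two decimals.
    """
    if ventral_length <= 0 or dorsal_length <= 0:
        raise InvalidMeasurementError("SA lengths must be positive")
    return round_half_up(ventral_length / dorsal_length, 2)


def classify_labellum(setulae_per_labellum: int, spinose: bool) -> StateCode:
    """Code labellar spinosity: not spinose (a), sparse (b), dense (c).

    A spinose labellum with scattered setulae numbering fewer than 30 per
    labellum is "sparse"; 30 or more is "dense".
    """
    if setulae_per_labellum < 0:
        raise InvalidMeasurementError("setulae count cannot be negative")
    d = get_definition("labellum")
    if not spinose:
        return d.state_for_code("a")
    return d.state_for_code("b" if setulae_per_labellum < 30 else "c")


def classify_palpal_setae(seta_length: float, palp_width: float) -> StateCode:
    """Palpal setae are "long" (a) only if strictly longer than the palp width."""
    if seta_length <= 0 or palp_width <= 0:
        raise InvalidMeasurementError("palpal measurements must be positive")
    d = get_definition("palpal_setae")
    return d.state_for_code("a" if seta_length > palp_width else "b")


def classify_hair_at_base_R(hair_length: float, vein_width: float,
                            present: bool) -> StateCode:
    """Code the hair at the base of vein R.

    Absent (a); "minute" (b) up to the vein width; "short" (c) above the
    width but at most twice it; "long" (d) strictly beyond twice the width.
    """
    d = get_definition("hair_at_base_r")
    if not present:
        return d.state_for_code("a")
    if hair_length <= 0 or vein_width <= 0:
        raise InvalidMeasurementError("hair and vein measurements must be positive")
    if hair_length <= vein_width:
        return d.state_for_code("b")
    if hair_length <= 2 * vein_width:
        return d.state_for_code("c")
    return d.state_for_code("d")


def compute_costal_index(costa_length: float, wing_length: float) -> float:
    """Costal index: costa length as a fraction of wing length, to 2 decimals.

    The costa never extends beyond the wing tip, so the index lies in
    (0, 1]; a costa longer than the wing is an invalid measurement.
    """
    if costa_length <= 0 or wing_length <= 0:
        raise InvalidMeasurementError("costa and wing lengths must be positive")
    if costa_length > wing_length:
        raise InvalidMeasurementError(
            f"costa length {costa_length} exceeds wing length {wing_length}")
    return round_half_up(costa_length / wing_length, 2)


def compute_costal_ratios(c1: float, c2: float, c3: float) -> tuple[float, float, int]:
    """Lengths of costal sections 1-3 as the ratio C1:C2:C3 with C3 = 1.

    The first two elements are rounded to two decimals; the third is
    identically 1.  Scaling all three sections by a common factor leaves
    the result unchanged.
    """
    if c1 <= 0 or c2 <= 0 or c3 <= 0:
        raise InvalidMeasurementError("costal section lengths must be positive")
    return (round_half_up(c1 / c3, 2), round_half_up(c2 / c3, 2), 1)


def classify_alular_count(n: int) -> StateCode:
    """Code the alular setae count: 1 (a), 2 (b), 3 (c), 4 or more (d).

    Counts of four and above are collapsed to the open-ended "4+" bin
    because they vary within species.  Zero has no code.
    """
    if n < 1:
        raise UnsupportedStateError(
            f"no coded state for {n} alular setae (counts start at 1)", raw=n)
    d = get_definition("alular_setae_count")
    return d.state_for_code("abc"[n - 1] if n < 4 else "d")


# ---------------------------------------------------------------------------
# Generic encoding
# ---------------------------------------------------------------------------

_WS = re.compile(r"\s+")


def _norm_label(text: str) -> str:
    return _WS.sub(" ", text.strip()).lower()


def resolve_state(definition: CharacterDefinition, raw: str) -> tuple[str, bool]:
    """Resolve a raw categorical label (or bare code letter) to a code.

    Matching is case-insensitive after whitespace normalisation.  Returns
    ``(code, flagged)`` where ``flagged`` marks a tolerated non-canonical
    alias.  Raises :class:`UnknownStateError` listing the valid labels.
    """
    norm = _norm_label(str(raw))
    for st in definition.states:
        if _norm_label(st.label) == norm:
            return st.code, False
    alias_code = definition.aliases.get(norm)
    if alias_code is not None:
        return alias_code, norm in {_norm_label(a) for a in definition.flagged_aliases}
    if len(norm) == 1 and any(st.code == norm for st in definition.states):
        return norm, False
    raise UnknownStateError(
        f"{definition.id!r}: cannot resolve state label {raw!r}; "
        f"valid labels: {[st.label for st in definition.states]}",
        valid_labels=[st.label for st in definition.states],
    )


def _parse_number(raw, what: str) -> float:
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise InvalidMeasurementError(f"cannot read {what} from {raw!r}") from None


def encode_value(character_id: str, raw, remark: str = "") -> CharacterValue:
    """Encode a raw observation into a stored :class:`CharacterValue`.

    Dispatches on the character's kind: numbers are rounded once to the
    schema precision, categorical labels resolve case-insensitively to a
    coded letter, segment ranges and ordering expressions are parsed, and
    the unknown sentinel ``"?"`` (or None) passes through unchanged.
    """
    d = get_definition(character_id)
    if raw is None or (isinstance(raw, str) and raw.strip() == UNKNOWN):
        return CharacterValue(character_id, None, remark)

    if d.id == "costal_ratios":
        if isinstance(raw, str):
            parts = raw.split(":")
            if len(parts) != 3:
                raise InvalidMeasurementError(
                    f"costal ratios must be 'C1:C2:C3', got {raw!r}")
            nums = [_parse_number(p, "costal ratio") for p in parts]
        else:
            nums = [_parse_number(p, "costal ratio") for p in tuple(raw)]
            if len(nums) != 3:
                raise InvalidMeasurementError("costal ratios need three elements")
        if any(n <= 0 for n in nums):
            raise InvalidMeasurementError("costal ratios must be positive")
        third = 1 if nums[2] == 1 else round_half_up(nums[2], d.precision)
        value = (round_half_up(nums[0], d.precision),
                 round_half_up(nums[1], d.precision), third)
        return CharacterValue(character_id, value, remark)

    if d.kind in NUMERIC_KINDS:
        x = _parse_number(raw, d.label)
        if x <= 0:
            raise InvalidMeasurementError(f"{d.label} must be positive, got {raw!r}")
        return CharacterValue(character_id, round_half_up(x, d.precision), remark)

    if d.kind == "count":
        if isinstance(raw, str) and raw.strip().endswith("+"):
            base = raw.strip()[:-1]
            n = int(_parse_number(base, d.label))
            if n != 4:
                raise UnsupportedStateError(
                    f"only '4+' is a coded open bound, got {raw!r}", raw=raw)
            return CharacterValue(character_id, "4+", remark)
        n = _parse_number(raw, d.label)
        if n != int(n):
            raise InvalidMeasurementError(f"{d.label} must be an integer, got {raw!r}")
        classify_alular_count(int(n))  # raises on counts with no code
        return CharacterValue(character_id, int(n), remark)

    if d.kind == "coded_categorical":
        code, _ = resolve_state(d, raw)
        return CharacterValue(character_id, code, remark)

    if d.kind == "segment_range":
        if isinstance(raw, SegmentRange):
            return CharacterValue(character_id, raw, remark)
        if isinstance(raw, (tuple, list)) and len(raw) == 2:
            return CharacterValue(character_id, SegmentRange(int(raw[0]), int(raw[1])), remark)
        text = str(raw).strip()
        m = re.fullmatch(r"(\d)\s*[-–]\s*(\d)", text) or re.fullmatch(r"(\d)", text)
        if not m:
            raise InvalidMeasurementError(
                f"cannot read segment range from {raw!r} (expected e.g. '1-4')")
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.lastindex == 2 else lo
        return CharacterValue(character_id, SegmentRange(lo, hi), remark)

    # order_expression
    if isinstance(raw, SetationOrder):
        return CharacterValue(character_id, raw, remark)
    return CharacterValue(character_id, parse_setation_order(str(raw)), remark)


def format_value(character_id: str, value: ValueType) -> str:
    """Canonical cell text for a stored value (inverse of :func:`encode_value`)."""
    d = get_definition(character_id)
    if value is None:
        return UNKNOWN
    if d.id == "costal_ratios":
        c1, c2, c3 = value
        c3txt = "1" if c3 == 1 else f"{c3:.{d.precision}f}"
        return f"{c1:.{d.precision}f}:{c2:.{d.precision}f}:{c3txt}"
    if d.kind in NUMERIC_KINDS:
        return f"{value:.{d.precision}f}"
    if d.kind == "count":
        return str(value)
    if d.kind == "coded_categorical":
        return d.state_label(value)
    return str(value)


def coded_letter(character_id: str, value: ValueType) -> str | None:
    """Single-letter code for a coded character's stored value (None if unknown)."""
    d = get_definition(character_id)
    if value is None:
        return None
    if d.kind == "coded_categorical":
        return value
    if d.kind == "count":
        n = 4 if value == "4+" else int(value)
        return classify_alular_count(n).code
    raise SchemaError(f"{character_id!r} is not a coded character")


def schema_to_json() -> dict:
    """Versioned, machine-readable export of the schema definition."""
    return {
        "format": SCHEMA_FORMAT,
        "version": SCHEMA_VERSION,
        "characters": [
            {
                "id": d.id,
                "label": d.label,
                "region": d.region,
                "kind": d.kind,
                "units": d.units,
                "precision": d.precision,
                "states": [{"code": st.code, "label": st.label} for st in d.states],
            }
            for d in _SCHEMA
        ],
    }
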