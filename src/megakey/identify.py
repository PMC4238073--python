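"""Tolerance-aware identification against a coded matrix.

The multi-access key: a user answers any subset of the 29 characters, in
any order, and every species in the matrix is scored against the partial
query.  Numeric characters carry a built-in relative tolerance so that
ordinary interspecific variation (a wing measured a few percent off the
type) does not eliminate the right species; categorical characters match
exactly unless a mismatch budget is allowed.  Species that survive all
tolerances rank first; the rest are ranked after them rather than
deleted, since the table is meant to narrow candidates down for a final
check against the figures, not to be the last word.

:func:`next_best_character` supports the interactive workflow by
proposing the unanswered character whose states best split the surviving
taxa (maximum Shannon entropy).
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from statistics import median

import yaml

from .description import Description
from .errors import ExhaustedKeyError, UsageError
from .matrix import CodedMatrix
from .schema import (
    NUMERIC_KINDS,
    CharacterDefinition,
    CharacterValue,
    SegmentRange,
    canonical_schema,
    character_ids,
    coded_letter,
    get_definition,
)
from .setation import SetationOrder, orders_compatible


class Verdict(str, Enum):
    COMPATIBLE = "compatible"
    INCOMPATIBLE = "incompatible"
    UNKNOWN_SKIPPED = "unknown-skipped"


@dataclass(frozen=True)
class ToleranceConfig:
    """Matching slack for the identification engine.

    ``relative_tolerance`` is the fractional window on ratio, proportion
    and length characters, measured relative to the *reference* (matrix)
    value so a species' recorded measurement anchors its window.
    ``absolute_count_tolerance`` is integer slack on counts ("4+" matches
    any count of four or more regardless).
    ``categorical_mismatch_budget`` is how many categorical disagreements
    a species may accumulate and still be reported as a candidate.
    ``overrides`` substitutes a per-character tolerance (relative for
    numeric characters, absolute for counts).

    The defaults (0.10 / 0 / 0) are deliberately strict placeholders:
    appropriate magnitudes for real interspecific variation must come
    from expert calibration, per character.
    """

    relative_tolerance: float = 0.10
    absolute_count_tolerance: int = 0
    categorical_mismatch_budget: int = 0
    overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.relative_tolerance < 0 or self.absolute_count_tolerance < 0 \
                or self.categorical_mismatch_budget < 0:
            raise UsageError("tolerances must be non-negative")
        for cid, tol in self.overrides.items():
            get_definition(cid)  # raises SchemaError on unknown ids
            if tol < 0:
                raise UsageError(f"override for {cid!r} must be non-negative")

    def numeric_tol(self, character_id: str) -> float:
        return self.overrides.get(character_id, self.relative_tolerance)

    def count_tol(self, character_id: str) -> float:
        return self.overrides.get(character_id, self.absolute_count_tolerance)

    @classmethod
    def from_file(cls, path) -> "ToleranceConfig":
        """Load a config from YAML or JSON (same keys as the fields)."""
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
        doc = json.loads(text) if text.lstrip().startswith("{") \
            else yaml.safe_load(text)
        doc = doc or {}
        return cls(
            relative_tolerance=float(doc.get("relative_tolerance", 0.10)),
            absolute_count_tolerance=int(doc.get("absolute_count_tolerance", 0)),
            categorical_mismatch_budget=int(doc.get("categorical_mismatch_budget", 0)),
            overrides={str(k): float(v)
                       for k, v in (doc.get("overrides") or {}).items()},
        )


@dataclass
class MatchResult:
    """Per-candidate outcome: verdict per character, counts, and 1-based rank.

    ``is_candidate`` is False when the species exceeded the categorical
    budget or failed any non-categorical tolerance; such species are
    ranked after every candidate."""

    taxon_name: str
    verdicts: dict[str, Verdict]
    mismatch_count: int
    unknown_count: int
    rank: int = 0
    is_candidate: bool = True


def _numbers_close(q: float, r: float, tol: float) -> bool:
    return abs(q - r) <= tol * r + 1e-12


def character_compatibility(query_value: CharacterValue,
                            reference_value: CharacterValue,
                            definition: CharacterDefinition,
                            tol: ToleranceConfig) -> Verdict:
    """Verdict for one character of one candidate.

    Unknown on either side skips the character.  Categoricals must share
    a code; numerics must fall within the relative window around the
    reference; counts within the absolute slack (both at four or more is
    always compatible); tarsomere ranges must be identical; setation
    orderings must impose no contradictory strict order.
    """
    if query_value.character_id != reference_value.character_id \
            or query_value.character_id != definition.id:
        raise UsageError(
            f"character ids disagree: {query_value.character_id!r} vs "
            f"{reference_value.character_id!r} vs {definition.id!r}")
    q, r = query_value.value, reference_value.value
    if q is None or r is None:
        return Verdict.UNKNOWN_SKIPPED

    if definition.kind == "coded_categorical":
        return Verdict.COMPATIBLE if q == r else Verdict.INCOMPATIBLE

    if definition.id == "costal_ratios":
        if not (isinstance(q, tuple) and isinstance(r, tuple)):
            return Verdict.INCOMPATIBLE
        t = tol.numeric_tol(definition.id)
        ok = all(_numbers_close(qi, ri, t) for qi, ri in zip(q, r))
        return Verdict.COMPATIBLE if ok else Verdict.INCOMPATIBLE

    if definition.kind in NUMERIC_KINDS:
        ok = _numbers_close(float(q), float(r), tol.numeric_tol(definition.id))
        return Verdict.COMPATIBLE if ok else Verdict.INCOMPATIBLE

    if definition.kind == "count":
        qn = 4 if q == "4+" else int(q)
        rn = 4 if r == "4+" else int(r)
        if qn >= 4 and rn >= 4:  # "4+" bins together all high counts
            return Verdict.COMPATIBLE
        ok = abs(qn - rn) <= tol.count_tol(definition.id)
        return Verdict.COMPATIBLE if ok else Verdict.INCOMPATIBLE

    if definition.kind == "segment_range":
        return Verdict.COMPATIBLE if q == r else Verdict.INCOMPATIBLE

    # order_expression
    if isinstance(q, SetationOrder) and isinstance(r, SetationOrder):
        return Verdict.COMPATIBLE if orders_compatible(q, r) \
            else Verdict.INCOMPATIBLE
    return Verdict.INCOMPATIBLE


def match(query: Description, m: CodedMatrix,
          tol: ToleranceConfig | None = None) -> list[MatchResult]:
    """Score every species in the matrix against a partial query.

    Every species receives a result; ordering is deterministic:
    candidates first, then (mismatch count, unknown count, taxon name)
    ascending, with ranks 1..n assigned without gaps.
    """
    tol = tol or ToleranceConfig()
    known = [cid for cid in character_ids()
             if cid in query.values and not query.values[cid].is_unknown]
    if not known:
        raise UsageError("query has no known characters")
    results: list[MatchResult] = []
    for d in m.descriptions:
        verdicts: dict[str, Verdict] = {}
        cat_mismatches = 0
        hard_fail = False
        for defn in canonical_schema():
            qv = query.values.get(defn.id) or CharacterValue(defn.id, None)
            rv = d.values[defn.id]
            v = character_compatibility(qv, rv, defn, tol)
            verdicts[defn.id] = v
            if v is Verdict.INCOMPATIBLE:
                if defn.kind == "coded_categorical":
                    cat_mismatches += 1
                else:
                    hard_fail = True
        mismatches = sum(v is Verdict.INCOMPATIBLE for v in verdicts.values())
        unknowns = sum(v is Verdict.UNKNOWN_SKIPPED for v in verdicts.values())
        results.append(MatchResult(
            taxon_name=d.taxon_name,
            verdicts=verdicts,
            mismatch_count=mismatches,
            unknown_count=unknowns,
            is_candidate=(not hard_fail
                          and cat_mismatches <= tol.categorical_mismatch_budget),
        ))
    results.sort(key=lambda r: (not r.is_candidate, r.mismatch_count,
                                r.unknown_count, r.taxon_name))
    for i, r in enumerate(results, 1):
        r.rank = i
    return results


def _bin(x: float, origin: float, width: float):
    """Tolerance-width window index, anchored at the smallest survivor value
    so values the engine would call compatible tend to share a bin."""
    if width <= 0:
        return x
    return math.floor((x - origin) / width + 1e-9)


def _state_keys(defn: CharacterDefinition, values: list, tol_frac: float):
    """Binned survivor states for entropy computation."""
    if defn.kind in ("coded_categorical", "count"):
        return [coded_letter(defn.id, v) for v in values]
    if defn.kind == "segment_range":
        return [(v.lo, v.hi) for v in values]
    if defn.kind == "order_expression":
        return [tuple(frozenset(g) for g in v.groups) for v in values]
    if defn.id == "costal_ratios":
        keys = []
        for pos in range(3):
            col = [v[pos] for v in values]
            width = tol_frac * median(col)
            keys.append([_bin(x, min(col), width) for x in col])
        return list(zip(*keys))
    col = [float(v) for v in values]
    width = tol_frac * median(col)
    return [_bin(x, min(col), width) for x in col]


def next_best_character(m: CodedMatrix, surviving: set[str],
                        answered: set[str],
                        tol: ToleranceConfig | None = None) -> str:
    """The unanswered character that best splits the surviving taxa.

    Scores each unanswered character by the Shannon entropy of the
    survivors' state distribution — numeric characters are binned into
    tolerance-width windows (width = relative tolerance × median survivor
    value) so differences the engine would forgive do not count as
    splits.  Ties break in schema order.  Raises
    :class:`~megakey.errors.ExhaustedKeyError` when no character remains
    or no remaining character separates any survivors.
    """
    tol = tol or ToleranceConfig()
    if len(surviving) < 2:
        raise UsageError("need at least two surviving taxa")
    rows = [m.row(name) for name in sorted(surviving)]
    candidates = [d for d in canonical_schema() if d.id not in answered]
    if not candidates:
        raise ExhaustedKeyError("every character has been answered")
    best_id, best_h = None, 0.0
    for defn in candidates:
        values = [d.values[defn.id].value for d in rows
                  if not d.values[defn.id].is_unknown]
        if len(values) < 2:
            continue
        counts = Counter(_state_keys(defn, values, tol.numeric_tol(defn.id)))
        n = sum(counts.values())
        h = -sum((c / n) * math.log2(c / n) for c in counts.values())
        if h > best_h + 1e-12:
            best_id, best_h = defn.id, h
    if best_id is None:
        raise ExhaustedKeyError(
            "no unanswered character separates the surviving taxa")
    return best_id
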