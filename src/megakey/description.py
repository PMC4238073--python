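"""Single-taxon description documents.

A description is one taxon's record under the 29-character table system:
the taxon name, a value for every character (possibly unknown), optional
per-character and general free-text remarks, and opaque figure labels.

Two on-disk dialects are supported:

* **TSV** — a human-facing transcription of the printed three-column
  table layout (character label, value, remark) with body-region section
  headers, UTF-8 and tab-separated.
* **JSON** — a machine-facing object keyed by stable character ids, with
  every value in its canonical cell text form.

Parsing is strict by default: any unresolvable cell aborts with an
aggregated :class:`~megakey.errors.DescriptionValidationError`.  Lenient
mode turns bad cells into unknowns and records a warning instead, for
ingesting legacy material with gaps.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

from .errors import DescriptionValidationError, MatrixFormatError, MegakeyError
from .schema import (
    UNKNOWN,
    CharacterValue,
    SegmentRange,
    canonical_schema,
    character_ids,
    encode_value,
    format_value,
    get_definition,
    resolve_state,
    schema_index,
)
from .setation import SetationOrder

DESCRIPTION_FORMAT = "megaselia-description"
DESCRIPTION_VERSION = 1

_SECTION_TITLES = {"head": "Head", "thorax": "Thorax", "leg": "Leg",
                   "wing": "Wing", "genitalia": "Genitalia"}
_GENERAL_HEADER = "General Remarks"


@dataclass(frozen=True)
class Finding:
    """One validation finding: ``level`` is "error" or "warning";
    ``character_id`` is None for document-level findings."""

    level: str
    character_id: str | None
    message: str


@dataclass
class Description:
    """One taxon's full table-based record.

    ``values`` maps every schema character id to a
    :class:`~megakey.schema.CharacterValue` (remarks ride on the values);
    ``figure_refs`` maps a section name ("habitus", "wing", "genitalia",
    ...) to an opaque figure label.  ``parse_warnings`` records tolerated
    oddities seen while parsing and is excluded from equality.
    """

    taxon_name: str
    values: dict[str, CharacterValue]
    general_remarks: str = ""
    figure_refs: dict[str, str] = field(default_factory=dict)
    parse_warnings: list[Finding] = field(default_factory=list, compare=False,
                                          repr=False)

    @property
    def character_remarks(self) -> dict[str, str]:
        return {cid: v.remark for cid, v in self.values.items() if v.remark}

    def value_of(self, character_id: str):
        v = self.values.get(character_id)
        return None if v is None else v.value

    def known_ids(self) -> list[str]:
        return [cid for cid, v in self.values.items() if not v.is_unknown]


def build_description(taxon_name: str, raw_values: dict | None = None,
                      remarks: dict | None = None, general_remarks: str = "",
                      figure_refs: dict | None = None) -> Description:
    """Build a Description from raw values, filling unspecified characters
    with unknowns.  ``raw_values`` maps character id to anything
    :func:`~megakey.schema.encode_value` accepts."""
    raw_values = raw_values or {}
    remarks = remarks or {}
    values: dict[str, CharacterValue] = {}
    for cid in character_ids():
        raw = raw_values.get(cid, UNKNOWN)
        if isinstance(raw, CharacterValue):
            values[cid] = raw
        else:
            values[cid] = encode_value(cid, raw, remark=remarks.get(cid, ""))
    return Description(taxon_name, values, general_remarks,
                       dict(figure_refs or {}))


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _check_value(d, v: CharacterValue) -> list[Finding]:
    out = []
    err = lambda msg: out.append(Finding("error", d.id, msg))
    warn = lambda msg: out.append(Finding("warning", d.id, msg))
    x = v.value
    if x is None:
        return out
    if d.id == "costal_ratios":
        if not (isinstance(x, tuple) and len(x) == 3):
            err(f"costal ratios must be a (C1, C2, C3) triple, got {x!r}")
        elif x[2] != 1:
            err(f"C3 must be 1 in costal ratios, got {x[2]!r}")
        elif any(not isinstance(e, (int, float)) or e <= 0 for e in x):
            err(f"costal ratios must be positive numbers, got {x!r}")
    elif d.kind in ("ratio", "length_mm"):
        if not isinstance(x, (int, float)) or x <= 0:
            err(f"{d.label} must be a positive number, got {x!r}")
    elif d.kind == "proportion":
        if not isinstance(x, (int, float)) or x <= 0:
            err(f"{d.label} must be a positive number, got {x!r}")
        elif x > 1:
            warn(f"{d.label} is a proportion but exceeds 1 ({x})")
    elif d.kind == "count":
        if x == "4+":
            pass
        elif not isinstance(x, int) or x < 1:
            err(f"{d.label} must be a positive integer or '4+', got {x!r}")
    elif d.kind == "coded_categorical":
        if not any(st.code == x for st in d.states):
            err(f"{d.label}: code {x!r} is not one of "
                f"{[st.code for st in d.states]}")
    elif d.kind == "segment_range":
        if not isinstance(x, SegmentRange):
            err(f"{d.label} must be a tarsomere range, got {x!r}")
    elif d.kind == "order_expression":
        if not isinstance(x, SetationOrder):
            err(f"{d.label} must be a setation ordering, got {x!r}")
    return out


def validate_description(d: Description) -> list[Finding]:
    """Check a Description against every schema constraint.

    Returns findings in schema order (document-level completeness
    findings first); the empty list means the record is fully valid.
    Never raises — findings, not exceptions.
    """
    findings: list[Finding] = []
    ids = set(character_ids())
    missing = [cid for cid in character_ids() if cid not in d.values]
    for cid in missing:
        findings.append(Finding("error", cid, f"character {cid!r} is missing"))
    extra = [cid for cid in d.values if cid not in ids]
    for cid in extra:
        findings.append(Finding("error", cid, f"unknown character {cid!r}"))
    for defn in canonical_schema():
        v = d.values.get(defn.id)
        if v is None:
            continue
        if v.character_id != defn.id:
            findings.append(Finding("error", defn.id,
                                    f"value carries wrong character id {v.character_id!r}"))
            continue
        findings.extend(_check_value(defn, v))
    return findings


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

_WS = re.compile(r"\s+")


def _norm(text: str) -> str:
    return _WS.sub(" ", text.strip()).lower()


_LABEL_TO_ID = {_norm(d.label): d.id for d in canonical_schema()}


def _write_tsv(d: Description) -> str:
    lines = [f"{d.taxon_name}\t{d.figure_refs.get('habitus', '')}"]
    for region, title in _SECTION_TITLES.items():
        fig = d.figure_refs.get(region, "")
        third = "Remarks" if region == "head" else ""
        lines.append(f"{title}\t{fig}\t{third}")
        for defn in canonical_schema():
            if defn.region != region:
                continue
            v = d.values[defn.id]
            cell = format_value(defn.id, v.value)
            lines.append(f"{defn.label}\t{cell}\t{v.remark}")
    lines.append(f"{_GENERAL_HEADER}\t\t")
    if d.general_remarks:
        lines.append(d.general_remarks)
    return "\n".join(lines) + "\n"


def _parse_tsv(text: str, strict: bool):
    lines = text.splitlines()
    taxon_name = ""
    figure_refs: dict[str, str] = {}
    raw_cells: dict[str, tuple[str, str]] = {}
    findings: list[Finding] = []
    warnings: list[Finding] = []
    general_lines: list[str] | None = None
    section_names = {_norm(t): r for r, t in _SECTION_TITLES.items()}
    seen_title = False
    for lineno, line in enumerate(lines, 1):
        if general_lines is not None:
            general_lines.append(line)
            continue
        if not line.strip():
            continue
        cells = line.split("\t")
        first = cells[0].strip()
        if not seen_title:
            taxon_name = first
            if len(cells) > 1 and cells[1].strip():
                figure_refs["habitus"] = cells[1].strip()
            seen_title = True
            continue
        if _norm(first) == _norm(_GENERAL_HEADER):
            general_lines = []
            continue
        if _norm(first) in section_names:
            region = section_names[_norm(first)]
            if len(cells) > 1 and cells[1].strip():
                figure_refs[region] = cells[1].strip()
            continue
        cid = _LABEL_TO_ID.get(_norm(first))
        if cid is None:
            findings.append(Finding("error", None,
                                    f"line {lineno}: unrecognized row label {first!r}"))
            continue
        if cid in raw_cells:
            findings.append(Finding("error", cid,
                                    f"line {lineno}: duplicate row for {cid!r}"))
            continue
        value_text = cells[1].strip() if len(cells) > 1 else ""
        remark = cells[2].strip() if len(cells) > 2 else ""
        raw_cells[cid] = (value_text, remark)
    general = "\n".join(general_lines) if general_lines else ""
    # trailing blank lines are layout, not remark content
    general = general.rstrip("\n")
    return taxon_name, figure_refs, raw_cells, general, findings, warnings


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def _write_json(d: Description) -> str:
    chars = {}
    for defn in canonical_schema():
        v = d.values[defn.id]
        entry: dict = {"value": format_value(defn.id, v.value)}
        if v.remark:
            entry["remark"] = v.remark
        chars[defn.id] = entry
    doc = {
        "format": DESCRIPTION_FORMAT,
        "version": DESCRIPTION_VERSION,
        "taxon_name": d.taxon_name,
        "figure_refs": dict(d.figure_refs),
        "characters": chars,
        "general_remarks": d.general_remarks,
    }
    return json.dumps(doc, indent=1, ensure_ascii=False) + "\n"


def description_from_json_obj(doc: dict, strict: bool = True) -> Description:
    """Build a Description from a decoded JSON-dialect object."""
    if not isinstance(doc, dict) or "characters" not in doc:
        raise MatrixFormatError("not a description object (no 'characters' key)")
    chars = doc.get("characters", {})
    raw_cells = {}
    findings = []
    for cid, entry in chars.items():
        if cid not in set(character_ids()):
            findings.append(Finding("error", cid, f"unknown character id {cid!r}"))
            continue
        if isinstance(entry, dict):
            raw_cells[cid] = (str(entry.get("value", UNKNOWN)),
                              str(entry.get("remark", "")))
        else:
            raw_cells[cid] = (str(entry), "")
    return _assemble(str(doc.get("taxon_name", "")),
                     dict(doc.get("figure_refs", {})), raw_cells,
                     str(doc.get("general_remarks", "")), findings, strict)


# ---------------------------------------------------------------------------
# Common assembly
# ---------------------------------------------------------------------------

def _assemble(taxon_name, figure_refs, raw_cells, general, findings,
              strict) -> Description:
    warnings: list[Finding] = []
    values: dict[str, CharacterValue] = {}
    for defn in canonical_schema():
        if defn.id not in raw_cells:
            findings.append(Finding("error", defn.id,
                                    f"character {defn.id!r} ({defn.label}) is missing"))
            values[defn.id] = CharacterValue(defn.id, None)
            continue
        raw, remark = raw_cells[defn.id]
        if raw == "" or raw == UNKNOWN:
            values[defn.id] = CharacterValue(defn.id, None, remark)
            continue
        try:
            if defn.kind == "coded_categorical":
                code, flagged = resolve_state(defn, raw)
                if flagged:
                    warnings.append(Finding(
                        "warning", defn.id,
                        f"non-canonical state label {raw!r} accepted as "
                        f"{defn.state_label(code)!r}"))
                values[defn.id] = CharacterValue(defn.id, code, remark)
            else:
                values[defn.id] = encode_value(defn.id, raw, remark=remark)
        except MegakeyError as exc:
            if strict:
                findings.append(Finding("error", defn.id,
                                        f"cannot parse {raw!r}: {exc}"))
                values[defn.id] = CharacterValue(defn.id, None, remark)
            else:
                warnings.append(Finding("warning", defn.id,
                                        f"unparseable cell {raw!r} treated as "
                                        f"unknown: {exc}"))
                values[defn.id] = CharacterValue(defn.id, None, remark)
    d = Description(taxon_name, values, general, figure_refs)
    post = [f for f in validate_description(d) if f.level == "error"]
    findings.extend(post)
    warnings.extend(f for f in validate_description(d) if f.level == "warning")
    if strict and findings:
        lines = "; ".join(
            f"{f.character_id or '<document>'}: {f.message}" for f in findings)
        raise DescriptionValidationError(
            f"invalid description {taxon_name!r}: {lines}", findings=findings)
    d.parse_warnings = sorted(
        warnings + ([] if strict else findings),
        key=lambda f: (schema_index(f.character_id) if f.character_id else -1))
    return d


def sniff_dialect(document: str) -> str:
    """Guess "json" or "tsv" from the document text."""
    return "json" if document.lstrip().startswith("{") else "tsv"


def parse_description(document: str, strict: bool = True) -> Description:
    """Parse a description document in either dialect (sniffed).

    In strict mode every invalid cell and every completeness violation is
    collected and raised as one
    :class:`~megakey.errors.DescriptionValidationError`; in lenient mode
    bad cells become unknowns and the problems are recorded on
    ``Description.parse_warnings``.
    """
    if sniff_dialect(document) == "json":
        try:
            doc = json.loads(document)
        except json.JSONDecodeError as exc:
            raise MatrixFormatError(
                f"malformed JSON at line {exc.lineno} column {exc.colno}: {exc.msg}"
            ) from exc
        return description_from_json_obj(doc, strict=strict)
    taxon, figs, cells, general, findings, _ = _parse_tsv(document, strict)
    return _assemble(taxon, figs, cells, general, findings, strict)


def write_description(d: Description, dialect: str = "tsv") -> str:
    """Serialize a Description deterministically in schema order.

    ``parse_description(write_description(d)) == d`` at the value level,
    remarks included, for both dialects.
    """
    if dialect == "tsv":
        return _write_tsv(d)
    if dialect == "json":
        return _write_json(d)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'tsv' or 'json')")


def description_json_schema() -> dict:
    """Draft-07 JSON Schema for the JSON dialect, for external consumers."""
    return {
        "$schema": "http://json-schema.org/draft-07/schema#",
        "title": "Megaselia table-based description",
        "type": "object",
        "required": ["format", "version", "taxon_name", "characters"],
        "properties": {
            "format": {"const": DESCRIPTION_FORMAT},
            "version": {"type": "integer"},
            "taxon_name": {"type": "string"},
            "figure_refs": {"type": "object",
                            "additionalProperties": {"type": "string"}},
            "general_remarks": {"type": "string"},
            "characters": {
                "type": "object",
                "propertyNames": {"enum": list(character_ids())},
                "additionalProperties": {
                    "type": "object",
                    "required": ["value"],
                    "properties": {"value": {"type": "string"},
                                   "remark": {"type": "string"}},
                },
            },
        },
    }
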