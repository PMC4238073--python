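"""Species × character coded matrix.

Many single-taxon descriptions assemble into one matrix: rows are taxa,
columns the 29 schema characters, cells the stored coded/numeric values.
The matrix is the substrate of the multi-access key
(:mod:`megakey.identify`) and of keyword retrieval: every free-text
remark is tokenized into an inverted index, so an extremely rare
character that lives only in remarks (a pigmented wing spot, say) still
finds its species instantly.
"""

from __future__ import annotations

import csv
import io
import json
import re

from .description import (
    DESCRIPTION_FORMAT,
    Description,
    description_from_json_obj,
    write_description,
)
from .errors import MatrixBuildError, MatrixFormatError, UsageError
from .schema import character_ids, coded_letter, format_value, get_definition

MATRIX_FORMAT = "megaselia-matrix"
MATRIX_VERSION = 1

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Lowercase, punctuation-stripped, whitespace-split remark tokens."""
    return _TOKEN_RE.findall(text.lower())


class CodedMatrix:
    """An ordered collection of validated Descriptions with a remark index.

    Rows keep insertion order; equality is row-by-row value equality, so
    ``load_matrix(save_matrix(m)) == m``.
    """

    def __init__(self, descriptions: list[Description]):
        names = [d.taxon_name for d in descriptions]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise MatrixBuildError(
                f"duplicate taxon name(s): {sorted(dupes)}")
        self.descriptions: list[Description] = list(descriptions)
        self._index: dict[str, set[str]] = {}
        for d in self.descriptions:
            for tok in self._row_tokens(d):
                self._index.setdefault(tok, set()).add(d.taxon_name)

    @staticmethod
    def _row_tokens(d: Description) -> set[str]:
        text = " ".join([d.general_remarks, *d.character_remarks.values()])
        return set(tokenize(text))

    # -- container protocol -------------------------------------------------
    @property
    def species(self) -> list[str]:
        return [d.taxon_name for d in self.descriptions]

    @property
    def columns(self) -> tuple[str, ...]:
        return character_ids()

    @property
    def remarks_index(self) -> dict[str, set[str]]:
        return {tok: set(taxa) for tok, taxa in self._index.items()}

    def __len__(self) -> int:
        return len(self.descriptions)

    def __iter__(self):
        return iter(self.descriptions)

    def __eq__(self, other) -> bool:
        return (isinstance(other, CodedMatrix)
                and self.descriptions == other.descriptions)

    def row(self, taxon_name: str) -> Description:
        for d in self.descriptions:
            if d.taxon_name == taxon_name:
                return d
        raise KeyError(taxon_name)

    def cell(self, taxon_name: str, character_id: str):
        return self.row(taxon_name).values[character_id]


def build_matrix(descriptions: list[Description]) -> CodedMatrix:
    """Assemble individually valid Descriptions into a matrix.

    Row order is insertion order; remarks are tokenized into the inverted
    index.  Raises :class:`~megakey.errors.MatrixBuildError` naming any
    duplicated taxon.
    """
    return CodedMatrix(list(descriptions))


def keyword_search(m: CodedMatrix, query: str) -> list[str]:
    """Taxa whose combined remarks contain *all* query tokens.

    Matching is case-insensitive and token-level (AND over tokens, no
    stemming), so the published retrieval behaviour — a species with
    "wing with central, bubbled, pigmented spot" in its remarks found by
    searching "wing spot" — holds verbatim.  Results are sorted by taxon
    name.
    """
    tokens = tokenize(query)
    if not tokens:
        raise UsageError("empty keyword query")
    hits: set[str] | None = None
    for tok in tokens:
        taxa = m.remarks_index.get(tok, set())
        hits = taxa if hits is None else hits & taxa
        if not hits:
            return []
    return sorted(hits)


def save_matrix(m: CodedMatrix) -> str:
    """Serialize a matrix to its JSON container (schema version + rows)."""
    rows = [json.loads(write_description(d, "json")) for d in m.descriptions]
    doc = {"format": MATRIX_FORMAT, "version": MATRIX_VERSION, "species": rows}
    return json.dumps(doc, indent=1, ensure_ascii=False) + "\n"


def load_matrix(text: str) -> CodedMatrix:
    """Parse a matrix file; corrupt input raises
    :class:`~megakey.errors.MatrixFormatError` with position context."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise MatrixFormatError(
            f"malformed matrix file at line {exc.lineno} column {exc.colno}: "
            f"{exc.msg}") from exc
    if not isinstance(doc, dict) or doc.get("format") != MATRIX_FORMAT:
        raise MatrixFormatError(
            f"not a {MATRIX_FORMAT} file (format={doc.get('format') if isinstance(doc, dict) else None!r})")
    rows = doc.get("species")
    if not isinstance(rows, list):
        raise MatrixFormatError("matrix file has no 'species' list")
    descriptions = []
    for i, row in enumerate(rows):
        if not isinstance(row, dict) or row.get("format") not in (
                None, DESCRIPTION_FORMAT):
            raise MatrixFormatError(f"species record {i} is not a description object")
        descriptions.append(description_from_json_obj(row, strict=True))
    return CodedMatrix(descriptions)


def export_csv(m: CodedMatrix) -> str:
    """Flat spreadsheet export: coded letters for coded characters,
    canonical text for the rest.  Lossy — remarks and figures are dropped."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["taxon_name", *character_ids()])
    for d in m.descriptions:
        row = [d.taxon_name]
        for cid in character_ids():
            v = d.values[cid].value
            defn = get_definition(cid)
            if v is None:
                row.append("?")
            elif defn.kind in ("coded_categorical", "count"):
                row.append(coded_letter(cid, v))
            else:
                row.append(format_value(cid, v))
        writer.writerow(row)
    return buf.getvalue()
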