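"""Exception hierarchy for megakey.

All package exceptions derive from :class:`MegakeyError` so callers can
catch the whole family with one clause; the CLI maps them to distinct
exit codes.
"""

from __future__ import annotations


class MegakeyError(Exception):
    """Base class for all megakey errors."""


class InvalidMeasurementError(MegakeyError, ValueError):
    """A raw measurement violates its domain (non-positive length, negative count...)."""


class UnsupportedStateError(MegakeyError, ValueError):
    """A raw observation has no coded state (e.g. 0 alular setae).

    Carries the offending raw value on ``.raw``.
    """

    def __init__(self, message: str, raw=None):
        super().__init__(message)
        self.raw = raw


class SchemaError(MegakeyError, KeyError):
    """Reference to a character id that does not exist in the canonical schema."""


class UnknownStateError(MegakeyError, ValueError):
    """A categorical label could not be resolved to a coded state.

    ``.valid_labels`` lists the labels the character accepts.
    """

    def __init__(self, message: str, valid_labels=()):
        super().__init__(message)
        self.valid_labels = tuple(valid_labels)


class SetationParseError(MegakeyError, ValueError):
    """A posterior-setation ordering expression is malformed.

    ``.position`` is the character offset at which parsing failed, when known.
    """

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


class DescriptionValidationError(MegakeyError, ValueError):
    """Aggregated strict-mode parse failure.

    ``.findings`` is the list of :class:`megakey.description.Finding`
    objects explaining every invalid cell.
    """

    def __init__(self, message: str, findings=()):
        super().__init__(message)
        self.findings = list(findings)


class MatrixBuildError(MegakeyError, ValueError):
    """Descriptions could not be assembled into a matrix (e.g. duplicate taxon)."""


class MatrixFormatError(MegakeyError, ValueError):
    """A persisted matrix or description file is corrupt or truncated."""


class UsageError(MegakeyError, ValueError):
    """An operation was called in a way that can never be meaningful
    (empty query, mismatched character ids...)."""


class ExhaustedKeyError(MegakeyError, RuntimeError):
    """No unanswered character can further separate the surviving taxa."""


class GenerationError(MegakeyError, RuntimeError):
    """The synthetic-species generator could not satisfy its constraints."""
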