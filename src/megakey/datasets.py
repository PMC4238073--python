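"""Packaged example data.

One fixture ships with the package: the table-based description of
*Megaselia shadeae* Hartop, a Costa Rican cloud-forest species whose
central bubbled wing spot and enlarged radial fork live in its remarks —
the worked example of the description system and of keyword retrieval.
"""

from __future__ import annotations

from importlib import resources

from .description import Description, parse_description


def shadeae_text() -> str:
    """Raw TSV text of the packaged *M. shadeae* description."""
    return (resources.files("megakey") / "data" / "shadeae.tsv").read_text(
        encoding="utf-8")


def shadeae_description() -> Description:
    """The packaged *M. shadeae* description, parsed strictly."""
    return parse_description(shadeae_text(), strict=True)
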