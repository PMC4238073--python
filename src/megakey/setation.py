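"""Posterior-setation ordering expressions.

Male *Megaselia* terminalia carry setae on tergite 6 (T6), the epandrium
(E), the cerci (C) and the hypoproct (H).  Their relative lengths are a
diagnostic character written as an ordering expression such as
``T6~E~H<C``: tokens in ascending order of setal length, joined by ``<``
(shorter than), ``=`` (equal) or ``~`` (subequal, approximately equal).

``=`` and ``~`` both place their operands in the same equivalence group;
the distinction is kept only for faithful re-rendering.  Two expressions
are *order-compatible* when they impose no contradictory strict order on
any token pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .errors import SetationParseError

TOKENS = ("T6", "E", "C", "H")
OPERATORS = ("<", "=", "~")


@dataclass(frozen=True)
class SetationOrder:
    """A parsed ordering expression over the four terminalia tokens.

    ``tokens`` are the structure abbreviations in written (ascending)
    order; ``relations`` are the three operators joining adjacent tokens
    exactly as written, so :meth:`render` reproduces the source text.
    """

    tokens: tuple[str, ...]
    relations: tuple[str, ...]

    def __post_init__(self):
        if sorted(self.tokens) != sorted(TOKENS):
            raise SetationParseError(
                f"expression must contain each of {TOKENS} exactly once, got {self.tokens}"
            )
        if len(self.relations) != len(self.tokens) - 1:
            raise SetationParseError(
                f"expected {len(self.tokens) - 1} operators, got {len(self.relations)}"
            )
        for op in self.relations:
            if op not in OPERATORS:
                raise SetationParseError(f"unknown operator {op!r}")

    @property
    def groups(self) -> list[set[str]]:
        """Equivalence groups in ascending length order; ``=``/``~`` merge."""
        out: list[set[str]] = [{self.tokens[0]}]
        for op, tok in zip(self.relations, self.tokens[1:]):
            if op == "<":
                out.append({tok})
            else:
                out[-1].add(tok)
        return out

    def ranks(self) -> dict[str, int]:
        """Map each token to the index of its equivalence group."""
        return {tok: i for i, grp in enumerate(self.groups) for tok in grp}

    def render(self) -> str:
        parts = [self.tokens[0]]
        for op, tok in zip(self.relations, self.tokens[1:]):
            parts.append(op)
            parts.append(tok)
        return "".join(parts)

    def __str__(self) -> str:
        return self.render()


def parse_setation_order(expression: str) -> SetationOrder:
    """Parse an expression like ``"T6<C=H<E"`` into a :class:`SetationOrder`.

    Raises :class:`SetationParseError` (with the failing character
    position) on an empty expression, an unknown token or operator, or a
    missing/duplicated token.
    """
    text = expression.strip()
    if not text:
        raise SetationParseError("empty setation expression", position=0)
    tokens: list[str] = []
    relations: list[str] = []
    pos = 0
    expect_token = True
    while pos < len(text):
        ch = text[pos]
        if ch.isspace():
            pos += 1
            continue
        if expect_token:
            matched = None
            for tok in TOKENS:  # "T6" is two characters, try longest-ish first
                if text.startswith(tok, pos):
                    matched = tok
                    break
            if matched is None:
                raise SetationParseError(
                    f"expected one of {TOKENS} at position {pos} in {expression!r}",
                    position=pos,
                )
            if matched in tokens:
                raise SetationParseError(
                    f"duplicate token {matched!r} at position {pos} in {expression!r}",
                    position=pos,
                )
            tokens.append(matched)
            pos += len(matched)
        else:
            if ch not in OPERATORS:
                raise SetationParseError(
                    f"expected operator (<, =, ~) at position {pos} in {expression!r}",
                    position=pos,
                )
            relations.append(ch)
            pos += 1
        expect_token = not expect_token
    if expect_token:
        raise SetationParseError(
            f"expression ends with an operator: {expression!r}", position=len(text)
        )
    missing = set(TOKENS) - set(tokens)
    if missing:
        raise SetationParseError(
            f"missing token(s) {sorted(missing)} in {expression!r}", position=len(text)
        )
    return SetationOrder(tuple(tokens), tuple(relations))


def orders_compatible(a: SetationOrder, b: SetationOrder) -> bool:
    """True unless the two expressions impose opposite strict orders on
    some token pair (``=``/``~`` count as equal rank, contradicting nothing)."""
    ra, rb = a.ranks(), b.ranks()
    for x, y in combinations(TOKENS, 2):
        da = ra[x] - ra[y]
        db = rb[x] - rb[y]
        if da * db < 0:
            return False
    return True
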