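"""SNOMED CT postcoordinated expressions (focus concept + refinements).

A clinical concept missing from SNOMED CT can be built compositionally
from an existing focus concept refined by attribute=value pairs, e.g.
"severe pain in the left abdomen" as::

    21522001 |abdominal pain|:
        272741003 |laterality| = 77710000 |left|,
        246113005 |severity| = 24484000 |severe|

Only this flat subset of the compositional grammar — one focus concept and
a flat list of attribute=value refinements, each code optionally followed
by a ``|display term|`` — is supported; nested refinement groups are not.
Codes are opaque digit strings, not checked against a terminology server.

Canonical rendering without terms is ``focus:attr=value,attr=value``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "Refinement",
    "PostcoordinatedExpression",
    "ExpressionSyntaxError",
    "compose_expression",
    "parse_expression",
]

_CODE_RE = re.compile(r"\d+")


class ExpressionSyntaxError(ValueError):
    """Expression text violates the grammar; ``position`` is the offset."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} at position {position}")
        self.position = position


def _check_code(code: str, what: str) -> None:
    if not code or not code.isdigit():
        raise ValueError(f"{what} must be a non-empty digit string, got {code!r}")


def _check_term(term: str | None, what: str) -> None:
    if term is not None and "|" in term:
        raise ValueError(f"{what} may not contain '|'")


@dataclass(frozen=True)
class Refinement:
    """One attribute=value refinement of a focus concept."""

    attribute_code: str
    value_code: str
    attribute_term: str | None = None
    value_term: str | None = None

    def validate(self) -> None:
        _check_code(self.attribute_code, "attribute code")
        _check_code(self.value_code, "value code")
        _check_term(self.attribute_term, "attribute term")
        _check_term(self.value_term, "value term")


@dataclass(frozen=True)
class PostcoordinatedExpression:
    """Focus concept plus ordered attribute=value refinements.

    An empty refinement list is the precoordinated case — the expression
    is just the focus concept.
    """

    focus_code: str
    focus_term: str | None = None
    refinements: tuple[Refinement, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "refinements", tuple(self.refinements))

    def validate(self) -> None:
        _check_code(self.focus_code, "focus code")
        _check_term(self.focus_term, "focus term")
        for refinement in self.refinements:
            refinement.validate()


def compose_expression(expr: PostcoordinatedExpression,
                       with_terms: bool = False) -> str:
    """Render the canonical string form of an expression.

    Without terms: ``focus:attr=value,attr=value``.  With terms, each code
    carrying a display term is followed by `` |term|``.
    """
    expr.validate()

    def code(value: str, term: str | None) -> str:
        if with_terms and term:
            return f"{value} |{term}|"
        return value

    rendered = code(expr.focus_code, expr.focus_term)
    if expr.refinements:
        rendered += ":" + ",".join(
            f"{code(r.attribute_code, r.attribute_term)}="
            f"{code(r.value_code, r.value_term)}"
            for r in expr.refinements)
    return rendered


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def at_end(self) -> bool:
        self.skip_ws()
        return self.pos >= len(self.text)

    def expect(self, char: str) -> None:
        self.skip_ws()
        if self.pos >= len(self.text) or self.text[self.pos] != char:
            raise ExpressionSyntaxError(f"expected {char!r}", self.pos)
        self.pos += 1

    def peek(self) -> str | None:
        self.skip_ws()
        return self.text[self.pos] if self.pos < len(self.text) else None

    def code_term(self) -> tuple[str, str | None]:
        self.skip_ws()
        match = _CODE_RE.match(self.text, self.pos)
        if not match:
            raise ExpressionSyntaxError("expected a concept code", self.pos)
        code = match.group()
        self.pos = match.end()
        term = None
        if self.peek() == "|":
            start = self.pos
            closing = self.text.find("|", self.pos + 1)
            if closing < 0:
                raise ExpressionSyntaxError("unterminated term", start)
            term = self.text[self.pos + 1:closing]
            self.pos = closing + 1
        return code, term


def parse_expression(text: str) -> PostcoordinatedExpression:
    """Parse the canonical grammar (terms optional, whitespace tolerated).

    Inverse of :func:`compose_expression`; grammar violations raise
    :class:`ExpressionSyntaxError` with the offending position.
    """
    parser = _Parser(text)
    focus_code, focus_term = parser.code_term()
    refinements: list[Refinement] = []
    if not parser.at_end():
        parser.expect(":")
        while True:
            attr_code, attr_term = parser.code_term()
            parser.expect("=")
            value_code, value_term = parser.code_term()
            refinements.append(
                Refinement(attr_code, value_code, attr_term, value_term))
            if parser.at_end():
                break
            parser.expect(",")
    if not parser.at_end():
        raise ExpressionSyntaxError("unexpected trailing text", parser.pos)
    return PostcoordinatedExpression(focus_code, focus_term, tuple(refinements))
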