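"""Recursive-descent parser for the expression language.

Precedence, loosest to tightest::

    or < and < not < comparisons < + - < * / < unary minus < ^

Comparisons are non-associative (``a = b = c`` is rejected); ``^`` is
right-associative and ``-x^2`` parses as ``-(x^2)``.
"""

from __future__ import annotations

import re

from ..errors import LogicParseError
from .ast import (
    COMPARISON_OPS,
    BLANK_LITERAL,
    Binary,
    Call,
    FieldRef,
    Literal,
    Node,
    SmartVar,
    Unary,
)
from .tokens import LogicToken, tokenize

__all__ = ["parse", "parse_source", "FUNCTIONS"]

# supported function -> (min arity, max arity)
FUNCTIONS: dict[str, tuple[int, int]] = {
    "if": (3, 3),
    "datediff": (3, 5),
    "round": (1, 2),
    "roundup": (1, 2),
    "rounddown": (1, 2),
    "abs": (1, 1),
    "sqrt": (1, 1),
    "min": (1, 99),
    "max": (1, 99),
    "sum": (1, 99),
    "mean": (1, 99),
}

_CHECKBOX_RE = re.compile(r"\[\s*([A-Za-z_][A-Za-z0-9_]*)\((.+?)\)\s*\]\Z")


class _Parser:
    def __init__(self, tokens: list[LogicToken]):
        self.tokens = tokens
        self.i = 0

    # -- token plumbing ----------------------------------------------------
    def _peek(self) -> LogicToken | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def _next(self) -> LogicToken:
        tok = self._peek()
        if tok is None:
            raise LogicParseError("unexpected end of expression")
        self.i += 1
        return tok

    def _at_operator(self, *ops: str) -> bool:
        tok = self._peek()
        return tok is not None and tok.kind == "operator" and tok.text.lower() in ops

    def _expect(self, kind: str) -> LogicToken:
        tok = self._peek()
        if tok is None or tok.kind != kind:
            where = "end of expression" if tok is None else f"{tok.text!r}"
            pos = None if tok is None else tok.position
            raise LogicParseError(f"expected {kind}, found {where}", position=pos)
        self.i += 1
        return tok

    # -- grammar -----------------------------------------------------------
    def parse(self) -> Node:
        if not self.tokens:
            raise LogicParseError("empty expression")
        node = self._or_expr()
        tok = self._peek()
        if tok is not None:
            raise LogicParseError(
                f"unexpected trailing token {tok.text!r}", position=tok.position
            )
        return node

    def _or_expr(self) -> Node:
        node = self._and_expr()
        while self._at_operator("or"):
            self._next()
            node = Binary("or", node, self._and_expr())
        return node

    def _and_expr(self) -> Node:
        node = self._not_expr()
        while self._at_operator("and"):
            self._next()
            node = Binary("and", node, self._not_expr())
        return node

    def _not_expr(self) -> Node:
        if self._at_operator("not"):
            self._next()
            return Unary("not", self._not_expr())
        return self._comparison()

    def _comparison(self) -> Node:
        node = self._additive()
        tok = self._peek()
        if tok is not None and tok.kind == "operator" and tok.text in COMPARISON_OPS | {"!="}:
            op = "<>" if tok.text == "!=" else tok.text
            self._next()
            node = Binary(op, node, self._additive())
            again = self._peek()
            if again is not None and again.kind == "operator" and again.text in COMPARISON_OPS | {"!="}:
                raise LogicParseError(
                    "comparisons are non-associative; use parentheses",
                    position=again.position,
                )
        return node

    def _additive(self) -> Node:
        node = self._multiplicative()
        while self._at_operator("+", "-"):
            op = self._next().text
            node = Binary(op, node, self._multiplicative())
        return node

    def _multiplicative(self) -> Node:
        node = self._unary()
        while self._at_operator("*", "/"):
            op = self._next().text
            node = Binary(op, node, self._unary())
        return node

    def _unary(self) -> Node:
        if self._at_operator("-"):
            self._next()
            return Unary("neg", self._unary())
        return self._power()

    def _power(self) -> Node:
        node = self._atom()
        if self._at_operator("^"):
            self._next()
            return Binary("^", node, self._unary())
        return node

    def _atom(self) -> Node:
        tok = self._peek()
        if tok is None:
            raise LogicParseError("dangling operator at end of expression")
        if tok.kind == "lparen":
            self._next()
            node = self._or_expr()
            self._expect("rparen")
            return node
        if tok.kind == "number":
            self._next()
            return Literal(float(tok.text), "number")
        if tok.kind == "string":
            self._next()
            text = tok.text[1:-1]
            return BLANK_LITERAL if text == "" else Literal(text, "string")
        if tok.kind == "func_name":
            nxt = self.tokens[self.i + 1] if self.i + 1 < len(self.tokens) else None
            if tok.text.lower() in ("true", "false") and (nxt is None or nxt.kind != "lparen"):
                self._next()
                return Literal(tok.text.lower(), "string")
            return self._call(tok)
        if tok.kind in ("field_ref", "smart_var", "checkbox_ref"):
            return self._bracketed(tok)
        raise LogicParseError(
            f"unexpected token {tok.text!r}", position=tok.position
        )

    def _call(self, tok: LogicToken) -> Node:
        self._next()
        name = tok.text.lower()
        if name not in FUNCTIONS:
            raise LogicParseError(
                f"unknown function {tok.text!r}", position=tok.position
            )
        self._expect("lparen")
        args: list[Node] = []
        nxt = self._peek()
        if nxt is not None and nxt.kind == "rparen":
            self._next()
        else:
            args.append(self._or_expr())
            while self._peek() is not None and self._peek().kind == "comma":
                self._next()
                args.append(self._or_expr())
            self._expect("rparen")
        lo, hi = FUNCTIONS[name]
        if not lo <= len(args) <= hi:
            raise LogicParseError(
                f"{name}() takes {lo}..{hi} arguments, got {len(args)}",
                position=tok.position,
            )
        return Call(name, tuple(args))

    def _bracketed(self, tok: LogicToken) -> Node:
        self._next()
        qualifier: str | None = None
        # `[event][field]` / `[smart-var][field]`: adjacency means qualification
        nxt = self._peek()
        if tok.kind in ("field_ref", "smart_var") and nxt is not None and nxt.kind in (
            "field_ref",
            "checkbox_ref",
        ):
            qualifier = tok.text[1:-1].strip()
            tok = self._next()
        if tok.kind == "smart_var":
            return SmartVar(tok.text[1:-1].strip())
        if tok.kind == "checkbox_ref":
            m = _CHECKBOX_RE.match(tok.text)
            return FieldRef(m.group(1), checkbox_code=m.group(2).strip(), event_qualifier=qualifier)
        return FieldRef(tok.text[1:-1].strip(), event_qualifier=qualifier)


def parse(tokens: list[LogicToken]) -> Node:
    """Parse a token list (from :func:`tokenize`) into an AST."""
    return _Parser(tokens).parse()


def parse_source(source: str) -> Node:
    """Tokenize and parse ``source`` in one step."""
    return parse(tokenize(source))
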