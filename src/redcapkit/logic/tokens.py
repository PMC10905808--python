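"""Lexer for REDCap branching-logic / calculated-field expressions.

Token kinds
-----------
``field_ref``     ``[age]``
``checkbox_ref``  ``[comorb(2)]``
``smart_var``     ``[event-name]`` (any bracketed name containing a hyphen)
``number``        ``18``, ``3.5``, ``.25``
``string``        ``'1'`` or ``"1"`` (no escape sequences, as in REDCap)
``operator``      ``= <> <= >= < > + - * / ^ and or not``
``lparen`` / ``rparen`` / ``comma``
``func_name``     bare identifier (validated against the supported set at parse time)

Concatenating the ``text`` slices at their recorded positions reproduces the
source string exactly; everything between tokens is whitespace.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from ..errors import LogicParseError

__all__ = ["LogicToken", "tokenize"]

_WORD_OPERATORS = {"and", "or", "not"}

# longest-first so "<=" wins over "<"
_SYMBOL_OPERATORS = ("<=", ">=", "<>", "!=", "=", "<", ">", "+", "-", "*", "/", "^")

_NUMBER_RE = re.compile(r"\d+\.\d+|\d+|\.\d+")
_IDENT_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")
_BRACKET_RE = re.compile(r"\[([^\[\]]*)\]")
_FIELD_NAME_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*\Z")
_CHECKBOX_RE = re.compile(r"([A-Za-z_][A-Za-z0-9_]*)\(([A-Za-z0-9_-]+)\)\Z")


@dataclass(frozen=True)
class LogicToken:
    kind: str
    text: str
    position: int  # 0-based character offset into the source

    def __repr__(self) -> str:  # compact, used in parser diagnostics
        return f"{self.kind}({self.text!r}@{self.position})"


def tokenize(source: str) -> list[LogicToken]:
    """Split ``source`` into :class:`LogicToken` objects.

    Raises :class:`LogicParseError` (with a 0-based offset) on unterminated
    strings/brackets or characters outside the expression alphabet.
    """
    tokens: list[LogicToken] = []
    i, n = 0, len(source)
    while i < n:
        ch = source[i]
        if ch.isspace():
            i += 1
            continue
        if ch == "[":
            m = _BRACKET_RE.match(source, i)
            if not m:
                raise LogicParseError("unterminated bracket", position=i)
            inner = m.group(1).strip()
            if _CHECKBOX_RE.match(inner):
                kind = "checkbox_ref"
            elif _FIELD_NAME_RE.match(inner):
                kind = "field_ref"
            elif "-" in inner and inner:
                kind = "smart_var"
            else:
                raise LogicParseError(
                    f"invalid bracketed name {inner!r}", position=i
                )
            tokens.append(LogicToken(kind, m.group(0), i))
            i = m.end()
            continue
        if ch in "'\"":
            end = source.find(ch, i + 1)
            if end < 0:
                raise LogicParseError("unterminated string literal", position=i)
            tokens.append(LogicToken("string", source[i : end + 1], i))
            i = end + 1
            continue
        if ch == "(":
            tokens.append(LogicToken("lparen", "(", i))
            i += 1
            continue
        if ch == ")":
            tokens.append(LogicToken("rparen", ")", i))
            i += 1
            continue
        if ch == ",":
            tokens.append(LogicToken("comma", ",", i))
            i += 1
            continue
        m = _NUMBER_RE.match(source, i)
        if m:
            tokens.append(LogicToken("number", m.group(0), i))
            i = m.end()
            continue
        m = _IDENT_RE.match(source, i)
        if m:
            word = m.group(0)
            kind = "operator" if word.lower() in _WORD_OPERATORS else "func_name"
            tokens.append(LogicToken(kind, word, i))
            i = m.end()
            continue
        for op in _SYMBOL_OPERATORS:
            if source.startswith(op, i):
                tokens.append(LogicToken("operator", op, i))
                i += len(op)
                break
        else:
            raise LogicParseError(f"unexpected character {ch!r}", position=i)
    return tokens
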