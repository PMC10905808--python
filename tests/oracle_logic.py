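"""Independent brute-force oracle for three-valued logic evaluation.

Expressions are plain nested tuples, evaluated directly from the Kleene
truth tables — no code shared with the engine under test. Each expression
can also be rendered to engine syntax (fully parenthesized, so only
evaluation semantics are exercised here, not precedence).

Tuple forms::

    ("atom", field, op, literal)   literal: "" | str | float
    ("not", child)
    ("and", left, right)
    ("or", left, right)

Truth values: True, False, None (None = missing/unknown).
"""

from __future__ import annotations

import random

FIELDS = ("a", "b", "c")
DOMAIN = ("", "0", "1", "2")
_OPS = ("=", "<>", "<", "<=", ">", ">=")


def _num(text):
    try:
        return float(text)
    except (TypeError, ValueError):
        return None


def eval_atom(value: str, op: str, literal) -> object:
    blank_literal = literal == ""
    if op in ("=", "<>") and blank_literal:
        is_blank = value == ""
        return is_blank if op == "=" else not is_blank
    if value == "" or (isinstance(literal, str) and literal == ""):
        return None  # comparison with blank -> missing
    lv, rv = _num(value), _num(literal)
    if lv is not None and rv is not None:
        a, b = lv, rv
    else:
        a, b = str(value), str(literal)
    return {
        "=": a == b,
        "<>": a != b,
        "<": a < b,
        "<=": a <= b,
        ">": a > b,
        ">=": a >= b,
    }[op]


def eval_expr(expr, ctx: dict) -> object:
    kind = expr[0]
    if kind == "atom":
        _, field, op, literal = expr
        return eval_atom(ctx.get(field, ""), op, literal)
    if kind == "not":
        value = eval_expr(expr[1], ctx)
        return None if value is None else not value
    left, right = eval_expr(expr[1], ctx), eval_expr(expr[2], ctx)
    if kind == "and":
        if left is False or right is False:
            return False
        if left is True and right is True:
            return True
        return None
    if kind == "or":
        if left is True or right is True:
            return True
        if left is False and right is False:
            return False
        return None
    raise ValueError(kind)


def render_expr(expr) -> str:
    kind = expr[0]
    if kind == "atom":
        _, field, op, literal = expr
        if isinstance(literal, float):
            lit = str(int(literal)) if literal == int(literal) else repr(literal)
        else:
            lit = f"'{literal}'"
        return f"[{field}] {op} {lit}"
    if kind == "not":
        return f"not ({render_expr(expr[1])})"
    return f"({render_expr(expr[1])}) {kind} ({render_expr(expr[2])})"


def random_expr(rng: random.Random, depth: int = 3):
    if depth == 0 or rng.random() < 0.35:
        field = rng.choice(FIELDS)
        op = rng.choice(_OPS)
        if rng.random() < 0.25:
            literal = ""
        elif rng.random() < 0.5:
            literal = rng.choice(DOMAIN[1:])  # string literal
        else:
            literal = float(rng.choice((0, 1, 2)))  # numeric literal
        return ("atom", field, op, literal)
    kind = rng.choice(("and", "or", "not"))
    if kind == "not":
        return ("not", random_expr(rng, depth - 1))
    return (kind, random_expr(rng, depth - 1), random_expr(rng, depth - 1))


def all_contexts():
    for va in DOMAIN:
        for vb in DOMAIN:
            for vc in DOMAIN:
                yield {"a": va, "b": vb, "c": vc}
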