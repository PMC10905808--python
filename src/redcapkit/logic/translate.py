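"""Translation of raw dictionary expressions into the post-transform convention.

Checkbox references ``[field(code)]`` are rewritten to the option-named
columns produced by the checkbox transformation; smart variables outside the
supported set (only ``[event-name]``) make the expression untranslatable and
are reported by name, mirroring the behaviour of warning rather than guessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

from ..errors import LogicParseError
from ..naming import checkbox_option_columns
from .ast import Binary, Call, FieldRef, Node, SmartVar, Unary, render
from .parser import parse_source

__all__ = ["TranslationReport", "translate", "checkbox_rename_map"]

SUPPORTED_SMART_VARS = {"event-name"}


@dataclass
class TranslationReport:
    source: str
    ast: Optional[Node]
    translatable: bool
    offending_smart_vars: list[str] = dc_field(default_factory=list)
    warning_text: str = ""
    rendered: str = ""


def checkbox_rename_map(dictionary: Sequence) -> dict[tuple[str, str], str]:
    """(checkbox field, option code) -> post-transform column name, computed
    deterministically in dictionary order."""
    taken = {f.name for f in dictionary}
    mapping: dict[tuple[str, str], str] = {}
    for f in dictionary:
        if f.field_type != "checkbox":
            continue
        columns = checkbox_option_columns(f.name, f.choices, taken)
        taken.update(columns.values())
        for code, column in columns.items():
            mapping[(f.name, code)] = column
    return mapping


def _rewrite(node: Node, renames: dict[tuple[str, str], str]) -> Node:
    if isinstance(node, FieldRef):
        qualifier = node.event_qualifier
        if qualifier in SUPPORTED_SMART_VARS:
            qualifier = None  # current event: plain reference
        if node.checkbox_code is not None:
            new_name = renames.get((node.name, node.checkbox_code))
            if new_name is not None:
                return FieldRef(new_name, event_qualifier=qualifier)
        if qualifier != node.event_qualifier:
            return FieldRef(node.name, node.checkbox_code, qualifier)
        return node
    if isinstance(node, Unary):
        return Unary(node.op, _rewrite(node.child, renames))
    if isinstance(node, Binary):
        return Binary(node.op, _rewrite(node.left, renames), _rewrite(node.right, renames))
    if isinstance(node, Call):
        return Call(node.func, tuple(_rewrite(a, renames) for a in node.args))
    return node


def _offending_smart_vars(node: Node) -> list[str]:
    seen: list[str] = []

    def visit(n: Node) -> None:
        if isinstance(n, SmartVar) and n.name not in SUPPORTED_SMART_VARS:
            if n.name not in seen:
                seen.append(n.name)
        elif isinstance(n, FieldRef):
            q = n.event_qualifier
            if q and "-" in q and q not in SUPPORTED_SMART_VARS and q not in seen:
                seen.append(q)
        elif isinstance(n, Unary):
            visit(n.child)
        elif isinstance(n, Binary):
            visit(n.left)
            visit(n.right)
        elif isinstance(n, Call):
            for a in n.args:
                visit(a)

    visit(node)
    return seen


def translate(source: str, dictionary: Sequence) -> TranslationReport:
    """Parse ``source`` and rewrite it to the post-transform column naming.

    Never raises on bad input: parse failures and unsupported smart variables
    come back as an untranslatable report carrying the diagnostic.
    """
    try:
        ast = parse_source(source)
    except LogicParseError as exc:
        return TranslationReport(
            source=source,
            ast=None,
            translatable=False,
            warning_text=f"could not parse expression: {exc}",
            rendered=source,
        )
    offending = _offending_smart_vars(ast)
    rewritten = _rewrite(ast, checkbox_rename_map(dictionary))
    if offending:
        names = ", ".join(f"[{n}]" for n in offending)
        return TranslationReport(
            source=source,
            ast=rewritten,
            translatable=False,
            offending_smart_vars=offending,
            warning_text=f"expression contains untranslatable smart variables: {names}",
            rendered=source,
        )
    return TranslationReport(
        source=source,
        ast=rewritten,
        translatable=True,
        rendered=render(rewritten),
    )
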