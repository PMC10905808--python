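"""Column/label naming helpers shared by the transform and logic layers."""

from __future__ import annotations

import re

__all__ = ["sanitize_label", "uniquify", "prettify", "checkbox_option_columns"]

_NON_ALNUM = re.compile(r"[^a-z0-9]+")
_ARM_SUFFIX = re.compile(r"_arm_\d+$")


def sanitize_label(label: str) -> str:
    """Turn a choice label into a column name: lowercase, runs of
    non-alphanumerics collapsed to ``_``, trimmed."""
    name = _NON_ALNUM.sub("_", label.lower()).strip("_")
    return name or "option"


def uniquify(names: list[str], taken: set[str]) -> list[str]:
    """Disambiguate ``names`` against each other and ``taken`` by appending
    ``_2``, ``_3``, ... to collisions."""
    seen = set(taken)
    out: list[str] = []
    for name in names:
        candidate = name
        counter = 2
        while candidate in seen:
            candidate = f"{name}_{counter}"
            counter += 1
        seen.add(candidate)
        out.append(candidate)
    return out


def prettify(raw: str) -> str:
    """Render a unique event / DAG / form name for humans:
    ``baseline_visit_arm_1`` -> ``Baseline visit``; ``hospital_11`` -> ``Hospital 11``."""
    text = _ARM_SUFFIX.sub("", raw.strip())
    text = text.replace("_", " ").strip()
    return text[:1].upper() + text[1:] if text else ""


def checkbox_option_columns(field_name: str, choices: dict[str, str],
                            taken: set[str]) -> dict[str, str]:
    """Map checkbox option code -> post-transform column name for one field.

    Names come from the sanitized option labels, uniquified against ``taken``
    and against each other in choice order.
    """
    codes = list(choices)
    names = uniquify([sanitize_label(choices[c]) for c in codes], taken)
    return dict(zip(codes, names))
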