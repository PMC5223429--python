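"""Canonical text serialization of guidelines (inverse of the parser)."""

from __future__ import annotations

from .expr import serialize_assignment, serialize_expression
from .model import ArchetypeBinding, Guideline, Rule

_INDENT = "    "


def _string_list(values) -> str:
    return ", ".join(f'"{v}"' for v in values)


def _serialize_rule(rule: Rule, depth: int) -> list:
    pad = _INDENT * depth
    inner = _INDENT * (depth + 1)
    when = _string_list(serialize_expression(e) for e in rule.when)
    then = _string_list(serialize_assignment(a) for a in rule.then)
    return [
        f'{pad}["{rule.id}"] = (RULE) <',
        f"{inner}when = <{when}>",
        f"{inner}then = <{then}>",
        f"{pad}>",
    ]


def _serialize_binding(binding: ArchetypeBinding, depth: int) -> list:
    pad = _INDENT * depth
    inner = _INDENT * (depth + 1)
    el_pad = _INDENT * (depth + 2)
    el_inner = _INDENT * (depth + 3)
    lines = [
        f'{pad}["{binding.id}"] = (ARCHETYPE_BINDING) <',
        f'{inner}archetype_id = <"{binding.archetype_id}">',
        f'{inner}domain = <"{binding.domain}">',
    ]
    if binding.elements:
        lines.append(f"{inner}elements = <")
        for el in binding.elements:
            lines.append(f'{el_pad}["{el.id}"] = (ELEMENT_BINDING) <')
            lines.append(f'{el_inner}path = <"{el.path}">')
            lines.append(f"{el_pad}>")
        lines.append(f"{inner}>")
    else:
        lines.append(f"{inner}elements = <>")
    lines.append(f"{pad}>")
    return lines


def serialize_guideline(g: Guideline) -> str:
    """Render ``g`` as guideline source; ``parse_guideline`` inverts it."""
    lines = ["(GUIDELINE) <"]
    lines.append(f'{_INDENT}id = <"{g.id}">')
    lines.append(f'{_INDENT}name = <"{g.name}">')
    if g.outputs:
        lines.append(f"{_INDENT}outputs = <{_string_list(g.outputs)}>")
    else:
        lines.append(f"{_INDENT}outputs = <>")
    if g.archetype_bindings:
        lines.append(f"{_INDENT}archetype_bindings = <")
        for binding in g.archetype_bindings:
            lines.extend(_serialize_binding(binding, 2))
        lines.append(f"{_INDENT}>")
    else:
        lines.append(f"{_INDENT}archetype_bindings = <>")
    if g.rules:
        lines.append(f"{_INDENT}rules = <")
        for rule in g.rules:
            lines.extend(_serialize_rule(rule, 2))
        lines.append(f"{_INDENT}>")
    else:
        lines.append(f"{_INDENT}rules = <>")
    lines.append(">")
    return "\n".join(lines) + "\n"
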