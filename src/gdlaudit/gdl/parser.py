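"""Parser for the guideline file serialization (``.gdl2t``).

The format nests object blocks inside angle-bracket lists:

    (GUIDELINE) <
        id = <"glucose_out_of_range">
        outputs = <"gt0049", "gt0050">
        archetype_bindings = <
            ["gt0017"] = (ARCHETYPE_BINDING) <
                archetype_id = <"openEHR-EHR-OBSERVATION.lab_test-blood_glucose.v1">
                domain = <"EHR">
                elements = <
                    ["gt0018"] = (ELEMENT_BINDING) < path = <"/data[at0001]..."> >
                >
            >
        >
        rules = <
            ["gt0004"] = (RULE) <
                when = <"$gt0020==null", "($gt0018<50,mg/dl)||($gt0018>400,mg/dl)">
                then = <"$gt0049=true", "$gt0020=true">
            >
        >
    >

Attribute values are either a comma-separated list of quoted strings or a
sequence of ``["id"] = (KIND) < ... >`` object blocks.  Expression strings
are handed to the expression sub-parser.  Every failure raises a
:class:`~gdlaudit.errors.GDLSyntaxError` carrying line and column; parsing
never yields a silently partial guideline.
"""

from __future__ import annotations

import re
from typing import Optional

from ..errors import GDLSyntaxError, UnresolvedCodeError
from . import expr as _expr
from .model import (
    ArchetypeBinding,
    ElementBinding,
    Guideline,
    Rule,
    is_gt_code,
    walk_vars,
)

_FILE_TOKEN_RE = re.compile(
    r"""
      (?P<ws>\s+)
    | (?P<comment>//[^\n]*)
    | (?P<string>"[^"\n]*")
    | (?P<ident>[A-Za-z_][A-Za-z0-9_]*)
    | (?P<punct>[\[\]()<>=,])
    """,
    re.VERBOSE,
)


class _Tok:
    __slots__ = ("kind", "text", "line", "col")

    def __init__(self, kind, text, line, col):
        self.kind = kind
        self.text = text
        self.line = line
        self.col = col


def _tokenize(text: str) -> list:
    tokens = []
    pos, line, line_start = 0, 1, 0
    while pos < len(text):
        m = _FILE_TOKEN_RE.match(text, pos)
        if m is None:
            raise GDLSyntaxError(
                f"unexpected character {text[pos]!r}",
                line=line,
                column=pos - line_start + 1,
            )
        kind = m.lastgroup
        if kind not in ("ws", "comment"):
            tokens.append(_Tok(kind, m.group(), line, m.start() - line_start + 1))
        nl = m.group().count("\n")
        if nl:
            line += nl
            line_start = m.start() + m.group().rindex("\n") + 1
        pos = m.end()
    return tokens


class _GuidelineParser:
    def __init__(self, text: str):
        self.tokens = _tokenize(text)
        self.i = 0

    def _peek(self) -> Optional[_Tok]:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def _next(self) -> _Tok:
        tok = self._peek()
        if tok is None:
            last = self.tokens[-1] if self.tokens else None
            raise GDLSyntaxError(
                "unexpected end of input",
                line=last.line if last else 1,
                column=last.col if last else 1,
            )
        self.i += 1
        return tok

    def _expect(self, text: str) -> _Tok:
        tok = self._next()
        if tok.text != text:
            raise GDLSyntaxError(
                f"expected {text!r}, found {tok.text!r}",
                line=tok.line,
                column=tok.col,
            )
        return tok

    def _expect_string(self) -> _Tok:
        tok = self._next()
        if tok.kind != "string":
            raise GDLSyntaxError(
                f"expected a quoted string, found {tok.text!r}",
                line=tok.line,
                column=tok.col,
            )
        return tok

    # ------------------------------------------------------------------

    def parse(self) -> Guideline:
        self._expect("(")
        kind = self._next()
        if kind.text != "GUIDELINE":
            raise GDLSyntaxError(
                f"expected GUIDELINE block, found {kind.text!r}",
                line=kind.line,
                column=kind.col,
            )
        self._expect(")")
        attrs = self._block_body()
        if self._peek() is not None:
            tok = self._peek()
            raise GDLSyntaxError(
                f"trailing input after guideline block: {tok.text!r}",
                line=tok.line,
                column=tok.col,
            )
        return self._build_guideline(attrs)

    def _block_body(self) -> dict:
        """Parse ``< attr* >`` where attr is ``ident = < ... >``."""
        self._expect("<")
        attrs: dict = {}
        while True:
            tok = self._peek()
            if tok is None:
                self._next()  # raises positioned end-of-input
            if tok.text == ">":
                self.i += 1
                return attrs
            if tok.kind != "ident":
                raise GDLSyntaxError(
                    f"expected attribute name, found {tok.text!r}",
                    line=tok.line,
                    column=tok.col,
                )
            name = self._next().text
            if name in attrs:
                raise GDLSyntaxError(
                    f"duplicate attribute {name!r}", line=tok.line, column=tok.col
                )
            self._expect("=")
            attrs[name] = self._value_list()

    def _value_list(self):
        """Parse ``< ... >`` holding strings, object entries, or nothing."""
        self._expect("<")
        tok = self._peek()
        if tok is None:
            self._next()
        if tok.text == ">":
            self.i += 1
            return []
        if tok.kind == "string":
            values = [self._string_value()]
            while True:
                tok = self._next()
                if tok.text == ">":
                    return values
                if tok.text != ",":
                    raise GDLSyntaxError(
                        f"expected ',' or '>', found {tok.text!r}",
                        line=tok.line,
                        column=tok.col,
                    )
                values.append(self._string_value())
        if tok.text == "[":
            entries = []
            while True:
                tok = self._peek()
                if tok is None:
                    self._next()
                if tok.text == ">":
                    self.i += 1
                    return entries
                entries.append(self._object_entry())
        raise GDLSyntaxError(
            f"expected strings or object entries, found {tok.text!r}",
            line=tok.line,
            column=tok.col,
        )

    def _string_value(self):
        tok = self._expect_string()
        return (tok.text[1:-1], tok.line, tok.col)

    def _object_entry(self):
        self._expect("[")
        ident_tok = self._expect_string()
        obj_id = ident_tok.text[1:-1]
        self._expect("]")
        self._expect("=")
        self._expect("(")
        kind_tok = self._next()
        if kind_tok.kind != "ident":
            raise GDLSyntaxError(
                f"expected block kind, found {kind_tok.text!r}",
                line=kind_tok.line,
                column=kind_tok.col,
            )
        self._expect(")")
        attrs = self._block_body()
        return (obj_id, kind_tok.text, attrs, ident_tok.line, ident_tok.col)

    # ------------------------------------------------------------------
    # semantic assembly

    def _build_guideline(self, attrs: dict) -> Guideline:
        gid = self._single_string(attrs, "id", default="")
        name = self._single_string(attrs, "name", default="")
        outputs = tuple(v for v, _, _ in attrs.get("outputs", []))
        bindings = tuple(
            self._build_binding(entry) for entry in attrs.get("archetype_bindings", [])
        )
        rules = tuple(self._build_rule(entry) for entry in attrs.get("rules", []))
        guideline = Guideline(
            id=gid, name=name, archetype_bindings=bindings, rules=rules,
            outputs=outputs,
        )
        _check_resolvable(guideline)
        return guideline

    @staticmethod
    def _single_string(attrs, name, default=None):
        if name not in attrs:
            return default
        values = attrs[name]
        if len(values) != 1 or not isinstance(values[0], tuple) or len(values[0]) != 3:
            first = values[0] if values else None
            line = first[3] if first and len(first) > 3 else 1
            raise GDLSyntaxError(f"attribute {name!r} must hold one string", line=line)
        return values[0][0]

    def _build_binding(self, entry) -> ArchetypeBinding:
        obj_id, kind, attrs, line, col = entry
        if kind != "ARCHETYPE_BINDING":
            raise GDLSyntaxError(
                f"expected ARCHETYPE_BINDING, found {kind!r}", line=line, column=col
            )
        elements = []
        for el in attrs.get("elements", []):
            el_id, el_kind, el_attrs, el_line, el_col = el
            if el_kind != "ELEMENT_BINDING":
                raise GDLSyntaxError(
                    f"expected ELEMENT_BINDING, found {el_kind!r}",
                    line=el_line,
                    column=el_col,
                )
            path = self._single_string(el_attrs, "path")
            if path is None:
                raise GDLSyntaxError(
                    f"element binding {el_id!r} lacks a path", line=el_line, column=el_col
                )
            try:
                elements.append(ElementBinding(id=el_id, path=path))
            except ValueError as err:
                raise GDLSyntaxError(str(err), line=el_line, column=el_col) from err
        try:
            return ArchetypeBinding(
                id=obj_id,
                archetype_id=self._single_string(attrs, "archetype_id", default=""),
                domain=self._single_string(attrs, "domain", default=""),
                elements=tuple(elements),
            )
        except ValueError as err:
            raise GDLSyntaxError(str(err), line=line, column=col) from err

    def _build_rule(self, entry) -> Rule:
        obj_id, kind, attrs, line, col = entry
        if kind != "RULE":
            raise GDLSyntaxError(f"expected RULE, found {kind!r}", line=line, column=col)
        when = []
        for text, e_line, e_col in attrs.get("when", []):
            try:
                when.append(_expr.parse_expression(text))
            except GDLSyntaxError as err:
                raise GDLSyntaxError(
                    f"in rule {obj_id!r} when-clause: {err}", line=e_line, column=e_col
                ) from err
        then = []
        for text, e_line, e_col in attrs.get("then", []):
            try:
                then.append(_expr.parse_assignment(text))
            except GDLSyntaxError as err:
                raise GDLSyntaxError(
                    f"in rule {obj_id!r} then-clause: {err}", line=e_line, column=e_col
                ) from err
        try:
            return Rule(id=obj_id, when=tuple(when), then=tuple(then))
        except ValueError as err:
            raise GDLSyntaxError(str(err), line=line, column=col) from err


def _check_resolvable(g: Guideline) -> None:
    """Every referenced gt-code must resolve to a binding or a rule target."""
    known = g.bound_codes() | g.assigned_codes()
    unresolved = set()
    for rule in g.rules:
        for cond in rule.when:
            for var in walk_vars(cond):
                if var.code not in known:
                    unresolved.add(var.code)
    if unresolved:
        raise UnresolvedCodeError(unresolved)


def parse_guideline(text: str) -> Guideline:
    """Parse guideline source text into a :class:`Guideline`.

    Raises :class:`GDLSyntaxError` (with line/column) on malformed input and
    :class:`UnresolvedCodeError` when a rule references an unbound, never-
    assigned gt-code.
    """
    parser = _GuidelineParser(text)
    if not parser.tokens:
        raise GDLSyntaxError("empty guideline source")
    return parser.parse()


def is_gt_code_list(values) -> bool:
    return all(is_gt_code(v) for v in values)
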