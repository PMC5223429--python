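"""Parser and serializer for condition/assignment expression strings.

The expression sub-grammar covers what guideline when/then clauses need:

    or_expr   : and_expr ( "||" and_expr )*
    and_expr  : not_expr ( "&&" not_expr )*
    not_expr  : "!" not_expr | cmp_expr
    cmp_expr  : primary ( CMPOP operand )?          -- non-associative
    primary   : "(" or_expr ")" | operand
    operand   : VAR | literal
    literal   : NUMBER "," UNIT | "true" | "false" | "null"

Quantity literals are written ``magnitude,unit`` with no space, exactly as
in guideline source (``50,mg/dl``).  Chained comparisons (``a<b<c``) are
rejected.  Assignments are ``VAR "=" literal``.
"""

from __future__ import annotations

import re
from typing import Optional, Union

from ..errors import GDLSyntaxError, UnitError
from ..units import UNITS, Quantity
from .model import (
    And,
    Assignment,
    Comparison,
    ConditionExpr,
    Lit,
    Not,
    Or,
    Var,
)

_TOKEN_RE = re.compile(
    r"""
      (?P<ws>\s+)
    | (?P<var>\$gt\d{4})
    | (?P<qty>\d+(?:\.\d+)?,[A-Za-z0-9/%]+)
    | (?P<num>\d+(?:\.\d+)?)
    | (?P<word>[A-Za-z_]+)
    | (?P<op>\|\||&&|==|!=|<=|>=|<|>|!|\(|\)|=)
    """,
    re.VERBOSE,
)

_CMP_OPS = {"==", "!=", "<", "<=", ">", ">="}


class _Token:
    __slots__ = ("kind", "text", "pos")

    def __init__(self, kind: str, text: str, pos: int):
        self.kind = kind
        self.text = text
        self.pos = pos


def _tokenize(text: str) -> list:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise GDLSyntaxError(
                f"unexpected character {text[pos]!r} in expression {text!r}",
                column=pos + 1,
            )
        kind = m.lastgroup
        if kind != "ws":
            tokens.append(_Token(kind, m.group(), pos))
        pos = m.end()
    return tokens


def _parse_quantity(tok: _Token) -> Quantity:
    mag_text, unit = tok.text.split(",", 1)
    if unit not in UNITS:
        raise GDLSyntaxError(
            f"unknown unit {unit!r} in quantity {tok.text!r}",
            column=tok.pos + 1,
        )
    return Quantity(float(mag_text), unit)


class _ExprParser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def _peek(self) -> Optional[_Token]:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def _next(self) -> _Token:
        tok = self._peek()
        if tok is None:
            raise GDLSyntaxError(
                f"unexpected end of expression {self.text!r}",
                column=len(self.text) + 1,
            )
        self.i += 1
        return tok

    def _at_op(self, text: str) -> bool:
        tok = self._peek()
        return tok is not None and tok.kind == "op" and tok.text == text

    def _error(self, message: str, tok: Optional[_Token] = None):
        col = (tok.pos + 1) if tok is not None else len(self.text) + 1
        raise GDLSyntaxError(f"{message} in expression {self.text!r}", column=col)

    # grammar -------------------------------------------------------------

    def parse_expression(self) -> ConditionExpr:
        expr = self._or_expr()
        if self._peek() is not None:
            self._error("trailing input", self._peek())
        return expr

    def parse_assignment(self) -> Assignment:
        tok = self._next()
        if tok.kind != "var":
            self._error("assignment must start with a $gt-code variable", tok)
        eq = self._next()
        if not (eq.kind == "op" and eq.text == "="):
            self._error("expected '=' in assignment", eq)
        value_tok = self._peek()
        value = self._operand()
        if not isinstance(value, Lit):
            self._error("assignment value must be a literal", value_tok)
        if self._peek() is not None:
            self._error("trailing input", self._peek())
        return Assignment(target=tok.text[1:], value=value)

    def _or_expr(self) -> ConditionExpr:
        items = [self._and_expr()]
        while self._at_op("||"):
            self.i += 1
            items.append(self._and_expr())
        return Or(tuple(items)) if len(items) > 1 else items[0]

    def _and_expr(self) -> ConditionExpr:
        items = [self._not_expr()]
        while self._at_op("&&"):
            self.i += 1
            items.append(self._not_expr())
        return And(tuple(items)) if len(items) > 1 else items[0]

    def _not_expr(self) -> ConditionExpr:
        if self._at_op("!"):
            self.i += 1
            return Not(self._not_expr())
        return self._cmp_expr()

    def _cmp_expr(self) -> ConditionExpr:
        left = self._primary()
        tok = self._peek()
        if tok is not None and tok.kind == "op" and tok.text in _CMP_OPS:
            if not isinstance(left, (Var, Lit)):
                self._error("comparison operands must be variables or literals", tok)
            self.i += 1
            right = self._operand()
            after = self._peek()
            if after is not None and after.kind == "op" and after.text in _CMP_OPS:
                self._error("chained comparison is not allowed", after)
            return Comparison(tok.text, left, right)
        return left

    def _primary(self) -> ConditionExpr:
        tok = self._peek()
        if tok is not None and tok.kind == "op" and tok.text == "(":
            self.i += 1
            expr = self._or_expr()
            close = self._next()
            if not (close.kind == "op" and close.text == ")"):
                self._error("expected ')'", close)
            return expr
        return self._operand()

    def _operand(self) -> Union[Var, Lit]:
        tok = self._next()
        if tok.kind == "var":
            return Var(tok.text[1:])
        if tok.kind == "qty":
            return Lit(_parse_quantity(tok))
        if tok.kind == "word":
            if tok.text == "true":
                return Lit(True)
            if tok.text == "false":
                return Lit(False)
            if tok.text == "null":
                return Lit(None)
            self._error(f"unknown keyword {tok.text!r}", tok)
        if tok.kind == "num":
            self._error(
                f"bare number {tok.text!r}: quantity literals require a unit "
                "(write e.g. '25,1' for a dimensionless score)",
                tok,
            )
        self._error(f"unexpected token {tok.text!r}", tok)


def parse_expression(text: str) -> ConditionExpr:
    """Parse one condition string, e.g. ``($gt0018<50,mg/dl)||($gt0018>400,mg/dl)``."""
    if not text.strip():
        raise GDLSyntaxError("empty expression")
    return _ExprParser(text).parse_expression()


def parse_assignment(text: str) -> Assignment:
    """Parse one assignment string, e.g. ``$gt0049=true``."""
    if not text.strip():
        raise GDLSyntaxError("empty assignment")
    return _ExprParser(text).parse_assignment()


# --------------------------------------------------------------------------
# serialization

def _serialize_literal(lit: Lit) -> str:
    v = lit.value
    if v is None:
        return "null"
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, Quantity):
        return f"{v.magnitude:g},{v.unit}"
    raise UnitError(f"unserializable literal: {v!r}")


def _serialize_operand(node) -> str:
    if isinstance(node, Var):
        return f"${node.code}"
    if isinstance(node, Lit):
        return _serialize_literal(node)
    raise ValueError(f"not an operand: {node!r}")


def _wrap(node) -> str:
    # operands stand alone; everything composite is parenthesized so the
    # output matches guideline source style: (a<x)||(b>y)
    if isinstance(node, (Var, Lit)):
        return _serialize_operand(node)
    return f"({serialize_expression(node)})"


def serialize_expression(expr: ConditionExpr) -> str:
    """Render an AST back to source; ``parse_expression`` inverts it."""
    if isinstance(expr, Comparison):
        return f"{_serialize_operand(expr.lhs)}{expr.op}{_serialize_operand(expr.rhs)}"
    if isinstance(expr, Or):
        return "||".join(_wrap(item) for item in expr.items)
    if isinstance(expr, And):
        return "&&".join(_wrap(item) for item in expr.items)
    if isinstance(expr, Not):
        return "!" + _wrap(expr.child)
    if isinstance(expr, (Var, Lit)):
        return _serialize_operand(expr)
    raise ValueError(f"not a condition expression: {expr!r}")


def serialize_assignment(a: Assignment) -> str:
    return f"${a.target}={_serialize_literal(a.value)}"
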