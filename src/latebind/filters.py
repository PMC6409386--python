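"""Row-filter predicate mini-language.

Grammar (parsed once at map-creation time, never per row)::

    expr     := or_expr
    or_expr  := and_expr ( '||' and_expr )*
    and_expr := not_expr ( '&&' not_expr )*
    not_expr := '!' not_expr | comparison
    comparison := operand ( ('==' | '!=' | '<=' | '>=' | '<' | '>') operand )?
    operand  := 'r.' IDENT | NUMBER | STRING | 'null' | 'true' | 'false'
               | '(' expr ')'

Field references ``r.NAME`` evaluate to the row's value, or *null* when the
field is absent.  ``==``/``!=`` treat null as a first-class value (a missing
field equals null).  Ordering comparisons against null are false.  When both
operands parse as numbers they are compared numerically, otherwise lexically
— mirroring how spreadsheet-style row expressions behave.
"""

from __future__ import annotations

import re
from typing import Callable

from .errors import FilterSyntaxError

_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<op>\|\||&&|==|!=|<=|>=|<|>|!|\(|\))
      | r\.(?P<field>[A-Za-z_][A-Za-z0-9_.]*)
      | (?P<number>-?\d+(?:\.\d+)?)
      | '(?P<sq>[^']*)'
      | "(?P<dq>[^"]*)"
      | (?P<kw>null|true|false)
      | (?P<bad>\S)
    )""",
    re.VERBOSE,
)

_NULL = object()  # sentinel distinct from any row value


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens = []
    for m in _TOKEN_RE.finditer(text):
        if m.group("bad"):
            raise FilterSyntaxError(f"unexpected character {m.group('bad')!r} in {text!r}")
        if m.group("op"):
            tokens.append(("op", m.group("op")))
        elif m.group("field"):
            tokens.append(("field", m.group("field")))
        elif m.group("number"):
            tokens.append(("number", m.group("number")))
        elif m.group("sq") is not None:
            tokens.append(("string", m.group("sq")))
        elif m.group("dq") is not None:
            tokens.append(("string", m.group("dq")))
        elif m.group("kw"):
            tokens.append(("kw", m.group("kw")))
    return tokens


def _as_number(value):
    try:
        return float(value)
    except (TypeError, ValueError):
        return None


def _compare(op: str, left, right) -> bool:
    if op == "==":
        return _eq(left, right)
    if op == "!=":
        return not _eq(left, right)
    if left is _NULL or right is _NULL:
        return False
    ln, rn = _as_number(left), _as_number(right)
    if ln is not None and rn is not None:
        left, right = ln, rn
    else:
        left, right = str(left), str(right)
    return {"<": left < right, "<=": left <= right,
            ">": left > right, ">=": left >= right}[op]


def _eq(left, right) -> bool:
    if left is _NULL or right is _NULL:
        return left is right
    ln, rn = _as_number(left), _as_number(right)
    if ln is not None and rn is not None:
        return ln == rn
    return str(left) == str(right)


class _Parser:
    def __init__(self, tokens: list[tuple[str, str]], text: str):
        self.tokens = tokens
        self.pos = 0
        self.text = text

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, None)

    def take(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def expect_op(self, op: str):
        kind, val = self.take()
        if kind != "op" or val != op:
            raise FilterSyntaxError(f"expected {op!r} in {self.text!r}")

    def parse(self) -> Callable[[dict], bool]:
        node = self.or_expr()
        if self.pos != len(self.tokens):
            raise FilterSyntaxError(f"trailing tokens in {self.text!r}")
        return node

    def or_expr(self):
        node = self.and_expr()
        while self.peek() == ("op", "||"):
            self.take()
            right = self.and_expr()
            left = node
            node = lambda row, l=left, r=right: l(row) or r(row)
        return node

    def and_expr(self):
        node = self.not_expr()
        while self.peek() == ("op", "&&"):
            self.take()
            right = self.not_expr()
            left = node
            node = lambda row, l=left, r=right: l(row) and r(row)
        return node

    def not_expr(self):
        if self.peek() == ("op", "!"):
            self.take()
            inner = self.not_expr()
            return lambda row, i=inner: not i(row)
        return self.comparison()

    def comparison(self):
        left = self.operand()
        kind, val = self.peek()
        if kind == "op" and val in ("==", "!=", "<", "<=", ">", ">="):
            self.take()
            right = self.operand()
            return lambda row, l=left, r=right, op=val: _compare(op, l(row), r(row))
        # bare operand: truthy when non-null, non-empty, not false/0
        return lambda row, l=left: _truthy(l(row))

    def operand(self):
        kind, val = self.take()
        if kind == "field":
            return lambda row, f=val: row[f] if f in row and row[f] is not None else _NULL
        if kind == "number":
            num = float(val)
            return lambda row, n=num: n
        if kind == "string":
            return lambda row, s=val: s
        if kind == "kw":
            const = {"null": _NULL, "true": True, "false": False}[val]
            return lambda row, c=const: c
        if kind == "op" and val == "(":
            node = self.or_expr()
            self.expect_op(")")
            return node
        raise FilterSyntaxError(f"unexpected token in {self.text!r}")


def _truthy(value) -> bool:
    if value is _NULL or value is False:
        return False
    if value is True:
        return True
    num = _as_number(value)
    if num is not None:
        return num != 0
    return str(value) != ""


def compile_filter(predicate: str) -> Callable[[dict], bool]:
    """Compile a predicate to ``row -> bool``; raises
    :class:`FilterSyntaxError` immediately on bad syntax."""
    tokens = _tokenize(predicate)
    if not tokens:
        raise FilterSyntaxError("empty predicate")
    return _Parser(tokens, predicate).parse()


def eval_filter(predicate: str, row: dict) -> bool:
    """One-shot convenience: compile and evaluate against a single row."""
    return compile_filter(predicate)(row)
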