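"""Arithmetic expression mini-language for device programs.

A small, deterministic expression grammar used by the scripting devices
(k_func, k_print, k_poincare, flag variables): reals, ``+ - * /``,
parentheses, unary minus, variable references, and the function set
``eq ne gt ge lt le`` (returning exactly 1.0 / 0.0), ``mod(a, b)``,
``ifle0(c, a, b)`` (a if c <= 0 else b), ``abs``, ``min``, ``max``.

Expressions are parsed once into a closure; evaluation broadcasts over
numpy arrays, so one compiled program serves both "nowhere" (global
scalar) and per-node (grid) contexts.
"""

from __future__ import annotations

import re

import numpy as np

__all__ = ["ExpressionError", "Expression", "compile_expr", "eval_expr",
           "parse_program"]


class ExpressionError(ValueError):
    """Malformed expression or unknown identifier."""


_TOKEN = re.compile(
    r"\s*(?:(?P<num>\d+\.?\d*(?:[eE][+-]?\d+)?|\.\d+(?:[eE][+-]?\d+)?)"
    r"|(?P<name>[A-Za-z_][A-Za-z_0-9]*)"
    r"|(?P<op>[-+*/(),]))"
)


def _tokenize(text: str):
    pos, out = 0, []
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or m.end() == pos:
            if text[pos:].strip():
                raise ExpressionError(
                    f"unexpected character {text[pos:].strip()[0]!r} in {text!r}"
                )
            break
        pos = m.end()
        if m.group("num") is not None:
            out.append(("num", float(m.group("num"))))
        elif m.group("name") is not None:
            out.append(("name", m.group("name")))
        else:
            out.append(("op", m.group("op")))
    out.append(("end", None))
    return out


def _bool(x):
    return np.where(x, 1.0, 0.0) if isinstance(x, np.ndarray) else float(bool(x))


def _mod(a, b):
    if np.any(np.asarray(b) == 0):
        raise ZeroDivisionError("mod(a, 0)")
    return np.mod(a, b)


def _div(a, b):
    if np.any(np.asarray(b) == 0):
        raise ZeroDivisionError("division by zero")
    return a / b


_FUNCTIONS = {
    "eq": (2, lambda a, b: _bool(np.equal(a, b))),
    "ne": (2, lambda a, b: _bool(np.not_equal(a, b))),
    "gt": (2, lambda a, b: _bool(np.greater(a, b))),
    "ge": (2, lambda a, b: _bool(np.greater_equal(a, b))),
    "lt": (2, lambda a, b: _bool(np.less(a, b))),
    "le": (2, lambda a, b: _bool(np.less_equal(a, b))),
    "mod": (2, _mod),
    "ifle0": (3, lambda c, a, b: np.where(np.less_equal(c, 0), a, b)
              if any(isinstance(v, np.ndarray) for v in (c, a, b))
              else (a if c <= 0 else b)),
    "abs": (1, np.abs),
    "min": (2, np.minimum),
    "max": (2, np.maximum),
}


class Expression:
    """A compiled expression; call with a variable context (mapping)."""

    def __init__(self, text: str, fn, names: frozenset[str]):
        self.text = text
        self._fn = fn
        self.names = names          # free variable names, for validation

    def __call__(self, context):
        return self._fn(context)

    def __repr__(self):
        return f"Expression({self.text!r})"


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.toks = _tokenize(text)
        self.i = 0
        self.names: set[str] = set()

    def peek(self):
        return self.toks[self.i]

    def next(self):
        t = self.toks[self.i]
        self.i += 1
        return t

    def expect_op(self, op):
        kind, val = self.next()
        if kind != "op" or val != op:
            raise ExpressionError(f"expected {op!r} in {self.text!r}")

    def parse(self):
        fn = self.expr()
        if self.peek()[0] != "end":
            raise ExpressionError(f"trailing tokens in {self.text!r}")
        return fn

    def expr(self):
        fn = self.term()
        while self.peek() == ("op", "+") or self.peek() == ("op", "-"):
            op = self.next()[1]
            rhs = self.term()
            if op == "+":
                fn = (lambda l, r: lambda c: l(c) + r(c))(fn, rhs)
            else:
                fn = (lambda l, r: lambda c: l(c) - r(c))(fn, rhs)
        return fn

    def term(self):
        fn = self.unary()
        while self.peek() == ("op", "*") or self.peek() == ("op", "/"):
            op = self.next()[1]
            rhs = self.unary()
            if op == "*":
                fn = (lambda l, r: lambda c: l(c) * r(c))(fn, rhs)
            else:
                fn = (lambda l, r: lambda c: _div(l(c), r(c)))(fn, rhs)
        return fn

    def unary(self):
        if self.peek() == ("op", "-"):
            self.next()
            inner = self.unary()
            return lambda c: -inner(c)
        return self.atom()

    def atom(self):
        kind, val = self.next()
        if kind == "num":
            return lambda c, _v=val: _v
        if kind == "name":
            if self.peek() == ("op", "("):
                self.next()
                if val not in _FUNCTIONS:
                    raise ExpressionError(f"unknown function {val!r}")
                arity, impl = _FUNCTIONS[val]
                args = [self.expr()]
                while self.peek() == ("op", ","):
                    self.next()
                    args.append(self.expr())
                self.expect_op(")")
                if len(args) != arity:
                    raise ExpressionError(
                        f"{val} takes {arity} arguments, got {len(args)}"
                    )
                return (lambda impl_, args_: lambda c: impl_(
                    *[a(c) for a in args_]
                ))(impl, args)
            self.names.add(val)

            def lookup(c, _n=val):
                try:
                    return c[_n]
                except KeyError:
                    raise ExpressionError(f"unknown identifier {_n!r}") from None

            return lookup
        if kind == "op" and val == "(":
            fn = self.expr()
            self.expect_op(")")
            return fn
        raise ExpressionError(f"unexpected token in {self.text!r}")


def compile_expr(text: str, known: set[str] | None = None) -> Expression:
    """Compile an expression; with ``known`` given, unknown identifiers
    raise at compile time (config errors surface before the run)."""
    p = _Parser(text)
    fn = p.parse()
    names = frozenset(p.names)
    if known is not None:
        missing = names - set(known)
        if missing:
            raise ExpressionError(
                f"unknown identifier(s) {sorted(missing)} in {text!r}"
            )
    return Expression(text, fn, names)


def eval_expr(expr: str, context) -> float:
    """Parse and evaluate in one go (scalar contexts)."""
    return compile_expr(expr)(context)


def parse_program(pgm: str | list, known: set[str] | None = None):
    """Parse an ordered assignment program ``a = expr; b = expr; ...``.

    Returns a list of (target, Expression).  Accepts either the
    semicolon-separated string form or a pre-split list of
    ``(target, expression-text)`` pairs.
    """
    pairs = []
    if isinstance(pgm, str):
        for stmt in pgm.split(";"):
            stmt = stmt.strip()
            if not stmt:
                continue
            if "=" not in stmt:
                raise ExpressionError(f"assignment expected: {stmt!r}")
            target, rhs = stmt.split("=", 1)
            pairs.append((target.strip(), rhs.strip()))
    else:
        pairs = [(t.strip(), e) for t, e in pgm]
    out = []
    for target, rhs in pairs:
        if not re.fullmatch(r"[A-Za-z_][A-Za-z_0-9]*", target):
            raise ExpressionError(f"invalid assignment target {target!r}")
        out.append((target, compile_expr(rhs, known)))
    return out
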