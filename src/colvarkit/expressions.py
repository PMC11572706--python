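"""Custom closed-form collective-variable functions.

A small expression language over named CV values: ``+ - * / ^``,
parentheses, the functions sin, cos, tan, asin, acos, atan, atan2, exp,
log, sqrt, abs, numeric literals and variable labels.  Expressions are
parsed once into an AST; evaluation runs forward-mode automatic
differentiation, so the partials df/dzeta_i are exact (not finite
differences).  Parse errors report the offending position; domain errors
(log of a negative value, sqrt of a negative, asin out of range) report the
offending value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["ExpressionSpec", "ExpressionError", "DomainError", "parse_expression",
           "CustomExpression"]

_FUNCTIONS = {"sin", "cos", "tan", "asin", "acos", "atan", "atan2",
              "exp", "log", "sqrt", "abs"}


class ExpressionError(ValueError):
    """Parse failure, with the character position that triggered it."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class DomainError(ValueError):
    """Evaluation outside a function's domain, with the offending value."""


# -- tokenizer --------------------------------------------------------------

def _tokenize(text: str):
    tokens = []  # (kind, value, pos)
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
            continue
        if c.isdigit() or (c == "." and i + 1 < n and text[i + 1].isdigit()):
            j = i
            while j < n and (text[j].isdigit() or text[j] == "."):
                j += 1
            if j < n and text[j] in "eE":
                k = j + 1
                if k < n and text[k] in "+-":
                    k += 1
                if k < n and text[k].isdigit():
                    j = k
                    while j < n and text[j].isdigit():
                        j += 1
            try:
                val = float(text[i:j])
            except ValueError:
                raise ExpressionError(f"bad numeric literal {text[i:j]!r}", i)
            tokens.append(("num", val, i))
            i = j
        elif c.isalpha() or c == "_":
            j = i
            while j < n and (text[j].isalnum() or text[j] == "_"):
                j += 1
            tokens.append(("name", text[i:j], i))
            i = j
        elif c in "+-*/^(),":
            tokens.append((c, c, i))
            i += 1
        else:
            raise ExpressionError(f"unexpected character {c!r}", i)
    tokens.append(("end", None, n))
    return tokens


# -- AST --------------------------------------------------------------------

@dataclass
class _Num:
    value: float

    def ev(self, vals, grads):
        return self.value, np.zeros(grads)


@dataclass
class _Var:
    index: int

    def ev(self, vals, grads):
        g = np.zeros(grads)
        g[self.index] = 1.0
        return vals[self.index], g


@dataclass
class _Bin:
    op: str
    left: object
    right: object

    def ev(self, vals, grads):
        a, ga = self.left.ev(vals, grads)
        b, gb = self.right.ev(vals, grads)
        if self.op == "+":
            return a + b, ga + gb
        if self.op == "-":
            return a - b, ga - gb
        if self.op == "*":
            return a * b, b * ga + a * gb
        if self.op == "/":
            if b == 0.0:
                raise DomainError("division by zero")
            return a / b, (ga * b - a * gb) / (b * b)
        # power
        if a == 0.0 and b < 0:
            raise DomainError(f"0 raised to negative power {b}")
        v = a ** b
        # d(a^b) = a^b (b/a da + ln a db); integer exponents avoid log
        if np.all(gb == 0.0):
            dv = b * a ** (b - 1.0) * ga if b != 0.0 else 0.0 * ga
        else:
            if a <= 0.0:
                raise DomainError(f"power with non-positive base {a} and varying exponent")
            dv = v * (b / a * ga + math.log(a) * gb)
        return v, dv


@dataclass
class _Neg:
    arg: object

    def ev(self, vals, grads):
        a, ga = self.arg.ev(vals, grads)
        return -a, -ga


@dataclass
class _Call:
    name: str
    args: list

    def ev(self, vals, grads):
        xs = [a.ev(vals, grads) for a in self.args]
        (a, ga) = xs[0]
        f = self.name
        if f == "atan2":
            b, gb = xs[1]
            denom = a * a + b * b
            if denom == 0.0:
                raise DomainError("atan2(0, 0) is undefined")
            return math.atan2(a, b), (b * ga - a * gb) / denom
        if f == "sin":
            return math.sin(a), math.cos(a) * ga
        if f == "cos":
            return math.cos(a), -math.sin(a) * ga
        if f == "tan":
            t = math.tan(a)
            return t, (1.0 + t * t) * ga
        if f == "asin":
            if not -1.0 <= a <= 1.0:
                raise DomainError(f"asin argument {a} outside [-1, 1]")
            return math.asin(a), ga / math.sqrt(max(1e-300, 1.0 - a * a))
        if f == "acos":
            if not -1.0 <= a <= 1.0:
                raise DomainError(f"acos argument {a} outside [-1, 1]")
            return math.acos(a), -ga / math.sqrt(max(1e-300, 1.0 - a * a))
        if f == "atan":
            return math.atan(a), ga / (1.0 + a * a)
        if f == "exp":
            v = math.exp(a)
            return v, v * ga
        if f == "log":
            if a <= 0.0:
                raise DomainError(f"log of non-positive value {a}")
            return math.log(a), ga / a
        if f == "sqrt":
            if a < 0.0:
                raise DomainError(f"sqrt of negative value {a}")
            v = math.sqrt(a)
            return v, ga / (2.0 * v) if v > 0 else ga * math.inf
        if f == "abs":
            return abs(a), (1.0 if a >= 0 else -1.0) * ga
        raise AssertionError(f)  # pragma: no cover


# -- parser (recursive descent, ^ right-associative) -----------------------

class _Parser:
    def __init__(self, tokens, labels):
        self.toks = tokens
        self.pos = 0
        self.labels = list(labels)

    def peek(self):
        return self.toks[self.pos]

    def next(self):
        t = self.toks[self.pos]
        self.pos += 1
        return t

    def expect(self, kind):
        t = self.next()
        if t[0] != kind:
            raise ExpressionError(f"expected {kind!r}, found {t[1]!r}", t[2])
        return t

    def parse(self):
        node = self.expr()
        t = self.peek()
        if t[0] != "end":
            raise ExpressionError(f"unexpected trailing token {t[1]!r}", t[2])
        return node

    def expr(self):
        node = self.term()
        while self.peek()[0] in "+-":
            op = self.next()[0]
            node = _Bin(op, node, self.term())
        return node

    def term(self):
        node = self.unary()
        while self.peek()[0] in "*/":
            op = self.next()[0]
            node = _Bin(op, node, self.unary())
        return node

    def unary(self):
        t = self.peek()
        if t[0] == "-":
            self.next()
            return _Neg(self.unary())
        if t[0] == "+":
            self.next()
            return self.unary()
        return self.power()

    def power(self):
        base = self.atom()
        if self.peek()[0] == "^":
            self.next()
            return _Bin("^", base, self.unary())  # right-associative
        return base

    def atom(self):
        t = self.next()
        if t[0] == "num":
            return _Num(t[1])
        if t[0] == "(":
            node = self.expr()
            self.expect(")")
            return node
        if t[0] == "name":
            name = t[1]
            if self.peek()[0] == "(":
                if name not in _FUNCTIONS:
                    raise ExpressionError(f"unknown function {name!r}", t[2])
                self.next()
                args = [self.expr()]
                while self.peek()[0] == ",":
                    self.next()
                    args.append(self.expr())
                self.expect(")")
                nargs = 2 if name == "atan2" else 1
                if len(args) != nargs:
                    raise ExpressionError(
                        f"{name} takes {nargs} argument(s), got {len(args)}", t[2])
                return _Call(name, args)
            if name not in self.labels:
                raise ExpressionError(f"unknown identifier {name!r}", t[2])
            return _Var(self.labels.index(name))
        raise ExpressionError(f"unexpected token {t[1]!r}", t[2])


@dataclass
class ExpressionSpec:
    expression: str
    variable_labels: list


def parse_expression(spec: ExpressionSpec):
    """Parse to an evaluator; raises :class:`ExpressionError` on failure."""
    tokens = _tokenize(spec.expression)
    return _Parser(tokens, spec.variable_labels).parse()


class CustomExpression:
    """Callable custom function f(zeta_1, ...) with exact partials.

    ``evaluate(values) -> (value, partials)`` where partials is an array
    aligned with ``variable_labels``.
    """

    def __init__(self, spec: ExpressionSpec):
        self.spec = spec
        self.ast = parse_expression(spec)
        self.n = len(spec.variable_labels)

    def evaluate(self, values):
        vals = np.asarray(values, dtype=float)
        if len(vals) != self.n:
            raise ValueError("value count does not match variable labels")
        v, g = self.ast.ev(vals, self.n)
        return float(v), g


class CustomExpressionComponent:
    """A CV defined as f(child components), chain-ruled to atom gradients."""

    periodic = False
    period = 360.0

    def __init__(self, spec: ExpressionSpec, components):
        if len(components) != len(spec.variable_labels):
            raise ValueError("one child component per variable label required")
        self.expr = CustomExpression(spec)
        self.components = list(components)

    def evaluate(self, positions):
        vals, grads = [], []
        for comp in self.components:
            v, g = comp.evaluate(positions)
            vals.append(v)
            grads.append(g)
        value, partials = self.expr.evaluate(vals)
        g = np.zeros_like(np.asarray(positions, dtype=float))
        for p, gv in zip(partials, grads):
            g += p * gv
        return value, g
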