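"""Operator-built algebraic rate expressions.

Arithmetic on model actors (Species, State, Parameter, …) builds an
:class:`Expression` tree instead of evaluating anything: ``2 + ca`` is a sum
node whose value — "two more than the local ca concentration" — is only
produced later, when the tree is compiled against a state vector.  The same
trees serve four purposes:

* **compile** — generate a vectorized evaluator (one value per location, all
  locations at once via numpy) from the canonical serialized form;
* **differentiate** — exact symbolic derivatives, used for the per-location
  reaction Jacobians of the implicit integrator;
* **reactant schemes** — expressions like ``2*hydrogen + oxygen`` are
  validated into stoichiometry maps with positive integer coefficients;
* **serialize** — a canonical fully-parenthesized string with stable
  reference ids, so structurally equal trees serialize identically (used to
  cache compiled evaluators).

The unary math catalog (log, exp, sin, …) is extensible at runtime through
:func:`register_function`.
"""

from __future__ import annotations

import itertools
import logging
import numbers
from typing import Callable, Union

import numpy as np

logger = logging.getLogger("dendrochem")

__all__ = [
    "ExpressionError",
    "CompileError",
    "SchemeError",
    "Arithmetic",
    "Expression",
    "as_expression",
    "serialize",
    "references",
    "compile_expression",
    "evaluate",
    "differentiate",
    "reactant_scheme",
    "register_function",
    "log",
    "log10",
    "exp",
    "sqrt",
    "sin",
    "cos",
    "tan",
    "sinh",
    "cosh",
    "tanh",
    "fabs",
]

_ref_ids = itertools.count()

#: tolerance deciding whether a constant counts as an integer in schemes
_INT_TOL = 1e-9

_BINARY_OPS = ("+", "-", "*", "/", "**")


class ExpressionError(TypeError):
    """Unsupported operand or malformed expression tree."""


class CompileError(ExpressionError):
    """A reference in the expression could not be resolved."""


class SchemeError(ValueError):
    """Expression is not a valid reactant scheme (stoichiometric sum)."""


class Arithmetic:
    """Mixin overloading arithmetic to build expression trees.

    Model actors inherit from this; instances gain a stable ``_ref_id`` used
    in canonical serialization.
    """

    def __init__(self):
        self._ref_id = next(_ref_ids)

    def __add__(self, other):
        return _bin("+", self, other)

    def __radd__(self, other):
        return _bin("+", other, self)

    def __sub__(self, other):
        return _bin("-", self, other)

    def __rsub__(self, other):
        return _bin("-", other, self)

    def __mul__(self, other):
        return _bin("*", self, other)

    def __rmul__(self, other):
        return _bin("*", other, self)

    def __truediv__(self, other):
        return _bin("/", self, other)

    def __rtruediv__(self, other):
        return _bin("/", other, self)

    def __pow__(self, other):
        return _bin("**", self, other)

    def __rpow__(self, other):
        return _bin("**", other, self)

    def __neg__(self):
        return _bin("-", 0.0, self)

    def __pos__(self):
        return as_expression(self)


class Expression(Arithmetic):
    """A node in an algebraic tree: constant, reference, binary op, or call."""

    __slots__ = ("kind", "value", "actor", "op", "a", "b", "fname", "arg", "_ref_id")

    def __init__(self, kind, **kw):
        super().__init__()
        self.kind = kind
        self.value = kw.get("value")
        self.actor = kw.get("actor")
        self.op = kw.get("op")
        self.a = kw.get("a")
        self.b = kw.get("b")
        self.fname = kw.get("fname")
        self.arg = kw.get("arg")

    def __repr__(self) -> str:
        return f"<Expression {serialize(self)}>"


def as_expression(obj) -> Expression:
    """Promote a number or actor to an Expression node (trees pass through)."""
    if isinstance(obj, Expression):
        return obj
    if isinstance(obj, numbers.Real) and not isinstance(obj, bool):
        return Expression("const", value=float(obj))
    if isinstance(obj, Arithmetic):
        return Expression("ref", actor=obj)
    raise ExpressionError(f"cannot use {obj!r} in a rate expression")


def _bin(op: str, a, b) -> Expression:
    if op not in _BINARY_OPS:
        raise ExpressionError(f"unsupported operator {op!r}")
    try:
        ea, eb = as_expression(a), as_expression(b)
    except ExpressionError:
        return NotImplemented
    return Expression("bin", op=op, a=ea, b=eb)


def _call(fname: str, arg) -> Expression:
    if fname not in _CATALOG:
        raise ExpressionError(f"unknown function {fname!r}")
    return Expression("call", fname=fname, arg=as_expression(arg))


# ---------------------------------------------------------------------------
# math catalog: name -> (numpy evaluator, derivative builder arg -> d f/d arg)
# ---------------------------------------------------------------------------

_CATALOG: dict[str, tuple[Callable, Callable[[Expression], Expression]]] = {}


def register_function(
    name: str,
    evaluator: Callable,
    derivative: Callable[[Expression], Expression],
) -> Callable:
    """Add a unary function to the math catalog at runtime.

    ``evaluator`` must accept numpy arrays; ``derivative`` maps the argument
    expression to d f/d arg (the chain rule is applied by
    :func:`differentiate`).  Returns a builder usable in expressions.
    """
    _CATALOG[name] = (evaluator, derivative)

    def builder(arg):
        return _call(name, arg)

    builder.__name__ = name
    return builder


log = register_function("log", np.log, lambda a: 1.0 / a)
log10 = register_function(
    "log10", np.log10, lambda a: 1.0 / (a * float(np.log(10.0)))
)
exp = register_function("exp", np.exp, lambda a: _call("exp", a))
sqrt = register_function("sqrt", np.sqrt, lambda a: 0.5 / _call("sqrt", a))
sin = register_function("sin", np.sin, lambda a: _call("cos", a))
cos = register_function("cos", np.cos, lambda a: 0.0 - _call("sin", a))
tan = register_function("tan", np.tan, lambda a: 1.0 + _call("tan", a) ** 2)
sinh = register_function("sinh", np.sinh, lambda a: _call("cosh", a))
cosh = register_function("cosh", np.cosh, lambda a: _call("sinh", a))
tanh = register_function("tanh", np.tanh, lambda a: 1.0 - _call("tanh", a) ** 2)
fabs = register_function("fabs", np.fabs, lambda a: a / _call("fabs", a))


# ---------------------------------------------------------------------------
# serialization and traversal
# ---------------------------------------------------------------------------


def _ref_label(actor) -> str:
    name = getattr(actor, "name", None)
    return f"{name or type(actor).__name__}#{actor._ref_id}"


def serialize(expr: Expression) -> str:
    """Canonical fully-parenthesized form with stable reference ids."""
    expr = as_expression(expr)
    if expr.kind == "const":
        return repr(expr.value)
    if expr.kind == "ref":
        return _ref_label(expr.actor)
    if expr.kind == "bin":
        return f"({serialize(expr.a)}{expr.op}{serialize(expr.b)})"
    if expr.kind == "call":
        return f"{expr.fname}({serialize(expr.arg)})"
    raise ExpressionError(f"unknown node kind {expr.kind!r}")


def references(expr: Expression) -> list:
    """Unique actors referenced, in order of first appearance."""
    out: list = []
    seen: set[int] = set()

    def visit(e):
        if e.kind == "ref":
            if id(e.actor) not in seen:
                seen.add(id(e.actor))
                out.append(e.actor)
        elif e.kind == "bin":
            visit(e.a)
            visit(e.b)
        elif e.kind == "call":
            visit(e.arg)

    visit(as_expression(expr))
    return out


# ---------------------------------------------------------------------------
# compilation
# ---------------------------------------------------------------------------

IndexMap = dict  # actor -> index array (into the state vector) or a number


def compile_expression(expr: Expression, index_map: IndexMap) -> Callable:
    """Compile a tree into a vectorized evaluator ``f(state) -> values``.

    ``index_map`` maps each referenced actor either to an integer index array
    (its locations in the state vector) or to a plain number (parameters).
    Unresolved references raise :class:`CompileError` naming the reference.
    The evaluator is generated by serializing the tree into Python/numpy
    source and byte-compiling it, so evaluation is a single vectorized pass.
    """
    expr = as_expression(expr)
    ns: dict = {"_np": np}

    def emit(e) -> str:
        if e.kind == "const":
            return repr(e.value)
        if e.kind == "ref":
            actor = e.actor
            if actor in index_map:
                v = index_map[actor]
                if isinstance(v, numbers.Real):
                    return repr(float(v))
                name = f"_i{actor._ref_id}"
                ns[name] = np.asarray(v, dtype=np.intp)
                return f"_s[{name}]"
            value = getattr(actor, "value", None)
            if value is not None and getattr(actor, "_is_parameter", False):
                return repr(float(value))
            raise CompileError(f"unresolved reference {_ref_label(actor)}")
        if e.kind == "bin":
            return f"({emit(e.a)}{e.op}{emit(e.b)})"
        if e.kind == "call":
            fn = f"_f_{e.fname}"
            ns[fn] = _CATALOG[e.fname][0]
            return f"{fn}({emit(e.arg)})"
        raise ExpressionError(f"unknown node kind {e.kind!r}")

    source = f"lambda _s: {emit(expr)}"
    raw = eval(source, ns)  # noqa: S307 - source generated above

    def evaluator(state):
        with np.errstate(divide="ignore", invalid="ignore"):
            result = raw(np.asarray(state))
        if not np.all(np.isfinite(np.atleast_1d(result))):
            logger.warning("expression %s evaluated to a non-finite value",
                           serialize(expr))
        return result

    evaluator.source = source
    return evaluator


def evaluate(expr: Expression, values: dict) -> float:
    """Interpret a tree at scalar reference values (reference path for tests)."""
    e = as_expression(expr)
    if e.kind == "const":
        return e.value
    if e.kind == "ref":
        if e.actor in values:
            return float(values[e.actor])
        value = getattr(e.actor, "value", None)
        if value is not None and getattr(e.actor, "_is_parameter", False):
            return float(value)
        raise CompileError(f"unresolved reference {_ref_label(e.actor)}")
    if e.kind == "bin":
        a, b = evaluate(e.a, values), evaluate(e.b, values)
        if e.op == "+":
            return a + b
        if e.op == "-":
            return a - b
        if e.op == "*":
            return a * b
        if e.op == "/":
            return a / b
        return a ** b
    return float(_CATALOG[e.fname][0](evaluate(e.arg, values)))


# ---------------------------------------------------------------------------
# symbolic differentiation
# ---------------------------------------------------------------------------


def _is_const(e, value=None) -> bool:
    return e.kind == "const" and (value is None or e.value == value)


def _add(a, b):
    a, b = as_expression(a), as_expression(b)
    if _is_const(a, 0.0):
        return b
    if _is_const(b, 0.0):
        return a
    if _is_const(a) and _is_const(b):
        return as_expression(a.value + b.value)
    return _bin("+", a, b)


def _sub(a, b):
    a, b = as_expression(a), as_expression(b)
    if _is_const(b, 0.0):
        return a
    if _is_const(a) and _is_const(b):
        return as_expression(a.value - b.value)
    return _bin("-", a, b)


def _mul(a, b):
    a, b = as_expression(a), as_expression(b)
    if _is_const(a, 0.0) or _is_const(b, 0.0):
        return as_expression(0.0)
    if _is_const(a, 1.0):
        return b
    if _is_const(b, 1.0):
        return a
    if _is_const(a) and _is_const(b):
        return as_expression(a.value * b.value)
    return _bin("*", a, b)


def _div(a, b):
    a, b = as_expression(a), as_expression(b)
    if _is_const(a, 0.0):
        return a
    if _is_const(b, 1.0):
        return a
    return _bin("/", a, b)


def differentiate(expr: Expression, wrt) -> Expression:
    """Symbolic derivative d expr / d wrt with standard calculus rules."""
    e = as_expression(expr)
    if e.kind == "const":
        return as_expression(0.0)
    if e.kind == "ref":
        return as_expression(1.0 if e.actor is wrt else 0.0)
    if e.kind == "bin":
        da, db = differentiate(e.a, wrt), differentiate(e.b, wrt)
        if e.op == "+":
            return _add(da, db)
        if e.op == "-":
            return _sub(da, db)
        if e.op == "*":
            return _add(_mul(da, e.b), _mul(e.a, db))
        if e.op == "/":
            # (a/b)' = a'/b - a b'/b^2
            return _sub(_div(da, e.b), _div(_mul(e.a, db), _mul(e.b, e.b)))
        # power rule; general case a**b = exp(b log a)
        if _is_const(e.b):
            n = e.b.value
            return _mul(_mul(n, _bin("**", e.a, as_expression(n - 1.0))), da)
        if _is_const(e.a):
            return _mul(_mul(e, _call("log", e.a)), db)
        return _mul(
            e, _add(_mul(db, _call("log", e.a)), _div(_mul(e.b, da), e.a))
        )
    if e.kind == "call":
        try:
            _, deriv = _CATALOG[e.fname]
        except KeyError:
            raise ExpressionError(f"no derivative for function {e.fname!r}")
        return _mul(as_expression(deriv(e.arg)), differentiate(e.arg, wrt))
    raise ExpressionError(f"unknown node kind {e.kind!r}")


# ---------------------------------------------------------------------------
# reactant schemes
# ---------------------------------------------------------------------------


def reactant_scheme(expr: Union[Expression, Arithmetic]) -> dict:
    """Validate a reactant expression into {actor: positive integer coefficient}.

    Valid schemes are stoichiometric sums of positive integer multiples of
    actors: only ``+`` and multiplication by integers are allowed — no
    functions, non-integer numbers, subtraction, or division.  A reaction is
    not an equality, so no algebraic simplification is performed; integer
    multiplication does distribute exactly over sums, so ``2*(h + o)`` maps
    to ``{h: 2, o: 2}`` just like its expanded form and ``2*(2*h + o)`` to
    ``{h: 4, o: 2}``.
    """
    out: dict = {}

    def as_int(e) -> int:
        if e.kind != "const":
            raise SchemeError(
                f"invalid multiplier {serialize(e)} in reactant scheme"
            )
        c = e.value
        if abs(c - round(c)) >= _INT_TOL:
            raise SchemeError(f"non-integer coefficient {c} in reactant scheme")
        n = int(round(c))
        if n <= 0:
            raise SchemeError(f"non-positive coefficient {n} in reactant scheme")
        return n

    def walk(e, mult: int):
        if e.kind == "ref":
            out[e.actor] = out.get(e.actor, 0) + mult
        elif e.kind == "bin" and e.op == "+":
            walk(e.a, mult)
            walk(e.b, mult)
        elif e.kind == "bin" and e.op == "*":
            if _is_const(e.a):
                walk(e.b, mult * as_int(e.a))
            elif _is_const(e.b):
                walk(e.a, mult * as_int(e.b))
            else:
                raise SchemeError(
                    "reactant schemes allow only integer multiples of species"
                )
        elif e.kind == "const":
            raise SchemeError("bare numbers are not valid reactants")
        elif e.kind == "call":
            raise SchemeError("functions are not allowed in reactant schemes")
        else:
            raise SchemeError(
                f"operation {e.op!r} is not allowed in reactant schemes"
            )

    walk(as_expression(expr), 1)
    if not out:
        raise SchemeError("empty reactant scheme")
    return out
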