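"""Shared helpers: random expression trees and a finite-difference oracle."""

import numpy as np

import dendrochem as dc


def random_expression(rng, refs, depth=3):
    """A random expression tree over the given references.

    Operand values are kept in domains where all catalog functions are
    well-defined for positive inputs around 1.
    """
    if depth == 0 or rng.random() < 0.25:
        if rng.random() < 0.6:
            return dc.as_expression(refs[rng.integers(0, len(refs))])
        return dc.as_expression(float(rng.uniform(0.2, 2.0)))
    kind = rng.random()
    if kind < 0.65:
        op = rng.choice(["+", "-", "*", "/"])
        a = random_expression(rng, refs, depth - 1)
        b = random_expression(rng, refs, depth - 1)
        if op == "/":
            # keep denominators bounded away from zero
            b = b * b + 0.5
        return {"+": a + b, "-": a - b, "*": a * b, "/": a / b}[op]
    if kind < 0.8:
        n = int(rng.integers(2, 4))
        return random_expression(rng, refs, depth - 1) ** n
    fn = [dc.exp, dc.sin, dc.cos, dc.tanh, dc.log, dc.sqrt][rng.integers(0, 6)]
    arg = random_expression(rng, refs, depth - 1)
    if fn in (dc.log, dc.sqrt):
        arg = arg * arg + 0.5  # positive domain
    if fn is dc.exp:
        arg = dc.tanh(arg)  # bounded argument
    return fn(arg)


def central_difference(expr, wrt, values, h=1e-6):
    """Independent derivative oracle: central finite difference."""
    hi = dict(values)
    lo = dict(values)
    hi[wrt] = values[wrt] + h
    lo[wrt] = values[wrt] - h
    return (dc.evaluate(expr, hi) - dc.evaluate(expr, lo)) / (2.0 * h)


def check_derivative(rng, refs, tol=1e-5):
    """Compare a symbolic derivative with the finite-difference oracle at a
    random point; returns (symbolic, numeric)."""
    expr = random_expression(rng, refs)
    wrt = refs[rng.integers(0, len(refs))]
    point = {r: float(rng.uniform(0.5, 1.5)) for r in refs}
    sym = dc.evaluate(dc.differentiate(expr, wrt), point)
    num = central_difference(expr, wrt, point)
    assert np.isfinite(sym) and np.isfinite(num)
    assert abs(sym - num) <= tol * max(1.0, abs(sym), abs(num)), (
        f"d/d{wrt!r} of {dc.serialize(expr)} at {point}: "
        f"symbolic {sym} vs finite difference {num}"
    )
    return sym, num
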