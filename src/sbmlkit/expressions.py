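"""Operator trees for content-MathML expressions.

Kinetic laws, rules, event triggers and (initial) assignments all share one
immutable tree type, :data:`MathNode`.  Simulation time is a distinct node
(:class:`TimeSymbol`), not a :class:`SymbolRef`, so a model parameter that
happens to be called ``t`` can never collide with time; in
:func:`free_symbols` output time is reported under :data:`TIME_ID`, a name
containing ``<`` and therefore syntactically impossible as an SBML id.

Conventions follow content MathML: unary ``minus`` is negation, ``root``
with one argument is the square root (two arguments: ``root(degree,
radicand)``), ``log`` without an explicit base is base 10 and ``ln`` is the
natural logarithm.  ``factorial`` and ``delay`` are representable — real
SBML documents contain them — but evaluation and compilation reject them;
support checking screens them out before a model reaches the compiler.
"""

from __future__ import annotations

import math as _m
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Union

from .errors import MathEvalError, ResolutionError, UnsupportedOperatorError

TIME_ID = "<time>"

N_ARY_OPS = frozenset({"plus", "times", "and", "or", "xor"})
UNARY_OPS = frozenset(
    {
        "exp", "ln", "abs", "floor", "ceiling",
        "sin", "cos", "tan", "asin", "acos", "atan",
        "sinh", "cosh", "tanh", "not", "factorial",
    }
)
BINARY_OPS = frozenset({"divide", "power"})
RELATIONAL_OPS = frozenset({"lt", "leq", "gt", "geq", "eq", "neq"})
#: every operator tag a MathNode Apply may carry; any other tag is a call
#: to a user-defined function (resolved away by function expansion)
OPERATORS = N_ARY_OPS | UNARY_OPS | BINARY_OPS | RELATIONAL_OPS | {
    "minus", "root", "log", "delay",
}


@dataclass(frozen=True)
class Number:
    value: float

    def __post_init__(self):
        object.__setattr__(self, "value", float(self.value))


@dataclass(frozen=True)
class SymbolRef:
    id: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("SymbolRef id must be nonempty")


@dataclass(frozen=True)
class TimeSymbol:
    pass


@dataclass(frozen=True)
class BoolConst:
    value: bool


@dataclass(frozen=True)
class Apply:
    op: str
    args: tuple["MathNode", ...]

    def __post_init__(self):
        object.__setattr__(self, "args", tuple(self.args))
        n = len(self.args)
        op = self.op
        if op == "minus" and n not in (1, 2):
            raise ValueError("minus takes 1 or 2 arguments")
        if op in BINARY_OPS and n != 2:
            raise ValueError(f"{op} takes exactly 2 arguments")
        if op in RELATIONAL_OPS and n != 2:
            raise ValueError(f"{op} takes exactly 2 arguments")
        if op == "not" and n != 1:
            raise ValueError("not takes exactly 1 argument")
        if op in ("and", "or") and n < 2:
            raise ValueError(f"{op} takes at least 2 arguments")
        if op in ("root", "log") and n not in (1, 2):
            raise ValueError(f"{op} takes 1 or 2 arguments")
        if op == "factorial" and n != 1:
            raise ValueError("factorial takes exactly 1 argument")
        if op in UNARY_OPS and op not in ("not", "factorial") and n != 1:
            raise ValueError(f"{op} takes exactly 1 argument")
        if op in N_ARY_OPS - {"and", "or"} and n < 1:
            raise ValueError(f"{op} takes at least 1 argument")


@dataclass(frozen=True)
class Piecewise:
    branches: tuple[tuple["MathNode", "MathNode"], ...]  # (value, condition)
    otherwise: Union["MathNode", None] = None

    def __post_init__(self):
        object.__setattr__(
            self, "branches", tuple((v, c) for v, c in self.branches)
        )


MathNode = Union[Number, SymbolRef, TimeSymbol, BoolConst, Apply, Piecewise]

TIME = TimeSymbol()


def num(x) -> Number:
    return Number(float(x))


def sym(name: str) -> SymbolRef:
    return SymbolRef(name)


def apply(op: str, *args: MathNode) -> Apply:
    return Apply(op, tuple(args))


# ---------------------------------------------------------------------------
# evaluation

def _as_bool(v, what: str) -> bool:
    if isinstance(v, bool):
        return v
    raise MathEvalError(f"{what} must be Boolean, got {v!r}")


def _as_real(v, what: str) -> float:
    if isinstance(v, bool):
        raise MathEvalError(f"{what} must be numeric, got Boolean {v!r}")
    return float(v)


def evaluate_math(node: MathNode, env: Mapping[str, float], t: float | None = None):
    """Evaluate ``node`` under ``env`` with simulation time bound to ``t``.

    Returns a float, or a bool for relational/Boolean expressions.  A
    piecewise takes the first branch whose condition is true, falling back
    to ``otherwise``; no match and no otherwise is an arithmetic error.
    """
    if isinstance(node, Number):
        return node.value
    if isinstance(node, BoolConst):
        return node.value
    if isinstance(node, TimeSymbol):
        if t is None:
            raise ResolutionError("simulation time referenced but not bound")
        return float(t)
    if isinstance(node, SymbolRef):
        try:
            return env[node.id]
        except KeyError:
            raise ResolutionError(f"unbound symbol {node.id!r}") from None
    if isinstance(node, Piecewise):
        for value, cond in node.branches:
            if _as_bool(evaluate_math(cond, env, t), "piecewise condition"):
                return evaluate_math(value, env, t)
        if node.otherwise is not None:
            return evaluate_math(node.otherwise, env, t)
        raise MathEvalError("piecewise: no branch matched and no otherwise")
    if isinstance(node, Apply):
        return _eval_apply(node, env, t)
    raise TypeError(f"not a MathNode: {node!r}")


def _eval_apply(node: Apply, env, t):
    op = node.op
    if op in ("factorial", "delay"):
        raise UnsupportedOperatorError(
            f"operator {op!r} cannot be evaluated", feature=op
        )
    if op not in OPERATORS:
        raise ResolutionError(
            f"call to unexpanded function {op!r}; run function expansion first"
        )
    if op in ("and", "or", "xor", "not"):
        vals = [_as_bool(evaluate_math(a, env, t), op) for a in node.args]
        if op == "and":
            return all(vals)
        if op == "or":
            return any(vals)
        if op == "xor":
            return sum(vals) % 2 == 1
        return not vals[0]
    vals = [_as_real(evaluate_math(a, env, t), op) for a in node.args]
    try:
        return _apply_real(op, vals)
    except (ZeroDivisionError, ValueError, OverflowError) as exc:
        raise MathEvalError(f"{op}({', '.join(map(repr, vals))}): {exc}") from exc


def _apply_real(op: str, v: list[float]):
    if op == "plus":
        return _m.fsum(v)
    if op == "times":
        out = 1.0
        for x in v:
            out *= x
        return out
    if op == "minus":
        return -v[0] if len(v) == 1 else v[0] - v[1]
    if op == "divide":
        if v[1] == 0.0:
            raise ZeroDivisionError("division by zero")
        return v[0] / v[1]
    if op == "power":
        return v[0] ** v[1]
    if op == "root":
        if len(v) == 1:
            return _m.sqrt(v[0])
        return v[1] ** (1.0 / v[0])
    if op == "log":
        if len(v) == 1:
            return _m.log10(v[0])
        return _m.log(v[1]) / _m.log(v[0])
    if op == "ln":
        return _m.log(v[0])
    if op == "ceiling":
        return float(_m.ceil(v[0]))
    if op == "floor":
        return float(_m.floor(v[0]))
    if op == "abs":
        return abs(v[0])
    if op in ("exp", "sin", "cos", "tan", "asin", "acos", "atan",
              "sinh", "cosh", "tanh"):
        return getattr(_m, op)(v[0])
    if op == "lt":
        return v[0] < v[1]
    if op == "leq":
        return v[0] <= v[1]
    if op == "gt":
        return v[0] > v[1]
    if op == "geq":
        return v[0] >= v[1]
    if op == "eq":
        return v[0] == v[1]
    if op == "neq":
        return v[0] != v[1]
    raise AssertionError(op)


# ---------------------------------------------------------------------------
# structural operations

def substitute(node: MathNode, mapping: Mapping[str, MathNode]) -> MathNode:
    """Replace every SymbolRef whose id is in ``mapping`` by its image.

    Replacement is simultaneous: images are not re-scanned against the
    mapping, so ``{x -> y, y -> 1}`` turns ``x`` into ``y``, not ``1``.
    Nodes are immutable, so sub-trees may be shared safely.
    """
    if isinstance(node, SymbolRef):
        return mapping.get(node.id, node)
    if isinstance(node, Apply):
        return Apply(node.op, tuple(substitute(a, mapping) for a in node.args))
    if isinstance(node, Piecewise):
        return Piecewise(
            tuple(
                (substitute(v, mapping), substitute(c, mapping))
                for v, c in node.branches
            ),
            substitute(node.otherwise, mapping) if node.otherwise is not None else None,
        )
    return node


def free_symbols(node: MathNode) -> set[str]:
    """All SymbolRef ids in the tree; time appears as :data:`TIME_ID`."""
    out: set[str] = set()
    _collect(node, out)
    return out


def _collect(node: MathNode, out: set[str]) -> None:
    if isinstance(node, SymbolRef):
        out.add(node.id)
    elif isinstance(node, TimeSymbol):
        out.add(TIME_ID)
    elif isinstance(node, Apply):
        for a in node.args:
            _collect(a, out)
    elif isinstance(node, Piecewise):
        for v, c in node.branches:
            _collect(v, out)
            _collect(c, out)
        if node.otherwise is not None:
            _collect(node.otherwise, out)


def walk(node: MathNode) -> Iterable[MathNode]:
    """Depth-first iterator over all nodes of the tree."""
    yield node
    if isinstance(node, Apply):
        for a in node.args:
            yield from walk(a)
    elif isinstance(node, Piecewise):
        for v, c in node.branches:
            yield from walk(v)
            yield from walk(c)
        if node.otherwise is not None:
            yield from walk(node.otherwise)


def contains_op(node: MathNode, op: str) -> bool:
    return any(isinstance(n, Apply) and n.op == op for n in walk(node))


def transform(node: MathNode, fn: Callable[[MathNode], MathNode | None]) -> MathNode:
    """Bottom-up rewrite: ``fn`` sees each (already rewritten) node and may
    return a replacement or None to keep it."""
    if isinstance(node, Apply):
        node = Apply(node.op, tuple(transform(a, fn) for a in node.args))
    elif isinstance(node, Piecewise):
        node = Piecewise(
            tuple((transform(v, fn), transform(c, fn)) for v, c in node.branches),
            transform(node.otherwise, fn) if node.otherwise is not None else None,
        )
    repl = fn(node)
    return node if repl is None else repl


# ---------------------------------------------------------------------------
# rendering

_INFIX = {"plus": "+", "minus": "-", "times": "*", "divide": "/",
          "lt": "<", "leq": "<=", "gt": ">", "geq": ">=",
          "eq": "==", "neq": "!="}


def to_string(node: MathNode) -> str:
    """Human-readable infix rendering (for dumps and error messages)."""
    if isinstance(node, Number):
        v = node.value
        return str(int(v)) if v == int(v) and abs(v) < 1e15 else repr(v)
    if isinstance(node, SymbolRef):
        return node.id
    if isinstance(node, TimeSymbol):
        return "time"
    if isinstance(node, BoolConst):
        return "true" if node.value else "false"
    if isinstance(node, Piecewise):
        parts = [f"{to_string(v)} if {to_string(c)}" for v, c in node.branches]
        if node.otherwise is not None:
            parts.append(f"else {to_string(node.otherwise)}")
        return "piecewise(" + ", ".join(parts) + ")"
    op = node.op
    args = node.args
    if op == "minus" and len(args) == 1:
        return f"-({to_string(args[0])})"
    if op in _INFIX:
        return "(" + f" {_INFIX[op]} ".join(to_string(a) for a in args) + ")"
    if op == "power":
        return f"({to_string(args[0])} ^ {to_string(args[1])})"
    if op in ("and", "or", "xor"):
        return "(" + f" {op} ".join(to_string(a) for a in args) + ")"
    return f"{op}(" + ", ".join(to_string(a) for a in args) + ")"


# ---------------------------------------------------------------------------
# code generation (hot paths: ODE right-hand sides, SSA propensities)

_CODE_FUNCS = {
    "exp": "_m.exp", "ln": "_m.log", "abs": "abs",
    "sin": "_m.sin", "cos": "_m.cos", "tan": "_m.tan",
    "asin": "_m.asin", "acos": "_m.acos", "atan": "_m.atan",
    "sinh": "_m.sinh", "cosh": "_m.cosh", "tanh": "_m.tanh",
}


def to_code(node: MathNode, symmap: Mapping[str, str], time_code: str = "t") -> str:
    """Render the tree as a Python expression string.

    ``symmap`` maps every free symbol id to a code fragment (e.g.
    ``"y[3]"``).  Used to compile rate laws once instead of walking trees
    inside integrator and SSA inner loops.
    """
    if isinstance(node, Number):
        return repr(node.value)
    if isinstance(node, BoolConst):
        return "True" if node.value else "False"
    if isinstance(node, TimeSymbol):
        return f"({time_code})"
    if isinstance(node, SymbolRef):
        try:
            return f"({symmap[node.id]})"
        except KeyError:
            raise ResolutionError(f"unbound symbol {node.id!r} in compiled math") from None
    if isinstance(node, Piecewise):
        code = "_pw_nomatch()" if node.otherwise is None else to_code(node.otherwise, symmap, time_code)
        for v, c in reversed(node.branches):
            code = (f"({to_code(v, symmap, time_code)} if "
                    f"{to_code(c, symmap, time_code)} else {code})")
        return code
    op = node.op
    if op in ("factorial", "delay"):
        raise UnsupportedOperatorError(f"operator {op!r} cannot be compiled", feature=op)
    if op not in OPERATORS:
        raise ResolutionError(f"call to unexpanded function {op!r}")
    a = [to_code(x, symmap, time_code) for x in node.args]
    if op == "plus":
        return "(" + " + ".join(a) + ")"
    if op == "times":
        return "(" + " * ".join(a) + ")"
    if op == "minus":
        return f"(-{a[0]})" if len(a) == 1 else f"({a[0]} - {a[1]})"
    if op == "divide":
        return f"({a[0]} / {a[1]})"
    if op == "power":
        return f"({a[0]} ** {a[1]})"
    if op == "root":
        return f"_m.sqrt({a[0]})" if len(a) == 1 else f"({a[1]} ** (1.0 / {a[0]}))"
    if op == "log":
        return f"_m.log10({a[0]})" if len(a) == 1 else f"(_m.log({a[1]}) / _m.log({a[0]}))"
    if op == "floor":
        return f"float(_m.floor({a[0]}))"
    if op == "ceiling":
        return f"float(_m.ceil({a[0]}))"
    if op in _CODE_FUNCS:
        return f"{_CODE_FUNCS[op]}({a[0]})"
    if op in _INFIX:
        return f"({a[0]} {_INFIX[op]} {a[1]})"
    if op == "and":
        return "(" + " and ".join(a) + ")"
    if op == "or":
        return "(" + " or ".join(a) + ")"
    if op == "not":
        return f"(not {a[0]})"
    if op == "xor":
        return "((" + " + ".join(f"bool({x})" for x in a) + ") % 2 == 1)"
    raise AssertionError(op)


def _pw_nomatch():
    raise MathEvalError("piecewise: no branch matched and no otherwise")


def compile_function(exprs: list[str], argnames: list[str], prelude: list[str] | None = None):
    """Build a fast callable returning a tuple of the given expressions.

    ``prelude`` lines (e.g. observed-variable bindings) run before the
    return.  Only ``_m`` (the math module), ``abs`` and ``_pw_nomatch`` are
    visible to the generated code.
    """
    body = "".join(f"    {line}\n" for line in (prelude or []))
    src = (f"def _f({', '.join(argnames)}):\n{body}"
           f"    return ({', '.join(exprs)}{',' if len(exprs) == 1 else ''})\n")
    ns = {"_m": _m, "abs": abs, "_pw_nomatch": _pw_nomatch, "float": float, "bool": bool}
    exec(compile(src, "<sbmlkit-codegen>", "exec"), ns)  # noqa: S102 - whitelisted namespace
    return ns["_f"]
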