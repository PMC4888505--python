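"""Derived INFO fields computed after (or without) annotation.

A post-annotation block names its input INFO keys, an output key, a
declared VCF value type, and an operation: either a pure expression over
the named fields or ``script:<function>`` calling a function from a user
script file.  Blocks evaluate in declaration order, so later blocks see
earlier outputs.  If any referenced field is absent from a record the
output key is simply absent — no error.

Expressions are a restricted subset of Python expression syntax:
arithmetic, comparisons, boolean logic, conditional expressions,
indexing (0-based), and calls to a whitelisted function table
(``first``, ``len``, ``min``, ``max``, ``sum``, ``abs``, ``float``,
``int``, ``str``, ``round``, ``sqrt``, ``log``, ``log10``, ``exp``,
``af_conf_lower``, plus any user script functions).  Attribute access,
lambdas, comprehensions and anything with side effects are rejected at
configuration time, so evaluation cannot perform I/O or mutate other
INFO keys.  Multi-valued INFO strings ("10,20") surface as lists;
``first(x)`` returns the first element of a list and a scalar unchanged.

The ``in place`` mode — a configuration with only post-annotation blocks
— runs the identical pipeline with an empty annotation source list,
deriving new INFO fields from a VCF's existing ones.
"""

from __future__ import annotations

import ast
import logging
import math
from dataclasses import dataclass, field
from statistics import NormalDist
from typing import Any, Callable

log = logging.getLogger("sweepanno")

__all__ = ["PostAnnotationSpec", "ExpressionError", "compile_expression",
           "evaluate_post", "builtin_af_conf_lower", "load_script",
           "base_function_table"]


class ExpressionError(ValueError):
    """A post-annotation expression failed static validation."""


def builtin_af_conf_lower(alt_count: float, total_count: float,
                          confidence: float = 0.95) -> float | None:
    """Lower bound of the Wilson score confidence interval for an allele
    frequency.

    Given ``alt_count`` successes out of ``total_count`` trials, returns
    the lower bound of the two-sided Wilson interval at ``confidence``
    (default 95%, z = 1.959964).  Useful for asking whether an observed
    allele frequency is distinguishable from zero.  Monotone
    non-decreasing in ``alt_count`` at fixed total and never above the
    point estimate alt/total.  ``total_count == 0`` yields no value.
    """
    if total_count is None or alt_count is None:
        return None
    n = float(total_count)
    if n <= 0:
        return None
    k = float(alt_count)
    z = NormalDist().inv_cdf(0.5 + confidence / 2.0)
    phat = k / n
    denom = 1.0 + z * z / n
    centre = phat + z * z / (2.0 * n)
    margin = z * math.sqrt(phat * (1.0 - phat) / n + z * z / (4.0 * n * n))
    return max(0.0, (centre - margin) / denom)


def _first(x: Any) -> Any:
    if isinstance(x, (list, tuple)):
        return x[0] if x else None
    return x


def base_function_table() -> dict[str, Callable]:
    return {
        "first": _first, "len": len, "min": min, "max": max, "sum": sum,
        "abs": abs, "float": float, "int": int, "str": str, "round": round,
        "sqrt": math.sqrt, "log": math.log, "log10": math.log10,
        "exp": math.exp, "af_conf_lower": builtin_af_conf_lower,
    }


def load_script(path: str) -> dict[str, Callable]:
    """Load user-defined operation/post-annotation functions.

    The file is ordinary Python executed once at configuration time; its
    top-level callables become available as ``script:<name>`` operations
    and inside post-annotation expressions.
    """
    namespace: dict[str, Any] = {}
    with open(path) as fh:
        code = compile(fh.read(), path, "exec")
    exec(code, namespace)
    return {k: v for k, v in namespace.items()
            if callable(v) and not k.startswith("_")}


_ALLOWED_NODES = (
    ast.Expression, ast.BinOp, ast.UnaryOp, ast.BoolOp, ast.Compare,
    ast.IfExp, ast.Call, ast.Name, ast.Constant, ast.Subscript, ast.List,
    ast.Tuple, ast.Slice, ast.Load, ast.keyword,
    ast.Add, ast.Sub, ast.Mult, ast.Div, ast.FloorDiv, ast.Mod, ast.Pow,
    ast.USub, ast.UAdd, ast.Not, ast.And, ast.Or,
    ast.Eq, ast.NotEq, ast.Lt, ast.LtE, ast.Gt, ast.GtE, ast.In, ast.NotIn,
)


def compile_expression(text: str, fields: tuple[str, ...],
                       functions: dict[str, Callable]):
    """Statically validate and compile a post-annotation expression.

    Rejects (at configuration time, hence fatally) any syntax outside
    the whitelist and any name that is neither a declared input field
    nor a whitelisted function.
    """
    try:
        tree = ast.parse(text, mode="eval")
    except SyntaxError as exc:
        raise ExpressionError(f"invalid expression {text!r}: {exc}") from exc
    allowed_names = set(fields) | set(functions)
    for node in ast.walk(tree):
        if not isinstance(node, _ALLOWED_NODES):
            raise ExpressionError(
                f"expression {text!r}: {type(node).__name__} is not allowed")
        if isinstance(node, ast.Call) and not isinstance(node.func, ast.Name):
            raise ExpressionError(
                f"expression {text!r}: only direct function calls are allowed")
        if isinstance(node, ast.Name) and node.id not in allowed_names:
            raise ExpressionError(
                f"expression {text!r}: unknown name {node.id!r} (not a "
                "declared field or whitelisted function)")
    return compile(tree, "<post-annotation>", "eval")


@dataclass
class PostAnnotationSpec:
    """One derived-field block: inputs, output key, expression, type."""

    fields: tuple[str, ...]
    name: str
    op: str
    value_type: str = "Float"  # Integer | Float | String | Flag
    _code: Any = field(default=None, repr=False, compare=False)

    def compile(self, functions: dict[str, Callable]) -> None:
        if self.op.startswith("script:"):
            fn = self.op[len("script:"):]
            if fn not in functions:
                raise ExpressionError(
                    f"post-annotation {self.name!r}: unknown script "
                    f"function {fn!r}")
            self._code = functions[fn]
        else:
            self._code = compile_expression(self.op, self.fields, functions)


def _coerce_info_value(raw: Any) -> Any:
    """Raw INFO string -> scalar or list of scalars for expression use."""
    if not isinstance(raw, str):
        return raw
    if "," in raw:
        parts = raw.split(",")
        out = []
        for p in parts:
            try:
                out.append(int(p))
            except ValueError:
                try:
                    out.append(float(p))
                except ValueError:
                    out.append(p)
        return out
    try:
        return int(raw)
    except ValueError:
        try:
            return float(raw)
        except ValueError:
            return raw


def _coerce_output(value: Any, value_type: str) -> Any:
    if value is None:
        return None
    if value_type == "Flag":
        return True if value else None
    if value_type == "Integer":
        return int(value)
    if value_type == "Float":
        return float(value)
    if value_type == "String":
        return value if isinstance(value, str) else str(value)
    return value


def evaluate_post(spec: PostAnnotationSpec, info: dict[str, Any],
                  functions: dict[str, Callable], *,
                  where: str = "?") -> Any:
    """Evaluate one block against the current INFO map.

    Returns the typed value, or None (key absent) when an input field is
    missing or the expression raises; expression failures warn once per
    record with coordinates.
    """
    if spec._code is None:
        spec.compile(functions)
    env = {}
    for f in spec.fields:
        if f not in info:
            return None
        env[f] = _coerce_info_value(info[f])
    try:
        if callable(spec._code):  # script:<fn>, fields passed positionally
            value = spec._code(*(env[f] for f in spec.fields))
        else:
            value = eval(spec._code, {"__builtins__": {}, **functions}, env)
        return _coerce_output(value, spec.value_type)
    except Exception as exc:
        log.warning("post-annotation %r failed at %s: %s",
                    spec.name, where, exc)
        return None
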