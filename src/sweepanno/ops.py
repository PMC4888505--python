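"""Summary operations: from raw overlap values to final INFO values.

For VCF annotation sources the overlap set is first filtered allele-aware
(position, REF and ALT must match, symbolic alleles excepted); the
configured operation then reduces the remaining value multiset to one
INFO value.  With a single overlapping record every operation except
``count`` and ``flag`` returns the raw value unchanged, so the choice of
operation only matters when a query intersects multiple database
intervals.

Built-in vocabulary
-------------------
``self``    the value itself (multiple values: comma-joined like concat)
``first``   first value in bundle order
``concat``  comma-separated list in bundle order
``uniq``    de-duplicated, first occurrence preserved
``count``   number of values (Integer)
``min/max/mean/sum``  numeric reductions; non-coercible values are
            skipped with a warning, never a crash
``flag``    presence marker (VCF Flag)
``script:<name>``  user function from the --script file, called with the
            value list
"""

from __future__ import annotations

import logging
from typing import Any, Callable, Sequence

from .core import AnnotationBundle, AnnotationSourceSpec, QueryRecord
from .io import MISSING, AnnoRecord, coerce_scalar

log = logging.getLogger("sweepanno")

__all__ = ["BUILTIN_OPS", "allele_match", "summarize", "build_bundles",
           "annotate_record", "validate_op"]

BUILTIN_OPS = frozenset(
    {"self", "first", "concat", "uniq", "count", "min", "max", "mean",
     "sum", "flag"})

#: ops for which a singleton bundle passes through unchanged
_IDENTITY_ON_SINGLETON = BUILTIN_OPS - {"count", "flag"}


def validate_op(op: str, script_env: dict[str, Callable] | None = None) -> None:
    if op in BUILTIN_OPS:
        return
    if op.startswith("script:"):
        fn = op[len("script:"):]
        if script_env is None or fn not in script_env:
            raise ValueError(f"operation {op!r} references unknown script "
                             f"function {fn!r}")
        return
    raise ValueError(f"unknown operation {op!r}")


def allele_match(q: QueryRecord, db: AnnoRecord) -> bool:
    """Position/REF/ALT matching between a query and a database VCF record.

    True iff the records share the start position and REF, and the
    database ALT set intersects the query's (an undecomposed multi-ALT
    database record matches if any of its alleles does).  Records
    carrying symbolic alleles on either side skip allele comparison —
    REF/ALT string equality is meaningless for them, so interval
    intersection alone governs.  Non-VCF sources never reach this check.
    """
    if db.ref is None:
        return True
    if q.has_symbolic_alt or db.has_symbolic_alt:
        return True
    if q.interval.start != db.start or q.ref != db.ref:
        return False
    return bool(set(q.alts) & set(db.alts or ()))


def _numeric(values: Sequence[Any], op: str, where: str) -> list:
    nums = []
    for v in values:
        c = coerce_scalar(v)
        if isinstance(c, bool) or not isinstance(c, (int, float)):
            log.warning("op %r at %s: skipping non-numeric value %r",
                        op, where, v)
            continue
        nums.append(c)
    return nums


def summarize(op: str, values: Sequence[Any], *, emit_empty: bool = False,
              script_env: dict[str, Callable] | None = None,
              where: str = "?") -> Any:
    """Reduce an ordered value list to one INFO value; None means
    "emit no key".

    Empty bundles emit nothing, except ``count`` with ``emit_empty``
    which reports 0.  ``where`` locates warnings (record coordinates).
    """
    if op.startswith("script:"):
        fn = (script_env or {}).get(op[len("script:"):])
        if fn is None:
            raise ValueError(f"unknown script function in op {op!r}")
        if not values:
            return None
        try:
            return fn(list(values))
        except Exception as exc:  # user code: warn, drop key
            log.warning("script op %r failed at %s: %s", op, where, exc)
            return None

    if not values:
        if op == "count" and emit_empty:
            return 0
        return None
    if len(values) == 1 and op in _IDENTITY_ON_SINGLETON:
        return values[0]

    if op == "flag":
        return True
    if op == "count":
        return len(values)
    if op == "first":
        return values[0]
    if op in ("self", "concat"):
        return list(values)
    if op == "uniq":
        seen: list = []
        for v in values:
            if v not in seen:
                seen.append(v)
        return seen
    if op in ("min", "max", "sum", "mean"):
        nums = _numeric(values, op, where)
        if not nums:
            log.warning("op %r at %s: no numeric values, key omitted",
                        op, where)
            return None
        if op == "min":
            return min(nums)
        if op == "max":
            return max(nums)
        if op == "sum":
            return sum(nums)
        return float(sum(nums)) / len(nums)
    raise ValueError(f"unknown operation {op!r}")


def build_bundles(q: QueryRecord, assoc: Sequence, specs:
                  list[AnnotationSourceSpec]) -> AnnotationBundle:
    """Turn a query's associated intervals into per-name value lists.

    Values keep the association order (database start, then file order,
    then file position).  VCF sources are allele-filtered; a record
    lacking a requested field contributes no value for that name.
    """
    bundle = AnnotationBundle()
    by_source: dict[int, list[AnnoRecord]] = {}
    for iv in assoc:
        by_source.setdefault(iv.source_id, []).append(iv.payload)
    for spec in specs:
        recs = by_source.get(spec.source_id, ())
        if spec.format == "VCF":
            recs = [r for r in recs if allele_match(q, r)]
        for idx, name in enumerate(spec.names):
            for rec in recs:
                v = rec.values[idx]
                if v is not MISSING:
                    bundle.add(name, v)
    return bundle


def annotate_record(q: QueryRecord, bundle: AnnotationBundle,
                    specs: list[AnnotationSourceSpec], *,
                    emit_empty: bool = False,
                    script_env: dict[str, Callable] | None = None,
                    ) -> dict[str, Any]:
    """Apply each configured operation; returns output name -> INFO value
    in configuration order (names with empty bundles are absent)."""
    where = f"{q.interval.chrom}:{q.pos}"
    out: dict[str, Any] = {}
    for spec in specs:
        for name, op in zip(spec.names, spec.ops):
            value = summarize(op, bundle.get(name, ()), emit_empty=emit_empty,
                              script_env=script_env, where=where)
            if value is not None:
                out[name] = value
    return out
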