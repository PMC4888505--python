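"""TOML configuration parsing and closed-world validation.

A configuration declares repeated ``[[annotation]]`` blocks (one per
annotation source) and ``[[postannotation]]`` blocks (derived fields)::

    [[annotation]]
    file   = "exac.vcf"
    fields = ["AC", "AN"]
    names  = ["exac_alts", "exac_total"]
    ops    = ["self", "self"]

    [[postannotation]]
    fields = ["exac_alts", "exac_total"]
    name   = "exac_aaf"
    op     = "first(exac_alts) / exac_total"
    type   = "Float"

BED and other column-oriented sources use ``columns = [4, ...]``
(1-based) instead of ``fields``.  ``names`` defaults to the field names
(or ``<stem>_col<N>`` for columns); ``ops`` defaults to ``self``.
Relative annotation paths resolve against the configuration file's
directory.  Everything is validated before any annotation begins: file
existence, block length consistency, operation names, output-name
uniqueness across all blocks, expression syntax, and post-annotation
declaration order.
"""

from __future__ import annotations

import hashlib
import os
import tomllib
from dataclasses import dataclass, field
from typing import Any, Callable

from .core import AnnotationSourceSpec
from .engine import ChunkingParams
from .io import sniff_format
from .ops import validate_op
from .postannotate import (
    ExpressionError,
    PostAnnotationSpec,
    base_function_table,
    load_script,
)

__all__ = ["ConfigError", "RunConfig", "parse_config"]

_ANNOTATION_KEYS = {"file", "format", "fields", "columns", "names", "ops"}
_POST_KEYS = {"fields", "name", "op", "type"}
_VALUE_TYPES = {"Integer", "Float", "String", "Flag"}


class ConfigError(ValueError):
    """Configuration failed validation; the message names the defect."""


@dataclass
class RunConfig:
    """Everything a run needs, validated closed-world."""

    annotations: list[AnnotationSourceSpec] = field(default_factory=list)
    posts: list[PostAnnotationSpec] = field(default_factory=list)
    params: ChunkingParams = field(default_factory=ChunkingParams)
    functions: dict[str, Callable] = field(default_factory=base_function_table)
    query_path: str = "-"
    output_path: str = "-"
    script_path: str | None = None
    config_digest: str = ""
    use_ci: bool = True
    emit_empty: bool = False

    @property
    def in_place(self) -> bool:
        return not self.annotations


def _require_list_of(block: dict, key: str, types, idx: int,
                     block_kind: str) -> None:
    val = block.get(key)
    if val is None:
        return
    if not isinstance(val, list) or not all(isinstance(v, types) for v in val):
        raise ConfigError(f"{block_kind} block {idx}: {key!r} must be a list")


def parse_config(path: str, *, script_path: str | None = None) -> RunConfig:
    """Parse and validate a configuration file into a :class:`RunConfig`."""
    try:
        with open(path, "rb") as fh:
            raw_bytes = fh.read()
        doc = tomllib.loads(raw_bytes.decode())
    except FileNotFoundError:
        raise ConfigError(f"configuration file not found: {path!r}") from None
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"configuration syntax error in {path!r}: {exc}"
                          ) from exc

    unknown_top = set(doc) - {"annotation", "postannotation"}
    if unknown_top:
        raise ConfigError(f"unknown configuration key(s): "
                          f"{', '.join(sorted(unknown_top))}")

    functions = base_function_table()
    if script_path is not None:
        if not os.path.exists(script_path):
            raise ConfigError(f"script file not found: {script_path!r}")
        functions.update(load_script(script_path))

    conf_dir = os.path.dirname(os.path.abspath(path))
    annotations: list[AnnotationSourceSpec] = []
    seen_names: set[str] = set()

    for idx, block in enumerate(doc.get("annotation", []), start=1):
        unknown = set(block) - _ANNOTATION_KEYS
        if unknown:
            raise ConfigError(f"annotation block {idx}: unknown key(s) "
                              f"{', '.join(sorted(unknown))}")
        if "file" not in block:
            raise ConfigError(f"annotation block {idx}: missing 'file'")
        apath = block["file"]
        if not os.path.isabs(apath):
            apath = os.path.join(conf_dir, apath)
        if not os.path.exists(apath):
            raise ConfigError(f"annotation block {idx}: file does not exist: "
                              f"{block['file']!r}")
        _require_list_of(block, "fields", str, idx, "annotation")
        _require_list_of(block, "columns", int, idx, "annotation")
        _require_list_of(block, "names", str, idx, "annotation")
        _require_list_of(block, "ops", str, idx, "annotation")
        fields = block.get("fields")
        columns = block.get("columns")
        if (fields is None) == (columns is None):
            raise ConfigError(f"annotation block {idx}: exactly one of "
                              "'fields'/'columns' is required")
        nkeys = len(fields if fields is not None else columns)
        if nkeys == 0:
            raise ConfigError(f"annotation block {idx}: empty fields/columns")
        try:
            fmt = block.get("format") or sniff_format(apath)
        except ValueError as exc:
            raise ConfigError(f"annotation block {idx}: {exc}") from exc
        fmt = fmt.upper()
        if fmt not in ("VCF", "BED", "GFF", "GTF"):
            raise ConfigError(f"annotation block {idx}: unsupported format "
                              f"{fmt!r}")
        if fmt == "VCF" and fields is None:
            raise ConfigError(f"annotation block {idx}: VCF sources need "
                              "'fields', not 'columns'")
        if fmt == "BED" and columns is None:
            raise ConfigError(f"annotation block {idx}: BED sources need "
                              "'columns', not 'fields'")
        if fields is not None:
            default_names = list(fields)
        else:
            stem = os.path.splitext(os.path.basename(apath))[0]
            default_names = [f"{stem}_col{c}" for c in columns]
        names = block.get("names", default_names)
        ops = block.get("ops", ["self"] * nkeys)
        if not (nkeys == len(names) == len(ops)):
            raise ConfigError(
                f"annotation block {idx} ({block['file']!r}): fields/columns, "
                f"names and ops lengths differ ({nkeys}, {len(names)}, "
                f"{len(ops)})")
        for op in ops:
            try:
                validate_op(op, functions)
            except ValueError as exc:
                raise ConfigError(f"annotation block {idx}: {exc}") from exc
        for name in names:
            if name in seen_names:
                raise ConfigError(f"annotation block {idx}: duplicate output "
                                  f"name {name!r}")
            seen_names.add(name)
        annotations.append(AnnotationSourceSpec(
            path=apath, format=fmt, names=tuple(names), ops=tuple(ops),
            fields=tuple(fields) if fields is not None else None,
            columns=tuple(columns) if columns is not None else None,
            source_id=len(annotations) + 1))

    posts: list[PostAnnotationSpec] = []
    post_names = {b.get("name") for b in doc.get("postannotation", [])}
    produced = set(seen_names)
    for idx, block in enumerate(doc.get("postannotation", []), start=1):
        unknown = set(block) - _POST_KEYS
        if unknown:
            raise ConfigError(f"postannotation block {idx}: unknown key(s) "
                              f"{', '.join(sorted(unknown))}")
        for key in ("name", "op"):
            if key not in block:
                raise ConfigError(f"postannotation block {idx}: missing "
                                  f"{key!r}")
        name = block["name"]
        if name in seen_names:
            raise ConfigError(f"postannotation block {idx}: duplicate output "
                              f"name {name!r}")
        vtype = block.get("type", "Float")
        if vtype not in _VALUE_TYPES:
            raise ConfigError(f"postannotation block {idx}: invalid type "
                              f"{vtype!r}")
        fields_in = tuple(block.get("fields", ()))
        for f in fields_in:
            if f in post_names and f not in produced:
                raise ConfigError(
                    f"postannotation block {idx} ({name!r}) consumes "
                    f"{f!r}, which is declared by a later block")
        spec = PostAnnotationSpec(fields=fields_in, name=name,
                                  op=block["op"], value_type=vtype)
        try:
            spec.compile(functions)
        except ExpressionError as exc:
            raise ConfigError(f"postannotation block {idx}: {exc}") from exc
        seen_names.add(name)
        produced.add(name)
        posts.append(spec)

    digest = hashlib.sha256(raw_bytes).hexdigest()[:12]
    return RunConfig(annotations=annotations, posts=posts,
                     functions=functions, script_path=script_path,
                     config_digest=digest)
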