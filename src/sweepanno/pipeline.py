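"""End-to-end orchestration: query stream -> engine -> summaries -> output.

This is the library-level entry point the CLI wraps.  Given a validated
:class:`~sweepanno.config.RunConfig` it streams the query VCF through the
chunked parallel sweep, applies the configured summary operations and
post-annotation blocks, and writes the annotated VCF with an updated
header.  The output is deterministic: repeated runs on identical inputs
produce identical bytes, and the header provenance line is derived from
the tool version and configuration digest, never from the clock.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass
from typing import Any, Iterator, TextIO

from . import __version__
from .config import RunConfig
from .core import QueryRecord
from .engine import EngineStats, annotate_stream
from .io import (
    OP_VALUE_TYPES,
    HeaderModel,
    _WarnLimiter,
    open_annotation,
    open_query_stream,
    write_vcf,
)
from .ops import annotate_record
from .postannotate import evaluate_post

log = logging.getLogger("sweepanno")

__all__ = ["run", "annotate_records", "build_header", "RunStats"]


@dataclass
class RunStats:
    records_in: int = 0
    records_out: int = 0
    values_added: int = 0
    warnings: int = 0


def build_header(original_lines: list[str], config: RunConfig) -> HeaderModel:
    header = HeaderModel(list(original_lines))
    for spec in config.annotations:
        for name, op in zip(spec.names, spec.ops):
            vtype = OP_VALUE_TYPES.get(op, "String")
            number = "0" if vtype == "Flag" else "."
            header.add_info(
                name, number, vtype,
                f"{op} of {spec.format} source "
                f"{spec.path.rsplit('/', 1)[-1]}")
    for post in config.posts:
        number = "0" if post.value_type == "Flag" else "."
        header.add_info(post.name, number, post.value_type,
                        f"derived: {post.op}")
    header.provenance = (f"##sweepanno=<Version={__version__},"
                         f"ConfigDigest={config.config_digest}>")
    return header


def annotate_records(config: RunConfig, *, stats: EngineStats | None = None,
                     ) -> Iterator[tuple[QueryRecord, dict[str, Any]]]:
    """Yield (query record, summarized new-INFO map) in input order."""
    query = open_query_stream(config.query_path)
    handles = [open_annotation(spec) for spec in config.annotations]
    try:
        for q, bundle in annotate_stream(iter(query), handles,
                                         config.annotations, config.params,
                                         use_ci=config.use_ci, stats=stats):
            summarized = annotate_record(
                q, bundle, config.annotations,
                emit_empty=config.emit_empty, script_env=config.functions)
            if config.posts:
                where = f"{q.interval.chrom}:{q.pos}"
                info_view = dict(q.info)
                info_view.update(summarized)
                for post in config.posts:
                    value = evaluate_post(post, info_view, config.functions,
                                          where=where)
                    if value is not None:
                        summarized[post.name] = value
                        info_view[post.name] = value
            yield q, summarized
    finally:
        query.close()
        for h in handles:
            h.close()


def run(config: RunConfig, out: TextIO | None = None) -> RunStats:
    """Annotate ``config.query_path`` and write the result.

    Returns run statistics (also logged as a summary line).
    """
    close_out = False
    if out is None:
        if config.output_path in ("-", None):
            out = sys.stdout
        else:
            out = open(config.output_path, "w")
            close_out = True

    estats = EngineStats()
    warner = _WarnLimiter()
    rstats = RunStats()
    try:
        query_header = open_query_stream(config.query_path)
        header = build_header(query_header.header_lines, config)
        query_header.close()

        def counted() -> Iterator[tuple[QueryRecord, dict[str, Any]]]:
            for q, summarized in annotate_records(config, stats=estats):
                rstats.values_added += len(summarized)
                yield q, summarized

        rstats.records_out = write_vcf(out, header, counted(), warner=warner)
        rstats.records_in = estats.records_in
        rstats.warnings = sum(warner.counts.values())
        log.info("done: %d records in, %d out, %d values added, %d warnings",
                 rstats.records_in, rstats.records_out, rstats.values_added,
                 rstats.warnings)
        return rstats
    finally:
        if close_out:
            out.close()
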