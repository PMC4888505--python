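"""Reading sorted query and annotation files; writing the annotated VCF.

The query VCF is parsed line-wise and its eight fixed columns are kept
verbatim, so records that receive no annotation round-trip byte-for-byte.
Annotation files are served through :class:`RegionQueryHandle`, which uses
a tabix index when the file is BGZF-compressed and indexed (via pysam) and
otherwise an in-memory per-chromosome sorted store — adequate at desk
scale and exact for region semantics.

INFO string escaping
--------------------
String values written into INFO are percent-encoded so the reserved VCF
characters cannot corrupt the field.  The table is stable:

    ``%`` -> ``%25``   ``;`` -> ``%3B``   ``=`` -> ``%3D``
    ``,`` -> ``%2C``   space -> ``%20``   tab -> ``%09``   newline -> ``%0A``

Commas *joining* list values are inserted after per-element escaping and
are therefore unambiguous.
"""

from __future__ import annotations

import gzip
import logging
import os
import sys
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Any, Iterable, Iterator, Optional, TextIO

from .core import (
    AnnotationSourceSpec,
    GenomicInterval,
    MalformedRecordError,
    QueryRecord,
    normalize_chrom,
    overlaps,
)

log = logging.getLogger("sweepanno")

#: sentinel for "this db record lacks the requested field" — contributes
#: no value to a bundle (never a "." placeholder polluting numeric ops).
MISSING = object()

_ESCAPES = [("%", "%25"), (";", "%3B"), ("=", "%3D"), (",", "%2C"),
            (" ", "%20"), ("\t", "%09"), ("\n", "%0A")]


def escape_info_value(text: str) -> str:
    for raw, enc in _ESCAPES:
        text = text.replace(raw, enc)
    return text


def _open_text(path: str) -> TextIO:
    if path == "-":
        return sys.stdin
    if path.endswith(".gz") or path.endswith(".bgz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# INFO parsing helpers

def parse_info(text: str) -> dict[str, Any]:
    """Parse a VCF INFO column into an ordered key -> raw-string map.

    Flags map to ``True``; values are kept as raw strings (consumers
    coerce at the point of use).  ``.`` yields an empty map.
    """
    info: dict[str, Any] = {}
    if text == "." or text == "":
        return info
    for token in text.split(";"):
        if not token:
            continue
        if "=" in token:
            key, _, val = token.partition("=")
            info[key] = val
        else:
            info[token] = True
    return info


def _parse_ci(raw: str | None) -> Optional[tuple[int, int]]:
    if raw is None or raw is True:
        return None
    try:
        lo, hi = raw.split(",", 1)
        return int(lo), int(hi)
    except (ValueError, AttributeError):
        return None


def coerce_scalar(raw: Any) -> Any:
    """Best-effort numeric coercion of a raw INFO string."""
    if not isinstance(raw, str):
        return raw
    try:
        return int(raw)
    except ValueError:
        try:
            return float(raw)
        except ValueError:
            return raw


# ---------------------------------------------------------------------------
# Query stream

class QueryStream:
    """Ordered stream of :class:`QueryRecord` from a sorted VCF.

    Sortedness is verified online: within each chromosome, POS must be
    non-decreasing, and a chromosome block may not recur.  The query
    file's own chromosome order defines the canonical order for the run —
    annotation files need not match it.
    """

    def __init__(self, path: str):
        self.path = path
        self.header_lines: list[str] = []
        self._fh = _open_text(path)
        self._line_number = 0
        line = self._fh.readline()
        while line.startswith("##"):
            self.header_lines.append(line.rstrip("\n"))
            self._line_number += 1
            line = self._fh.readline()
        if not line.startswith("#CHROM"):
            raise MalformedRecordError(
                "missing #CHROM header line", path, self._line_number + 1)
        self.header_lines.append(line.rstrip("\n"))
        self._line_number += 1

    def __iter__(self) -> Iterator[QueryRecord]:
        seen: set[str] = set()
        cur_chrom: str | None = None
        last_start = -1
        order = 0
        for line in self._fh:
            self._line_number += 1
            line = line.rstrip("\n")
            if not line:
                continue
            rec = parse_query_line(line, order,
                                   path=self.path, line_number=self._line_number)
            chrom = rec.interval.chrom
            if chrom != cur_chrom:
                if chrom in seen:
                    raise MalformedRecordError(
                        f"query VCF unsorted: chromosome {chrom} recurs at "
                        f"POS {rec.pos}", self.path, self._line_number)
                seen.add(chrom)
                cur_chrom = chrom
                last_start = -1
            if rec.interval.start < last_start:
                raise MalformedRecordError(
                    f"query VCF unsorted: {chrom}:{rec.pos} after "
                    f"{chrom}:{last_start + 1}", self.path, self._line_number)
            last_start = rec.interval.start
            yield rec
            order += 1

    def close(self) -> None:
        if self._fh is not sys.stdin:
            self._fh.close()


def parse_query_line(line: str, order: int = 0, *, path: str | None = None,
                     line_number: int | None = None) -> QueryRecord:
    cols = line.split("\t")
    if len(cols) < 8:
        raise MalformedRecordError(
            f"VCF record has {len(cols)} columns (need >= 8)", path, line_number)
    try:
        pos = int(cols[1])
    except ValueError:
        raise MalformedRecordError(
            f"non-integer POS {cols[1]!r}", path, line_number) from None
    chrom = normalize_chrom(cols[0], path=path, line_number=line_number)
    ref = cols[3]
    alts = tuple(cols[4].split(",")) if cols[4] != "." else ()
    info = parse_info(cols[7])
    start = pos - 1
    end = start + len(ref)
    symbolic = any(a.startswith("<") or "[" in a or "]" in a for a in alts)
    if symbolic and "END" in info:
        try:
            end = max(end, int(info["END"]))
        except (TypeError, ValueError):
            pass
    return QueryRecord(
        interval=GenomicInterval(chrom, start, end, source_id=0),
        ref=ref,
        alts=alts,
        id=cols[2],
        qual=cols[5],
        filter=cols[6],
        info=info,
        ci_pos=_parse_ci(info.get("CIPOS")),
        ci_end=_parse_ci(info.get("CIEND")),
        raw_line_order=order,
        raw_fields=tuple(cols),  # all columns, incl. FORMAT/samples
    )


def open_query_stream(path: str) -> QueryStream:
    return QueryStream(path)


# ---------------------------------------------------------------------------
# Annotation record parsing

@dataclass(slots=True)
class AnnoRecord:
    """A parsed annotation record: span + extracted values.

    ``values`` aligns with the source spec's output names; entries may be
    :data:`MISSING`.  ``ref``/``alts`` are set for VCF sources only and
    drive allele-aware matching.
    """

    chrom: str
    start: int
    end: int
    values: tuple
    ref: str | None = None
    alts: tuple[str, ...] | None = None
    file_order: int = 0

    @property
    def has_symbolic_alt(self) -> bool:
        return self.alts is not None and any(
            a.startswith("<") or "[" in a or "]" in a for a in self.alts)


def _parse_gff_attributes(text: str, gtf: bool) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for token in text.strip().split(";"):
        token = token.strip()
        if not token:
            continue
        if not gtf and "=" in token:
            key, _, val = token.partition("=")
        else:
            key, _, val = token.partition(" ")
        attrs[key.strip()] = val.strip().strip('"')
    return attrs


def parse_annotation_record(fmt: str, line: str, spec: AnnotationSourceSpec,
                            file_order: int = 0, *, path: str | None = None,
                            line_number: int | None = None) -> AnnoRecord:
    """Parse one raw annotation line into an :class:`AnnoRecord`.

    Coordinates are converted to the internal 0-based half-open
    convention (VCF/GFF/GTF are 1-based inclusive on disk; BED is
    already half-open).
    """
    cols = line.rstrip("\n").split("\t")
    if fmt == "BED":
        if len(cols) < 3:
            raise MalformedRecordError("BED record needs >= 3 columns",
                                       path, line_number)
        chrom = normalize_chrom(cols[0], path=path, line_number=line_number)
        start, end = int(cols[1]), int(cols[2])
        vals = []
        for col in spec.columns:  # type: ignore[union-attr]
            if col > len(cols):
                raise MalformedRecordError(
                    f"requested column {col} but record has {len(cols)} "
                    "columns", path or spec.path, line_number)
            vals.append(cols[col - 1])
        return AnnoRecord(chrom, start, end, tuple(vals), file_order=file_order)

    if fmt == "VCF":
        if len(cols) < 8:
            raise MalformedRecordError("VCF record needs >= 8 columns",
                                       path, line_number)
        chrom = normalize_chrom(cols[0], path=path, line_number=line_number)
        pos = int(cols[1])
        ref = cols[3]
        alts = tuple(cols[4].split(",")) if cols[4] != "." else ()
        info = parse_info(cols[7])
        start = pos - 1
        end = start + len(ref)
        symbolic = any(a.startswith("<") or "[" in a or "]" in a for a in alts)
        if symbolic and "END" in info:
            try:
                end = max(end, int(info["END"]))
            except (TypeError, ValueError):
                pass
        vals = tuple(info.get(f, MISSING) for f in spec.fields)  # type: ignore[union-attr]
        return AnnoRecord(chrom, start, end, vals, ref=ref, alts=alts,
                          file_order=file_order)

    if fmt in ("GFF", "GTF"):
        if len(cols) < 9:
            raise MalformedRecordError(f"{fmt} record needs 9 columns",
                                       path, line_number)
        chrom = normalize_chrom(cols[0], path=path, line_number=line_number)
        start = int(cols[3]) - 1
        end = int(cols[4])
        attrs = _parse_gff_attributes(cols[8], gtf=(fmt == "GTF"))
        vals = tuple(attrs.get(f, MISSING) for f in spec.fields)  # type: ignore[union-attr]
        return AnnoRecord(chrom, start, end, vals, file_order=file_order)

    raise ValueError(f"unknown annotation format {fmt!r}")


def sniff_format(path: str) -> str:
    base = path[:-3] if path.endswith(".gz") or path.endswith(".bgz") else path
    ext = os.path.splitext(base)[1].lower()
    mapping = {".vcf": "VCF", ".bed": "BED", ".gff": "GFF", ".gff3": "GFF",
               ".gtf": "GTF"}
    if ext not in mapping:
        raise ValueError(f"cannot infer annotation format from {path!r}")
    return mapping[ext]


# ---------------------------------------------------------------------------
# Region-queryable annotation handles

class RegionQueryHandle:
    """Bounded region retrieval against one sorted annotation file.

    Two interchangeable backends satisfy the same contract: a tabix index
    (BGZF-compressed file with ``.tbi``/``.csi`` alongside) or an
    in-memory sorted store built on first open.  ``region_query`` yields
    exactly the annotation intervals overlapping ``[lo, hi)`` sorted by
    start; a chromosome absent from the file yields an empty stream.
    """

    def __init__(self, spec: AnnotationSourceSpec):
        self.spec = spec
        self.source_id = spec.source_id
        self.format = spec.format
        self._tabix = None
        self._contig_map: dict[str, str] = {}
        self._store: dict[str, tuple[list[int], list[int], list[AnnoRecord]]] = {}
        if self._has_index(spec.path):
            self._open_tabix(spec.path)
        else:
            self._load_store(spec.path)

    @staticmethod
    def _has_index(path: str) -> bool:
        if not (path.endswith(".gz") or path.endswith(".bgz")):
            return False
        return os.path.exists(path + ".tbi") or os.path.exists(path + ".csi")

    def _open_tabix(self, path: str) -> None:
        import pysam
        try:
            self._tabix = pysam.TabixFile(path)
        except OSError as exc:
            raise MalformedRecordError(
                f"cannot open tabix index for {path!r}: {exc}; re-run "
                "`tabix -p <preset> <file>` on the sorted BGZF file",
                path) from exc
        for contig in self._tabix.contigs:
            self._contig_map[normalize_chrom(contig)] = contig

    def _load_store(self, path: str) -> None:
        fmt = self.format
        skip = ("#",) if fmt in ("VCF", "GFF", "GTF") else ("#", "track", "browser")
        with _open_text(path) as fh:
            order = 0
            for ln, line in enumerate(fh, start=1):
                stripped = line.rstrip("\n")
                if not stripped or any(stripped.startswith(p) for p in skip):
                    continue
                rec = parse_annotation_record(fmt, stripped, self.spec, order,
                                              path=path, line_number=ln)
                starts, maxends, recs = self._store.setdefault(
                    rec.chrom, ([], [], []))
                if starts and rec.start < starts[-1]:
                    raise MalformedRecordError(
                        f"annotation file unsorted on {rec.chrom}: start "
                        f"{rec.start} after {starts[-1]}", path, ln)
                starts.append(rec.start)
                maxends.append(max(rec.end, maxends[-1]) if maxends else rec.end)
                recs.append(rec)
                order += 1

    def region_query(self, chrom: str, lo: int, hi: int
                     ) -> Iterator[GenomicInterval]:
        if lo > hi:
            raise ValueError(f"region_query: lo {lo} > hi {hi}")
        if self._tabix is not None:
            yield from self._tabix_query(chrom, lo, hi)
            return
        entry = self._store.get(chrom)
        if entry is None:
            return
        starts, maxends, recs = entry
        probe = GenomicInterval(chrom, lo, hi)
        i = bisect_right(maxends, lo)          # first index whose span can reach lo
        stop = bisect_right(starts, hi)        # zero-length records at hi included
        for idx in range(i, stop):
            rec = recs[idx]
            iv = GenomicInterval(chrom, rec.start, rec.end,
                                 source_id=self.source_id, payload=rec)
            if overlaps(iv, probe):
                yield iv

    def _tabix_query(self, chrom: str, lo: int, hi: int
                     ) -> Iterator[GenomicInterval]:
        contig = self._contig_map.get(chrom)
        if contig is None:
            return
        if lo == hi:
            hi = lo + 1
        for order, line in enumerate(self._tabix.fetch(contig, lo, hi)):
            rec = parse_annotation_record(self.format, line, self.spec, order,
                                          path=self.spec.path)
            yield GenomicInterval(rec.chrom, rec.start, rec.end,
                                  source_id=self.source_id, payload=rec)

    def chroms(self) -> list[str]:
        if self._tabix is not None:
            return list(self._contig_map)
        return list(self._store)

    def close(self) -> None:
        if self._tabix is not None:
            self._tabix.close()


def open_annotation(spec: AnnotationSourceSpec) -> RegionQueryHandle:
    return RegionQueryHandle(spec)


# ---------------------------------------------------------------------------
# Output

#: value-type inferred from the summary op when writing header lines
OP_VALUE_TYPES = {
    "count": "Integer", "mean": "Float", "max": "Float", "min": "Float",
    "sum": "Float", "flag": "Flag",
}


@dataclass
class HeaderModel:
    """Original header lines plus definitions for every new INFO key."""

    original_lines: list[str]
    new_info: dict[str, tuple[str, str, str]] = field(default_factory=dict)
    provenance: str | None = None

    def add_info(self, key: str, number: str, value_type: str,
                 description: str) -> None:
        if key in self.new_info:
            raise ValueError(f"duplicate INFO definition for {key!r}")
        self.new_info[key] = (number, value_type, description)

    def render(self) -> list[str]:
        lines = list(self.original_lines)
        extra = [
            f'##INFO=<ID={key},Number={num},Type={typ},Description="{desc}">'
            for key, (num, typ, desc) in self.new_info.items()
        ]
        if self.provenance:
            extra.append(self.provenance)
        # insert before the #CHROM line
        return lines[:-1] + extra + lines[-1:]


def format_scalar(value: Any) -> str:
    if value is True:
        return ""
    if isinstance(value, bool):
        return ""
    if isinstance(value, float):
        return format(value, "g")
    if isinstance(value, int):
        return str(value)
    return escape_info_value(str(value))


def format_info_value(value: Any) -> str:
    if isinstance(value, (list, tuple)):
        return ",".join(format_scalar(v) for v in value)
    return format_scalar(value)


class _WarnLimiter:
    """Rate-limits warnings per category: first 10 verbatim, then a count."""

    def __init__(self, limit: int = 10):
        self.limit = limit
        self.counts: dict[str, int] = {}

    def warn(self, category: str, message: str) -> None:
        n = self.counts.get(category, 0) + 1
        self.counts[category] = n
        if n <= self.limit:
            log.warning(message)
        elif n == self.limit + 1:
            log.warning("further '%s' warnings suppressed", category)


def write_annotated(record: QueryRecord, summarized: dict[str, Any],
                    header: HeaderModel, *, collision_suffix: str = "_2",
                    warner: _WarnLimiter | None = None) -> str:
    """Assemble the output VCF line for one query record.

    The eight fixed columns, including the pre-existing INFO string, are
    emitted verbatim; new keys are appended in configuration order.  A
    new key colliding with a pre-existing INFO key is emitted under
    ``key + collision_suffix`` with a warning — never a silent overwrite.
    """
    cols = list(record.raw_fields)
    if summarized:
        existing = record.info
        parts = [] if cols[7] == "." else [cols[7]]
        for key, value in summarized.items():
            out_key = key
            if key in existing:
                out_key = key + collision_suffix
                msg = (f"INFO key {key!r} already present at "
                       f"{record.interval.chrom}:{record.pos}; writing "
                       f"{out_key!r}")
                if warner is not None:
                    warner.warn("info-collision", msg)
                else:
                    log.warning(msg)
            if value is True:
                parts.append(out_key)
            else:
                parts.append(f"{out_key}={format_info_value(value)}")
        cols[7] = ";".join(parts) if parts else "."
    return "\t".join(cols)


def write_vcf(out: TextIO, header: HeaderModel,
              annotated: Iterable[tuple[QueryRecord, dict[str, Any]]],
              *, warner: _WarnLimiter | None = None) -> int:
    """Write header + annotated records; returns the record count."""
    for line in header.render():
        out.write(line + "\n")
    n = 0
    for record, summarized in annotated:
        out.write(write_annotated(record, summarized, header, warner=warner) + "\n")
        n += 1
    return n
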