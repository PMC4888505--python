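"""Core domain types and coordinate conventions.

All coordinates are 0-based half-open internally: an interval covers
``[start, end)``.  VCF and GFF/GTF positions (1-based, end-inclusive on
disk) are converted at parse time in :mod:`sweepanno.io`; BED is already
half-open.  Chromosome labels are normalized by stripping a leading
``chr`` prefix (case-insensitive) so that files using ``chr1`` and ``1``
dialects interoperate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

__all__ = [
    "GenomicInterval",
    "QueryRecord",
    "AnnotationSourceSpec",
    "AnnotationBundle",
    "Chunk",
    "MalformedRecordError",
    "normalize_chrom",
    "overlaps",
    "effective_interval",
]


class MalformedRecordError(ValueError):
    """A record in an input file violates the format or sort contract."""

    def __init__(self, message: str, path: str | None = None,
                 line_number: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line_number}" if line_number else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line_number = line_number


@dataclass(slots=True)
class GenomicInterval:
    """A normalized-chromosome, 0-based half-open genomic span.

    ``source_id`` identifies the originating file (0 is reserved for the
    query stream); ``payload`` carries an opaque reference to the parsed
    record (a :class:`QueryRecord`, or a parsed annotation record).
    """

    chrom: str
    start: int
    end: int
    source_id: int = 0
    payload: Any = None

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def is_zero_length(self) -> bool:
        return self.start == self.end


@dataclass(slots=True)
class QueryRecord:
    """One query VCF record plus its parsed alleles and INFO map.

    The eight fixed VCF columns are retained verbatim in ``raw_fields``
    so un-annotated records round-trip byte-for-byte.  ``ci_pos`` /
    ``ci_end`` hold (negative_offset, positive_offset) breakpoint
    confidence pairs from CIPOS/CIEND when present.
    """

    interval: GenomicInterval
    ref: str
    alts: tuple[str, ...]
    id: str = "."
    qual: str = "."
    filter: str = "."
    info: dict[str, Any] = field(default_factory=dict)
    ci_pos: Optional[tuple[int, int]] = None
    ci_end: Optional[tuple[int, int]] = None
    raw_line_order: int = 0
    raw_fields: tuple[str, ...] = ()

    @property
    def pos(self) -> int:
        """1-based POS as printed in the VCF."""
        return self.interval.start + 1

    @property
    def has_symbolic_alt(self) -> bool:
        return any(a.startswith("<") or "[" in a or "]" in a for a in self.alts)


@dataclass(slots=True)
class AnnotationSourceSpec:
    """One configured annotation source.

    Exactly one of ``fields`` (VCF/GFF/GTF attribute keys) or ``columns``
    (1-based column indices, BED/tab-delimited) is set; ``names`` gives
    the output INFO keys and ``ops`` the summary operation per name.
    """

    path: str
    format: str  # one of VCF, BED, GFF, GTF
    names: tuple[str, ...]
    ops: tuple[str, ...]
    fields: tuple[str, ...] | None = None
    columns: tuple[int, ...] | None = None
    source_id: int = 0

    def __post_init__(self) -> None:
        if (self.fields is None) == (self.columns is None):
            raise ValueError(
                f"annotation source {self.path!r}: exactly one of "
                "fields/columns must be given"
            )
        keys = self.fields if self.fields is not None else self.columns
        if not (len(keys) == len(self.names) == len(self.ops)):
            raise ValueError(
                f"annotation source {self.path!r}: fields/columns, names and "
                f"ops must have equal length (got {len(keys)}, "
                f"{len(self.names)}, {len(self.ops)})"
            )

    @property
    def keys(self) -> Sequence:
        return self.fields if self.fields is not None else self.columns


class AnnotationBundle(dict):
    """Per query record: output name -> ordered list of raw values.

    Values are ordered by database-interval start, ties broken by file
    order then file position — exactly the order the sweep associates
    intervals in.
    """

    def add(self, name: str, value: Any) -> None:
        self.setdefault(name, []).append(value)


@dataclass(slots=True)
class Chunk:
    """A bounded run of consecutive query records: one unit of parallel work.

    ``lo``/``hi`` cover the *effective* (confidence-interval expanded)
    spans of all member queries, so structural-variant breakpoint ranges
    never extend past the region requested from annotation files.
    """

    queries: list[QueryRecord]
    chrom: str
    lo: int
    hi: int
    sequence_id: int

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(f"chunk {self.sequence_id}: lo {self.lo} > hi {self.hi}")


def normalize_chrom(label: str, *, path: str | None = None,
                    line_number: int | None = None) -> str:
    """Strip a leading ``chr`` prefix (case-insensitive) from a chromosome label.

    Idempotent; no other aliasing is applied (``MT`` and ``M`` remain
    distinct).  An empty label is a malformed record.
    """
    if not label:
        raise MalformedRecordError("empty chromosome label", path, line_number)
    if label[:3].lower() == "chr":
        return label[3:]
    return label


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Half-open interval overlap on one chromosome.

    ``[a.start, a.end)`` and ``[b.start, b.end)`` overlap iff
    ``a.start < b.end and b.start < a.end``.  Zero-length intervals
    (``start == end``, e.g. some insertion representations) use an
    inclusive-point rule: point ``p`` hits ``[s, e)`` iff ``s < p <= e``,
    so insertions remain annotatable by intervals they abut on the left.
    Callers pre-filter by chromosome; differing chromosomes are a
    contract violation.
    """
    if a.chrom != b.chrom:
        raise ValueError(f"overlaps() across chromosomes: {a.chrom} vs {b.chrom}")
    if a.start == a.end:
        return b.start < a.start <= b.end
    if b.start == b.end:
        return a.start < b.start <= a.end
    return a.start < b.end and b.start < a.end


def effective_interval(q: QueryRecord, *, use_ci: bool = True) -> GenomicInterval:
    """The query span expanded by breakpoint confidence intervals.

    Only the outward offsets widen the span: the negative side of CIPOS
    moves the start left, the positive side of CIEND moves the end right
    (clamped at zero).  Absent attributes mean no expansion; with
    ``use_ci=False`` the raw interval is returned unchanged.
    """
    iv = q.interval
    if not use_ci or (q.ci_pos is None and q.ci_end is None):
        return iv
    start = iv.start
    end = iv.end
    if q.ci_pos is not None:
        start = max(0, start + min(q.ci_pos[0], 0))
    if q.ci_end is not None:
        end = end + max(q.ci_end[1], 0)
    return GenomicInterval(iv.chrom, start, end, iv.source_id, iv.payload)
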