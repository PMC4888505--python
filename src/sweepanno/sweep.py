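"""Serial streaming intersection: the chrom-sweep.

Sorted interval streams (one query stream, any number of annotation
streams) are merged through a single priority queue ordered by start
coordinate.  A cache holds the intervals live at the sweep frontier.
When a query interval enters the cache it is checked against every
cached annotation interval; every cached interval the frontier has
strictly passed (``end < new query's start``) is ejected, and ejected
*query* intervals are finalized with their accumulated associations.  An
annotation interval entering the cache associates with every cached
query it overlaps.  End-of-stream flushes all remaining queries.

Because all streams are sorted by start, an interval needs comparing
only against the current cache: nothing yet to come — zero-length points
included — can reach back before an ejected interval's end.  Queries are
emitted strictly in input order through a small reorder buffer, since a
long query can sit in the cache while shorter, later ones are ejected
first.

Eviction happens only on query entry and at end-of-stream; annotation
intervals may therefore sit in the cache past their end, which is
harmless because association always re-checks ``overlaps()``.
Duplicate annotation intervals each contribute a value — de-duplication
is the job of the ``uniq`` summary operation, not the sweep.
"""

from __future__ import annotations

import heapq
from typing import Iterable, Iterator

from .core import GenomicInterval, MalformedRecordError, QueryRecord, overlaps

__all__ = ["merge_streams", "sweep", "sweep_chromosome"]


def merge_streams(streams: list[Iterable[GenomicInterval]],
                  chrom_rank: dict[str, int] | None = None,
                  ) -> Iterator[GenomicInterval]:
    """Merge sorted interval streams into one globally sorted stream.

    Ordering is by (chromosome rank, start), ties broken by (source_id,
    within-stream order) so the merge is fully deterministic.  Within a
    chunk all intervals share one chromosome and the rank is trivial.
    A stream violating its own sort order is a fatal error with
    provenance.
    """
    rank = chrom_rank or {}

    def keyed(stream: Iterable[GenomicInterval], stream_idx: int):
        last_key = None
        for n, iv in enumerate(stream):
            key = (rank.get(iv.chrom, 0), iv.start, iv.source_id, n)
            sort_key = key[:2]
            if last_key is not None and sort_key < last_key:
                raise MalformedRecordError(
                    f"stream {stream_idx} (source {iv.source_id}) unsorted at "
                    f"{iv.chrom}:{iv.start}")
            last_key = sort_key
            yield key, iv

    for _, iv in heapq.merge(*(keyed(s, i) for i, s in enumerate(streams)),
                             key=lambda pair: pair[0]):
        yield iv


def sweep(merged: Iterable[GenomicInterval], query_source_id: int = 0,
          ) -> Iterator[tuple[QueryRecord, list[GenomicInterval]]]:
    """Run the chrom-sweep over a merged single-chromosome stream.

    Yields each query exactly once, in input order, paired with the list
    of annotation intervals that overlap it.  Association order follows
    the merged stream (start, then source, then file position), which is
    the bundle order downstream summary operations rely on.
    """
    # cache entries: [interval, assoc-list or None, query-index]; the
    # assoc-list is only kept for queries.  A long query can outlive a
    # later, shorter one in the cache, so finalized queries pass through
    # a reorder buffer and are emitted strictly in entry (= input) order.
    cache: list[list] = []
    n_queries = 0
    next_emit = 0
    done: dict[int, tuple] = {}
    for iv in merged:
        if iv.source_id == query_source_id:
            assoc: list[GenomicInterval] = []
            kept: list[list] = []
            for entry in cache:
                cached_iv, cached_assoc, qidx = entry
                if overlaps(cached_iv, iv):
                    if cached_assoc is None:  # cached annotation interval
                        assoc.append(cached_iv)
                    kept.append(entry)
                elif cached_iv.end < iv.start:
                    # the frontier has strictly passed: nothing yet to come
                    # (all starts >= iv.start, zero-length points included)
                    # can reach back to this end, so ejection is safe
                    if cached_assoc is not None:  # ejected query: finalize
                        done[qidx] = (cached_iv.payload, cached_assoc)
                    # ejected annotation intervals are simply dropped
                else:
                    # non-overlapping only under the zero-length point
                    # rule (e.g. a zero-length query entering at this
                    # start); keep until the frontier truly passes
                    kept.append(entry)
            kept.append([iv, assoc, n_queries])
            n_queries += 1
            cache = kept
            while next_emit in done:
                yield done.pop(next_emit)
                next_emit += 1
        else:
            for entry in cache:
                cached_iv, cached_assoc, _ = entry
                if cached_assoc is not None and overlaps(cached_iv, iv):
                    cached_assoc.append(iv)
            cache.append([iv, None, -1])
    for cached_iv, cached_assoc, qidx in cache:  # end-of-stream flush
        if cached_assoc is not None:
            done[qidx] = (cached_iv.payload, cached_assoc)
    while next_emit in done:
        yield done.pop(next_emit)
        next_emit += 1


def sweep_chromosome(query_intervals: Iterable[GenomicInterval],
                     annotation_streams: list[Iterable[GenomicInterval]],
                     ) -> Iterator[tuple[QueryRecord, list[GenomicInterval]]]:
    """Convenience entry point: merge one chromosome's streams and sweep."""
    merged = merge_streams([query_intervals, *annotation_streams])
    return sweep(merged, query_source_id=0)
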