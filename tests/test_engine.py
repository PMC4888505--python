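import random
import threading
import time
from concurrent.futures import ThreadPoolExecutor

import pytest

from sweepanno.config import parse_config
from sweepanno.core import AnnotationSourceSpec
from sweepanno.engine import (
    ChunkingParams,
    EngineStats,
    annotate_stream,
    define_chunks,
    ordered_gather,
    run_chunk,
    serial_annotate,
)
from sweepanno.io import open_annotation, open_query_stream
from conftest import make_query


def queries_at(starts, chrom="1", length=1):
    return [make_query(chrom, s, s + length, i) for i, s in enumerate(starts)]


class TestDefineChunks:
    def test_chunk_size_threshold(self):
        chunks = list(define_chunks(queries_at([10, 11, 12, 13, 14]),
                                    ChunkingParams(chunk_size=2,
                                                   gap_size=10**9)))
        assert [len(c.queries) for c in chunks] == [2, 2, 1]
        assert [c.sequence_id for c in chunks] == [0, 1, 2]

    def test_gap_size_threshold(self):
        chunks = list(define_chunks(queries_at([100, 200, 50_000]),
                                    ChunkingParams(chunk_size=1000,
                                                   gap_size=20_000)))
        assert [[q.interval.start for q in c.queries] for c in chunks] == \
            [[100, 200], [50_000]]

    def test_chromosome_change_always_splits(self):
        qs = queries_at([5, 6], "1") + [make_query("2", 7, 8, 2)]
        chunks = list(define_chunks(qs, ChunkingParams(chunk_size=10**6,
                                                       gap_size=10**9)))
        assert [c.chrom for c in chunks] == ["1", "2"]

    def test_overlapping_queries_never_split(self):
        # zero/negative end-to-next-start gaps stay in one chunk even at
        # gap_size=0
        qs = queries_at([10, 10, 15], length=20)
        chunks = list(define_chunks(qs, ChunkingParams(chunk_size=100,
                                                       gap_size=0)))
        assert len(chunks) == 1

    def test_partition_property(self, rng):
        starts = sorted(rng.randrange(100_000) for _ in range(200))
        qs = queries_at(starts)
        for cs, gs in [(1, 0), (7, 100), (50, 5000), (1000, 20000)]:
            chunks = list(define_chunks(qs, ChunkingParams(cs, gs, 1)))
            flat = [q for c in chunks for q in c.queries]
            assert flat == qs  # concatenation of chunks == input
            for c in chunks:
                assert len(c.queries) <= cs
                assert c.lo == min(q.interval.start for q in c.queries)
                assert c.hi == max(q.interval.end for q in c.queries)

    def test_ci_expanded_bounds(self):
        q = make_query("1", 1000, 2000, 0, alts=("<DEL>",),
                       ci_pos=(-50, 50), ci_end=(-100, 100))
        (chunk,) = define_chunks([q], ChunkingParams())
        assert (chunk.lo, chunk.hi) == (950, 2100)
        (chunk,) = define_chunks([q], ChunkingParams(), use_ci=False)
        assert (chunk.lo, chunk.hi) == (1000, 2000)


class TestOrderedGather:
    def test_single_chunk_passthrough(self):
        with ThreadPoolExecutor(2) as pool:
            fut = pool.submit(lambda: 42)
            assert list(ordered_gather(iter([fut]), 3)) == [42]

    def test_out_of_order_completion_restored(self):
        # chunks 1,2,3 completing as 3,1,2 still emit as 1,2,3
        events = [threading.Event() for _ in range(3)]

        def job(i):
            events[i].wait(5)
            return i

        with ThreadPoolExecutor(3) as pool:
            futs = [pool.submit(job, i) for i in range(3)]
            for i in (2, 0, 1):
                events[i].set()
                time.sleep(0.01)
            assert list(ordered_gather(iter(futs), 10)) == [0, 1, 2]

    def test_hundred_shuffled_completions(self, rng):
        # randomized scheduler: emission order equals submission order
        def job(i):
            time.sleep(rng.random() * 0.003)
            return i

        with ThreadPoolExecutor(8) as pool:
            futs = (pool.submit(job, i) for i in range(100))
            assert list(ordered_gather(futs, 10)) == list(range(100))

    def test_failed_chunk_aborts_after_earlier_results(self):
        def job(i):
            if i == 2:
                raise RuntimeError("chunk 2 exploded")
            return i

        got = []
        with ThreadPoolExecutor(2) as pool:
            futs = (pool.submit(job, i) for i in range(5))
            with pytest.raises(RuntimeError, match="chunk 2"):
                for r in ordered_gather(futs, 3):
                    got.append(r)
        assert got == [0, 1]


class TestEngineEquivalence:
    def load(self, tmp_path):
        cfg = parse_config(str(tmp_path / "conf.toml"))
        handles = [open_annotation(s) for s in cfg.annotations]
        queries = list(open_query_stream(str(tmp_path / "query.vcf")))
        return cfg, handles, queries

    @staticmethod
    def render(results):
        return [(q.raw_line_order, sorted((k, list(map(str, v)))
                                          for k, v in b.items()))
                for q, b in results]

    def test_chunked_equals_serial_across_grid(self, fixture_dir):
        tmp_path, _ = fixture_dir
        cfg, handles, queries = self.load(tmp_path)
        baseline = self.render(serial_annotate(iter(queries), handles,
                                               cfg.annotations))
        for chunk_size in (1, 2, 7, 1000):
            for gap_size in (0, 10, 20000):
                for procs in (1, 4):
                    params = ChunkingParams(chunk_size, gap_size, procs)
                    got = self.render(annotate_stream(
                        iter(queries), handles, cfg.annotations, params))
                    assert got == baseline, (chunk_size, gap_size, procs)

    def test_annotation_interval_crossing_chunk_boundary(self, tmp_path):
        # a db interval overlapping the query but extending past chunk.hi
        # must still associate (region queries return partial overlaps)
        (tmp_path / "a.bed").write_text("1\t0\t1000000\twide\n")
        spec = AnnotationSourceSpec(path=str(tmp_path / "a.bed"),
                                    format="BED", columns=(4,),
                                    names=("w",), ops=("self",), source_id=1)
        handle = open_annotation(spec)
        qs = queries_at([100, 50_000, 900_000])
        chunks = list(define_chunks(qs, ChunkingParams(chunk_size=1,
                                                       gap_size=0)))
        assert len(chunks) == 3
        for c in chunks:
            ((q, bundle),) = run_chunk(c, [handle], [spec])
            assert bundle == {"w": ["wide"]}

    def test_chromosome_absent_from_one_source(self, tmp_path):
        (tmp_path / "a.bed").write_text("1\t0\t500\tx\n")
        (tmp_path / "b.bed").write_text("2\t0\t500\ty\n")
        specs = [
            AnnotationSourceSpec(path=str(tmp_path / "a.bed"), format="BED",
                                 columns=(4,), names=("xa",), ops=("self",),
                                 source_id=1),
            AnnotationSourceSpec(path=str(tmp_path / "b.bed"), format="BED",
                                 columns=(4,), names=("yb",), ops=("self",),
                                 source_id=2),
        ]
        handles = [open_annotation(s) for s in specs]
        out = list(annotate_stream(iter(queries_at([10], "2")), handles,
                                   specs, ChunkingParams()))
        assert out[0][1] == {"yb": ["y"]}

    def test_memory_bound_on_large_synthetic_run(self, fixture_dir):
        tmp_path, _ = fixture_dir
        cfg, handles, queries = self.load(tmp_path)
        stats = EngineStats()
        params = ChunkingParams(chunk_size=5, gap_size=10**9, procs=4)
        list(annotate_stream(iter(queries), handles, cfg.annotations,
                             params, stats=stats))
        # FIFO keeps at most procs + queue-depth chunks' queries retained
        assert stats.peak_retained_queries <= params.chunk_size * \
            (params.procs + 3)
        assert stats.records_in == stats.records_out == len(queries)
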