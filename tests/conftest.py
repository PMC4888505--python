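import random

import pytest

from sweepanno.core import GenomicInterval, QueryRecord
from sweepanno.fixtures import DensityProfile, make_query_vcf, \
    make_annotation_set


def make_query(chrom, start, end, order=0, ref="A", alts=("G",), **kw):
    """Minimal QueryRecord for engine/sweep-level tests."""
    fields = (chrom, str(start + 1), ".", ref, ",".join(alts), ".", ".", ".")
    return QueryRecord(
        interval=GenomicInterval(chrom, start, end, source_id=0),
        ref=ref, alts=tuple(alts), raw_line_order=order,
        raw_fields=fields, **kw)


def query_iv(chrom, start, end, order=0, **kw):
    q = make_query(chrom, start, end, order, **kw)
    return GenomicInterval(chrom, start, end, source_id=0, payload=q)


def db_iv(chrom, start, end, source_id=1, label=None):
    return GenomicInterval(chrom, start, end, source_id=source_id,
                           payload=label or f"s{source_id}:{start}-{end}")


def brute_force_pairs(query_ivs, db_ivs):
    """All-pairs overlap oracle, independent of the sweep.

    Returns, per query (by list position), the associated db intervals in
    (start, source_id, file order) order — the bundle order contract.
    """
    out = []
    for q in query_ivs:
        hits = []
        for n, d in enumerate(db_ivs):
            if d.chrom != q.chrom:
                continue
            if q.start == q.end:
                hit = d.start < q.start <= d.end
            elif d.start == d.end:
                hit = q.start < d.start <= q.end
            else:
                hit = q.start < d.end and d.start < q.end
            if hit:
                hits.append((d.start, d.source_id, n, d))
        hits.sort(key=lambda h: h[:3])
        out.append([h[3] for h in hits])
    return out


def random_instance(rng, max_intervals=50, max_coord=100, max_files=4):
    """One randomized sweep instance: sorted query + annotation streams."""
    n_q = rng.randint(0, max_intervals)
    n_files = rng.randint(1, max_files)
    queries = []
    for i, start in enumerate(sorted(rng.randrange(max_coord)
                                     for _ in range(n_q))):
        end = start + rng.choice([0, 1, 1, 2, 5, 10, 30])
        queries.append(query_iv("1", start, end, order=i))
    dbs = []
    for src in range(1, n_files + 1):
        n_d = rng.randint(0, max_intervals)
        starts = sorted(rng.randrange(max_coord) for _ in range(n_d))
        dbs.append([db_iv("1", s, s + rng.choice([0, 1, 2, 8, 25]), src)
                    for s in starts])
    return queries, dbs


@pytest.fixture
def fixture_dir(tmp_path):
    """A small ready-made fixture set: query + 3 annotation files + manifest."""
    profile = DensityProfile(n=120, seed=11, chrom_lengths={"1": 200_000,
                                                            "2": 150_000})
    qpath = str(tmp_path / "query.vcf")
    make_query_vcf(profile, qpath)
    manifest = make_annotation_set(str(tmp_path), qpath, profile)
    return tmp_path, manifest


@pytest.fixture
def rng():
    return random.Random(20_260_928)
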