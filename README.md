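# sweepanno

Streaming, chunk-parallel annotation of VCF variants from sorted
VCF/BED/GFF/GTF interval files.

A VCF produced by a variant caller names loci and alleles but says
nothing about them. Interpreting variants — is this allele in a clinical
database, how frequent is it in a reference cohort, does it fall in a
low-complexity region — means aggregating attributes from many
annotation resources into each record's INFO field. `sweepanno` does
this in a single pass over a sorted query VCF against any number of
sorted annotation files, with configuration-driven summary operations,
allele-aware matching for VCF sources, structural-variant breakpoint
confidence intervals, and derived ("post-annotation") fields computed
from already-extracted values.

## How it works

**Chrom-sweep.** All inputs are sorted by chromosome and start, so
intersections can be found by a sort-merge sweep: intervals from the
query and every annotation source merge through one priority queue
ordered by start coordinate; a cache holds the intervals live at the
sweep frontier. A query entering the cache associates with every cached
annotation interval it overlaps (half-open arithmetic:
`a.start < b.end and b.start < a.end`); an annotation interval entering
associates with every cached query. When the frontier strictly passes an
interval's end it is ejected — ejected queries are finalized with their
accumulated associations. One pass, no interval trees, memory
proportional to the local overlap depth.

**Chunked parallelism.** The query stream is cut into chunks of
consecutive records: a chunk closes at `chunk_size` records (default
1000), when the gap to the next record exceeds `gap_size` bases
(default 20000), or at a chromosome change. Each chunk is swept
independently against annotation slices fetched by bounded region
queries (a tabix index when available, otherwise an in-memory sorted
store), and a FIFO of placeholders restores input order on output. Two
consequences worth knowing: annotation files may use any chromosome
*block* order and either `chr1` or `1` labels (labels are normalized,
and region queries make block order irrelevant), and chunking parameters
affect only performance — output bytes are identical for every
`(chunk_size, gap_size, procs)` choice.

**Summary operations.** Per extracted attribute one of
`self, first, concat, uniq, count, min, max, mean, sum, flag`, or
`script:<fn>` calling a user Python function. With a single overlapping
interval every operation except `count`/`flag` returns the raw value
unchanged. VCF sources are matched on position, REF and ALT (symbolic
alleles fall back to interval intersection; for structural variants the
span is first expanded by the outward CIPOS/CIEND offsets).

**Post-annotation.** Derived fields are sandboxed pure expressions over
named INFO keys, e.g. an alternate allele frequency `first(AC) / AN`, or
the built-in `af_conf_lower(k, n)` — the lower bound of the Wilson score
interval

    ( p̂ + z²/2n − z·√(p̂(1−p̂)/n + z²/4n²) ) / (1 + z²/n),   p̂ = k/n

at 95% confidence (z = 1.959964), which tells you whether an observed
frequency is distinguishable from zero.

## Usage

```sh
sweepanno [-p N] [--chunk-size N] [--gap-size N] [--script FILE] \
          [--no-ci] CONFIG QUERY_VCF > annotated.vcf
```

The TOML configuration declares one `[[annotation]]` block per source
and optional `[[postannotation]]` blocks:

```toml
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
```

A configuration with only post-annotation blocks runs "in place",
deriving fields from the query's own INFO. `sweepanno fixtures --out DIR`
emits a ready-to-run synthetic input set (query, annotations,
configuration, and a brute-force ground-truth overlap manifest).

## Worked example

`python examples/post_annotation_in_place.py` generates a small cohort
VCF carrying AC/AN counts and derives the allele frequency plus its
Wilson lower bound in place:

```
POS    AC/AN        aaf      af_lb
136759 536/5008     0.1070   0.0988
249524 734/1000     0.7340   0.7058
633257 117/2504     0.0467   0.0391
```

`aaf` is the point estimate AC/AN; `af_lb` is the 95% lower confidence
bound — always at or below the estimate, and closer to it the larger AN.
The other examples demonstrate multi-source annotation
(`annotate_basic.py`), breakpoint confidence intervals
(`sv_confidence_intervals.py`, where a deletion with
`CIPOS=-150,50;CIEND=-50,300` picks up BED intervals that only its
expanded span `[849,2300)` touches), and byte-identity of output across
the chunking grid (`parallel_determinism.py`).

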