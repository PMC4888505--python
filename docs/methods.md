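# Methods

## Problem and model

`sweepanno` computes, for every record of a position-sorted query VCF,
the set of intervals from N sorted annotation files (VCF, BED, GFF, GTF)
that intersect it, then reduces the attribute values carried by those
intervals to new INFO fields under user-configured summary operations.
The computational core is a sort-merge sweep over interval streams; the
scalability layer cuts the query stream into chunks processed
concurrently and re-ordered on output. Both layers are exact: the
chunked parallel engine is contractually byte-equivalent to the serial
whole-file sweep, and the test suite and acceptance script verify that
equivalence rather than assume it.

## Coordinate and naming conventions

* Internal coordinates are 0-based half-open everywhere. Converters
  live at the parse boundary: VCF and GFF/GTF are 1-based
  end-inclusive on disk (`start = POS - 1`, `end = start + len(REF)`,
  or the `END` INFO key for symbolic alleles); BED is already
  half-open.
* Overlap is `a.start < b.end and b.start < a.end`. Zero-length
  intervals (`start == end`, which can arise in BED representations of
  insertion points) use an inclusive-point rule: point `p` hits
  `[s, e)` iff `s < p ≤ e`. Pure half-open arithmetic would make such
  features unannotatable; the rule is applied consistently in the
  engine, the brute-force oracle, and the region-query backends.
* Chromosome labels are normalized by stripping a leading `chr`
  (case-insensitive). No other aliasing is performed — `MT` and `M`
  remain distinct; collapsing them silently would be a correctness
  hazard, so it is left to upstream renaming.
* Symbolic ALTs (`<DEL>`, breakend notation) set the record's end from
  the `END` INFO key when present. This is a dialect decision of this
  implementation, not something the VCF specification forces.

## The sweep

Streams (the query plus one per annotation source) merge through a
single priority queue keyed by `(start, source_id, within-file order)`,
making the merge fully deterministic under ties. A cache holds intervals
live at the frontier:

* a **query** entering the cache associates with every cached
  annotation interval it overlaps, and ejects every cached interval the
  frontier has strictly passed (`end < entering start`); ejected
  queries are finalized;
* an **annotation interval** entering associates with every cached
  query it overlaps (association is checked in both directions, so
  arrival order under ties cannot change results);
* end-of-stream flushes all remaining queries.

The strict-inequality ejection criterion is what makes ejection safe
under the zero-length point rule: nothing yet to come (all starts ≥ the
entering start, zero-length points included) can reach back to an
ejected end. Because a long query can outlive shorter, later queries in
the cache, finalized queries pass through a small reorder buffer and are
emitted strictly in input order.

Duplicate annotation intervals each contribute a value; collapsing
duplicates is the job of the `uniq` operation, not the sweep. Bundle
order — the order value lists are handed to summary operations — is
database start, then file order, then file position.

## Chunking and parallelism

A chunk closes when it holds `chunk_size` records (default 1000), when
the gap from its rightmost effective end to the next record's effective
start exceeds `gap_size` bases (default 20000), or at a chromosome
change. Gaps are measured end-to-next-start, so overlapping or abutting
queries never split. The defaults follow the observation that
uniformly dense (genome-wide) query sets are governed by the count
threshold while clustered (exome-like) sets are governed by the gap
threshold; both are CLI-exposed (`--chunk-size`, `--gap-size`).

Chunk bounds `[lo, hi)` cover the confidence-interval-expanded spans of
all member queries, so structural-variant breakpoint ranges never cross
a chunk edge unannotated. Each chunk issues one region request per
source bounded by `[lo, hi)`; region queries return partial overlaps, so
annotation intervals extending past chunk bounds still associate. Within
a chunk, effective intervals are re-sorted by start before sweeping
(confidence-interval expansion can perturb the POS order) and results
are returned in raw record order.

Workers are isolated (chunk in, results out) and communicate with the
scheduler only through futures; a FIFO of placeholders yields completed
chunks strictly in submission order with bounded buffering
(`procs + 2` chunks in flight), which also bounds retained memory to
roughly `chunk_size × (procs + 3)` query records. The current scheduler
uses a thread pool: `procs` controls the number of concurrent sweeps and
overlapped I/O, and the ordering contract — the part that matters for
correctness — is identical for any conforming scheduler. The engine
contains no randomness; repeated runs are byte-identical, and the header
provenance line is derived from the tool version and a configuration
digest, never the clock.

Region retrieval is backend-agnostic: a tabix index (via pysam) when the
file is BGZF-compressed with a `.tbi`/`.csi` alongside, otherwise an
in-memory per-chromosome sorted store built on first open. The store
answers `region_query(chrom, lo, hi)` with two bisections (a
running-max-end array finds the leftmost candidate) and an overlap
filter, which keeps the whole-grid equivalence tests fast at desk scale.
A consequence of per-chunk region requests is that annotation files need
not share the query's chromosome order; only within-chromosome
sortedness is required (and verified, fatally, on load).

## Allele matching and summary operations

For VCF annotation sources, an intersecting record contributes values
only if it matches on position (start), REF, and ALT — the database
record's ALT set must intersect the query's, so an undecomposed
multi-allelic database record still matches. Exact string equality is
intentional: indel representation is assumed normalized (left-aligned,
decomposed) upstream, as is standard practice; no internal realignment
is attempted. If either side carries a symbolic allele, REF/ALT
comparison is meaningless and interval intersection (CI-expanded)
governs alone. Non-VCF sources match on position only.

Operations reduce the ordered value list per output name: `self`
(value, comma-joined if several), `first`, `concat`, `uniq` (first
occurrence kept), `count`, `min`/`max`/`mean`/`sum` (numeric coercion;
non-coercible values are skipped with a rate-limited warning, never a
crash; an entirely non-numeric bundle omits the key), `flag` (presence
marker), and `script:<fn>` (user Python function receiving the value
list). Empty bundles emit no key, except `count` with `--emit-empty`
which reports 0. With a singleton bundle every operation except
`count`/`flag` returns the raw value unchanged — string formatting
included — so operation choice only matters under multiple overlaps.

`mean` always yields a float; `min`/`max`/`sum` preserve integerness
when all inputs coerce to int. Floats are printed with `%g`
(≤ 6 significant digits); values passed through `self`/`first`/
`concat`/`uniq` keep their original spelling.

## INFO writing and escaping

The eight fixed columns plus any FORMAT/sample columns are emitted
verbatim; new keys are appended to INFO in configuration order. A new
key colliding with a pre-existing INFO key is written under
`<key>_2` with a warning — never a silent overwrite. Header `##INFO`
lines are added for every output name with Number `.` (unknown arity;
`0` for flags) and Type inferred from the operation (`count` → Integer;
`min`/`max`/`mean`/`sum` → Float; `flag` → Flag; all else String, the
safe choice given that extracted attributes are strings of unknown
type).

String values are percent-encoded with a fixed, version-stable table
(`%`→`%25` first, then `;`→`%3B`, `=`→`%3D`, `,`→`%2C`, space→`%20`,
tab→`%09`, newline→`%0A`). The VCF specification is ambiguous about `=`
inside values; encoding it is this package's dialect choice. Commas
joining list values are inserted after per-element escaping and are
therefore unambiguous.

## Post-annotation

Post-annotation blocks compute derived INFO fields from named inputs
(earlier annotation outputs, earlier post-annotation outputs, or the
query's own INFO), evaluated in declaration order so later blocks see
earlier outputs; a block consuming a key that a *later* block declares
fails validation. Expressions are a whitelisted subset of Python
expression syntax — arithmetic, comparisons, boolean logic, conditional
expressions, 0-based indexing, and calls to a fixed function table —
validated by AST inspection at configuration time and evaluated with no
builtins, so they cannot perform I/O or mutate other keys. If any
referenced field is absent from a record the output key is simply
absent. Multi-valued INFO strings (`"10,3"`) surface as lists; `first()`
takes the first element of a list and passes scalars through, which is
how "the count for the first alternate allele" is expressed regardless
of whether the source was decomposed.

User functions come from an ordinary Python file passed via `--script`,
loaded once at configuration time; its top-level callables become
`script:<name>` operations and expression-callable functions. The script
itself is trusted user code (it is the analogue of handing the tool a
scripting file); the sandbox applies to configuration expressions, which
may come from less-trusted configuration files.

`af_conf_lower(k, n, confidence=0.95)` is the lower bound of the Wilson
score interval, computed from the closed form with
`z = Φ⁻¹((1+confidence)/2)` (1.959964 at 95%). The choice of Wilson — as
opposed to Wald or Clopper–Pearson — is this package's standardization:
it is well-behaved at the extremes (`k=0` gives exactly 0; `k=n` gives
`1/(1+z²/n) < 1`), monotone in `k`, and never exceeds the point
estimate. `n = 0` yields no value. The normal quantile comes from
`statistics.NormalDist`, and a test pins the implementation to an
independently transcribed algebraic form of the same interval at 1e-9.

## Synthetic data

The fixture generator is deterministic (byte-identical files for equal
profile and seed) and emulates coordinate structure only. Two density
modes mirror the two regimes that matter for chunking behaviour:
`uniform` scatters variants across the chromosomes (genome-wide calling)
and `clustered` confines them to a few narrow windows (exome-like
capture; default 5 windows of 5 kb). Default mix per query set: 10%
symbolic deletions of 0.5–5 kb carrying CIPOS/CIEND offsets drawn from
0–200 bp (the scale SV callers typically report), 20% short indels,
the rest SNVs; every record carries AC/AN with AN drawn from
{1000, 2504, 5008} (diploid cohort sizes of familiar reference panels)
so in-place pipelines have inputs. Annotation sets comprise a BED with a
numeric score, a VCF with AF in which half the records copy query
(POS, REF, ALT) so allele matching has positives, and a GFF with a
`score` attribute; generators can toggle `chr` prefixes and permute
chromosome block order to exercise dialect robustness.

The ground-truth manifest is computed by an exhaustive all-pairs scan
that restates overlap, interval expansion and allele matching locally,
sharing no code with the sweep engine — agreement between the two is
therefore evidence, not tautology. A third, independently written check
in the test suite validates the manifest itself. What passing these
tests does *not* show: behaviour on real allele-frequency spectra, LD
structure, pathological VCF dialects beyond those generated, or
wall-clock performance on genome-scale inputs.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale by design:
1000 randomized sweep instances of ≤ 50 intervals over 1–4 sources for
oracle equivalence; 10 000 query records × 3 annotation sources for the
chunking/parallelism grid (byte-identity across
`chunk_size ∈ {1,7,1000} × gap_size ∈ {0,20000} × procs ∈ {1,4}`);
400 records × 4 chromosomes for dialect robustness; 300 records for the
derived-frequency pipeline. These sizes exercise every boundary
(chunk-of-one, zero gap, chromosome transitions, empty sources) while
keeping the default runs fast; the invariants they check are
size-independent.

Other conventions: ties in the merge are broken by source then file
position; `uniq` compares values as strings; expression indexing is
0-based (documented, tested on first-element semantics rather than any
particular index spelling); validation is closed-world before any
annotation begins (files exist, lengths agree, output names unique,
expressions compile); warnings are rate-limited per category (first 10,
then a count).

## Known limitations

* Attributes declared `Number=A` in database VCFs are surfaced as whole
  field strings; per-allele-index selection for multi-allelic queries is
  not attempted (inputs are assumed decomposed).
* No sequence-aware allele normalization: indels must be left-aligned
  and decomposed upstream for exact-string matching to be meaningful.
* BAM pileup annotation sources are out of scope; the region-query
  handle is the natural extension point for such a backend.
* Genotype/FORMAT-aware annotation and record rewriting (CHROM/POS/ALT
  changes) are out of scope.
* Thread-based workers mean `procs` chiefly overlaps parsing and I/O;
  CPU-bound scaling is modest in pure Python. The parameter's
  correctness contract (identical output for any value) is what the
  package guarantees and tests.
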