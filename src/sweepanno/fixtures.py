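"""Deterministic synthetic inputs: sorted query VCFs, annotation files,
and a brute-force ground-truth overlap manifest.

Every generator is a pure function of its profile and seed, so identical
inputs produce byte-identical files.  Two density modes emulate common
study designs: ``uniform`` spreads variants genome-wide (whole-genome
calling), ``clustered`` concentrates them in a few narrow windows
(exome-like capture).  Queries mix SNVs, indels and symbolic structural
variants carrying CIPOS/CIEND breakpoint confidence intervals, and every
record carries AC/AN allele counts so derived-field pipelines are
exercisable.  The generators emulate coordinate structure only — allele
frequencies, LD and functional annotation content are not realistic.

The overlap manifest is the independent oracle: it is computed by a
brute-force all-pairs scan with its *own* overlap, interval-expansion and
allele-match arithmetic, deliberately sharing no code with the sweep
engine so that agreement between the two is meaningful evidence.
"""

from __future__ import annotations

import json
import os
import random
from dataclasses import dataclass, field
from typing import Any

__all__ = ["DensityProfile", "make_query_vcf", "make_annotation_set",
           "write_fixture_dir"]

_BASES = "ACGT"

_QUERY_HEADER = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=AC,Number=A,Type=Integer,Description="Alternate allele count">',
    '##INFO=<ID=AN,Number=1,Type=Integer,Description="Total allele number">',
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">',
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">',
    '##INFO=<ID=CIPOS,Number=2,Type=Integer,Description="CI around POS">',
    '##INFO=<ID=CIEND,Number=2,Type=Integer,Description="CI around END">',
]


@dataclass(slots=True)
class DensityProfile:
    """Controls where and how many variants/intervals are generated."""

    mode: str = "uniform"  # "uniform" (genome-like) or "clustered" (exome-like)
    n: int = 100
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"1": 1_000_000, "2": 800_000})
    cluster_count: int = 5
    cluster_width: int = 5_000
    seed: int = 0
    sv_fraction: float = 0.1
    indel_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.mode not in ("uniform", "clustered"):
            raise ValueError(f"unknown density mode {self.mode!r}")
        if self.n < 0:
            raise ValueError("n must be >= 0")


def _positions(profile: DensityProfile, rng: random.Random
               ) -> dict[str, list[int]]:
    """Sorted 0-based positions per chromosome, honouring the density mode."""
    total_len = sum(profile.chrom_lengths.values())
    out: dict[str, list[int]] = {}
    remaining = profile.n
    chroms = list(profile.chrom_lengths)
    for i, chrom in enumerate(chroms):
        length = profile.chrom_lengths[chrom]
        if i == len(chroms) - 1:
            k = remaining
        else:
            k = round(profile.n * length / total_len)
            k = min(k, remaining)
        remaining -= k
        if profile.mode == "uniform":
            pos = sorted(rng.randrange(1, max(2, length - 10_000))
                         for _ in range(k))
        else:
            width = profile.cluster_width
            centers = sorted(rng.randrange(width, max(width + 1,
                                                      length - width))
                             for _ in range(profile.cluster_count))
            pos = sorted(
                max(1, rng.choice(centers) + rng.randrange(-width // 2,
                                                           width // 2 + 1))
                for _ in range(k))
        out[chrom] = pos
    return out


def cluster_windows(profile: DensityProfile) -> dict[str, list[tuple[int, int]]]:
    """The clustered mode's windows (for membership checks in tests).

    Re-derives the same centers the generator draws, so positions can be
    verified to fall inside ``center ± cluster_width/2``.
    """
    rng = random.Random(profile.seed)
    out: dict[str, list[tuple[int, int]]] = {}
    # mirror _positions' RNG consumption order exactly
    total_len = sum(profile.chrom_lengths.values())
    remaining = profile.n
    chroms = list(profile.chrom_lengths)
    for i, chrom in enumerate(chroms):
        length = profile.chrom_lengths[chrom]
        k = remaining if i == len(chroms) - 1 else min(
            round(profile.n * length / total_len), remaining)
        remaining -= k
        width = profile.cluster_width
        centers = sorted(rng.randrange(width, max(width + 1, length - width))
                         for _ in range(profile.cluster_count))
        for _ in range(k):
            rng.choice(centers)
            rng.randrange(-width // 2, width // 2 + 1)
        out[chrom] = [(c - width // 2 - 1, c + width // 2 + 1)
                      for c in centers]
    if profile.mode == "uniform":
        return {c: [(0, profile.chrom_lengths[c])] for c in chroms}
    return out


def make_query_vcf(profile: DensityProfile, path: str) -> str:
    """Write a sorted, decomposed, single-ALT query VCF.

    Record mix: symbolic deletions with CIPOS/CIEND at ``sv_fraction``,
    indels at ``indel_fraction``, SNVs otherwise; every record carries
    AC/AN so in-place post-annotation has inputs.
    """
    rng = random.Random(profile.seed)
    positions = _positions(profile, rng)
    lines = list(_QUERY_HEADER)
    lines += [f"##contig=<ID={c},length={l}>"
              for c, l in profile.chrom_lengths.items()]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    counter = 0
    for chrom, pos_list in positions.items():
        for pos in pos_list:
            counter += 1
            an = rng.choice([1000, 2504, 5008])
            ac = rng.randint(0, an)
            draw = rng.random()
            if draw < profile.sv_fraction:
                ref = rng.choice(_BASES)
                end = pos + rng.randint(500, 5000)
                ci = [rng.randint(0, 200) for _ in range(4)]
                info = (f"SVTYPE=DEL;END={end};CIPOS=-{ci[0]},{ci[1]};"
                        f"CIEND=-{ci[2]},{ci[3]};AC={ac};AN={an}")
                alt = "<DEL>"
            elif draw < profile.sv_fraction + profile.indel_fraction:
                ref = "".join(rng.choice(_BASES)
                              for _ in range(rng.randint(2, 5)))
                alt = ref[0]
                info = f"AC={ac};AN={an};DP={rng.randint(5, 200)}"
            else:
                ref = rng.choice(_BASES)
                alt = rng.choice([b for b in _BASES if b != ref])
                info = f"AC={ac};AN={an};DP={rng.randint(5, 200)}"
            lines.append(f"{chrom}\t{pos}\tv{counter}\t{ref}\t{alt}\t"
                         f"{rng.randint(10, 100)}\tPASS\t{info}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Annotation file generators

def _intervals(profile: DensityProfile, rng: random.Random,
               max_len: int = 2000) -> dict[str, list[tuple[int, int]]]:
    positions = _positions(profile, rng)
    return {chrom: [(p, p + rng.randint(1, max_len)) for p in pos_list]
            for chrom, pos_list in positions.items()}


def _chrom_label(chrom: str, chr_prefix: bool) -> str:
    return f"chr{chrom}" if chr_prefix else chrom


def _ordered_chroms(chroms: list[str], permute: bool,
                    rng: random.Random) -> list[str]:
    if not permute:
        return chroms
    shuffled = list(chroms)
    rng.shuffle(shuffled)
    return shuffled


def make_annotation_bed(profile: DensityProfile, path: str, *,
                        chr_prefix: bool = False,
                        permute_chroms: bool = False) -> list[dict]:
    """BED4 with a numeric score in column 4; returns parsed records."""
    rng = random.Random(profile.seed + 101)
    ivs = _intervals(profile, rng)
    records = []
    for chrom, pairs in ivs.items():
        for start, end in pairs:
            records.append({"chrom": chrom, "start": start, "end": end,
                            "value": f"{rng.uniform(0, 1):.4f}"})
    order = _ordered_chroms(list(ivs), permute_chroms, rng)
    with open(path, "w") as fh:
        for chrom in order:
            for r in records:
                if r["chrom"] == chrom:
                    fh.write(f"{_chrom_label(chrom, chr_prefix)}\t"
                             f"{r['start']}\t{r['end']}\t{r['value']}\n")
    return records


def make_annotation_vcf(profile: DensityProfile, path: str,
                        query_records: list[dict], *,
                        match_fraction: float = 0.5,
                        chr_prefix: bool = False,
                        permute_chroms: bool = False) -> list[dict]:
    """VCF with an AF INFO field; a fraction of records copy query
    (pos, REF, ALT) so allele-aware matching has positives."""
    rng = random.Random(profile.seed + 202)
    records = []
    n_match = int(min(len(query_records), profile.n) * match_fraction)
    snv_queries = [q for q in query_records if not q["alt"].startswith("<")]
    matched = rng.sample(snv_queries, min(n_match, len(snv_queries)))
    for q in matched:
        records.append({"chrom": q["chrom"], "pos": q["pos"], "ref": q["ref"],
                        "alt": q["alt"], "af": f"{rng.uniform(0, 0.5):.4f}"})
    positions = _positions(profile, rng)
    for chrom, pos_list in positions.items():
        for pos in pos_list:
            ref = rng.choice(_BASES)
            alt = rng.choice([b for b in _BASES if b != ref])
            records.append({"chrom": chrom, "pos": pos + 1, "ref": ref,
                            "alt": alt, "af": f"{rng.uniform(0, 0.5):.4f}"})
    records.sort(key=lambda r: (r["chrom"], r["pos"]))
    chroms = sorted({r["chrom"] for r in records})
    order = _ordered_chroms(chroms, permute_chroms, rng)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,'
                 'Description="Allele frequency">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom in order:
            for r in records:
                if r["chrom"] == chrom:
                    fh.write(f"{_chrom_label(chrom, chr_prefix)}\t{r['pos']}"
                             f"\t.\t{r['ref']}\t{r['alt']}\t.\t.\t"
                             f"AF={r['af']}\n")
    return records


def make_annotation_gff(profile: DensityProfile, path: str, *,
                        chr_prefix: bool = False,
                        permute_chroms: bool = False) -> list[dict]:
    """GFF3 features with a ``score`` attribute; returns parsed records."""
    rng = random.Random(profile.seed + 303)
    ivs = _intervals(profile, rng, max_len=5000)
    records = []
    for chrom, pairs in ivs.items():
        for start, end in pairs:
            records.append({"chrom": chrom, "start": start, "end": end,
                            "value": str(rng.randint(1, 100))})
    order = _ordered_chroms(list(ivs), permute_chroms, rng)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in order:
            for r in records:
                if r["chrom"] == chrom:
                    fh.write(f"{_chrom_label(chrom, chr_prefix)}\tsynth\t"
                             f"region\t{r['start'] + 1}\t{r['end']}\t.\t+\t.\t"
                             f"ID=f{r['start']};score={r['value']}\n")
    return records


# ---------------------------------------------------------------------------
# Brute-force ground truth (independent of the sweep engine)

def _bf_overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    # independent re-statement of the half-open + inclusive-point rule
    if a_start == a_end:
        return b_start < a_start <= b_end
    if b_start == b_end:
        return a_start < b_start <= a_end
    return a_start < b_end and b_start < a_end


def _bf_effective(q: dict) -> tuple[int, int]:
    start, end = q["start"], q["end"]
    if q.get("cipos") is not None:
        start = max(0, start + min(q["cipos"][0], 0))
    if q.get("ciend") is not None:
        end = end + max(q["ciend"][1], 0)
    return start, end


def _bf_allele_match(q: dict, db: dict) -> bool:
    if q["alt"].startswith("<"):
        return True
    return (q["start"] == db["pos"] - 1 and q["ref"] == db["ref"]
            and q["alt"] in db["alt"].split(","))


def _parse_query_for_manifest(path: str) -> list[dict]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            info = dict(kv.partition("=")[::2] for kv in cols[7].split(";"))
            pos = int(cols[1])
            start = pos - 1
            end = start + len(cols[3])
            if cols[4].startswith("<") and "END" in info:
                end = max(end, int(info["END"]))

            def ci(key: str):
                if key not in info:
                    return None
                lo, hi = info[key].split(",")
                return int(lo), int(hi)

            out.append({"chrom": cols[0], "pos": pos, "start": start,
                        "end": end, "ref": cols[3], "alt": cols[4],
                        "cipos": ci("CIPOS"), "ciend": ci("CIEND")})
    return out


def build_manifest(query_path: str,
                   sources: list[tuple[str, str, list[dict]]]) -> dict:
    """Brute-force expected associations per query record.

    ``sources`` is a list of (name, format, parsed records).  Association
    order matches bundle order: database start, then source order, then
    file position.
    """
    queries = _parse_query_for_manifest(query_path)
    manifest: dict[str, Any] = {"sources": [s[0] for s in sources],
                                "queries": []}
    # group per chromosome (pure bookkeeping; every same-chromosome pair
    # is still tested exhaustively)
    by_chrom: list[dict[str, list[tuple[int, dict]]]] = []
    for _, _, records in sources:
        grouped: dict[str, list[tuple[int, dict]]] = {}
        for file_order, r in enumerate(records):
            grouped.setdefault(r["chrom"], []).append((file_order, r))
        by_chrom.append(grouped)
    for q in queries:
        lo, hi = _bf_effective(q)
        assoc = []
        for src_idx, (name, fmt, records) in enumerate(sources):
            for file_order, r in by_chrom[src_idx].get(q["chrom"], ()):
                if fmt == "VCF":
                    r_start, r_end = r["pos"] - 1, r["pos"] - 1 + len(r["ref"])
                    value = r["af"]
                else:
                    r_start, r_end = r["start"], r["end"]
                    value = r["value"]
                if not _bf_overlaps(lo, hi, r_start, r_end):
                    continue
                if fmt == "VCF" and not _bf_allele_match(q, r):
                    continue
                assoc.append({"source": src_idx, "start": r_start,
                              "end": r_end, "value": value,
                              "order": file_order})
        assoc.sort(key=lambda a: (a["start"], a["source"], a["order"]))
        manifest["queries"].append({
            "chrom": q["chrom"], "pos": q["pos"], "ref": q["ref"],
            "alt": q["alt"], "associations": assoc})
    return manifest


# ---------------------------------------------------------------------------
# Ready-to-run fixture directories

_CONF_TEMPLATE = """\
[[annotation]]
file = "anno.bed"
columns = [4]
names = ["bed_score"]
ops = ["{bed_op}"]

[[annotation]]
file = "anno.vcf"
fields = ["AF"]
names = ["vcf_af"]
ops = ["self"]

[[annotation]]
file = "anno.gff"
fields = ["score"]
names = ["gff_score"]
ops = ["concat"]
"""


def make_annotation_set(out_dir: str, query_path: str,
                        profile: DensityProfile, *,
                        chr_prefix: bool = False,
                        permute_chroms: bool = False,
                        bed_op: str = "max",
                        with_manifest: bool = True) -> dict | None:
    """Emit BED + VCF + GFF annotation files, a matching configuration,
    and (unless ``with_manifest=False``, for large timing-oriented sets)
    the brute-force manifest; returns the manifest."""
    kw = {"chr_prefix": chr_prefix, "permute_chroms": permute_chroms}
    queries = _parse_query_for_manifest(query_path)
    bed = make_annotation_bed(profile, os.path.join(out_dir, "anno.bed"), **kw)
    vcf = make_annotation_vcf(profile, os.path.join(out_dir, "anno.vcf"),
                              queries, **kw)
    gff = make_annotation_gff(profile, os.path.join(out_dir, "anno.gff"), **kw)
    with open(os.path.join(out_dir, "conf.toml"), "w") as fh:
        fh.write(_CONF_TEMPLATE.format(bed_op=bed_op))
    if not with_manifest:
        return None
    manifest = build_manifest(query_path, [("bed_score", "BED", bed),
                                           ("vcf_af", "VCF", vcf),
                                           ("gff_score", "GFF", gff)])
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def write_fixture_dir(out_dir: str, profile: DensityProfile, *,
                      chr_prefix: bool = False,
                      permute_chroms: bool = False,
                      with_manifest: bool = True) -> str:
    """One call: query.vcf + annotations + conf.toml + manifest.json."""
    os.makedirs(out_dir, exist_ok=True)
    query_path = os.path.join(out_dir, "query.vcf")
    make_query_vcf(profile, query_path)
    make_annotation_set(out_dir, query_path, profile,
                        chr_prefix=chr_prefix, permute_chroms=permute_chroms,
                        with_manifest=with_manifest)
    return out_dir
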