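import logging
import random

import pytest
from hypothesis import given, strategies as st

from sweepanno.core import AnnotationBundle, AnnotationSourceSpec
from sweepanno.io import AnnoRecord
from sweepanno.ops import (
    BUILTIN_OPS,
    allele_match,
    annotate_record,
    summarize,
    validate_op,
)
from conftest import make_query


def db_vcf(pos, ref, alt, values=("x",)):
    """Database VCF record at 1-based pos."""
    return AnnoRecord(chrom="1", start=pos - 1, end=pos - 1 + len(ref),
                      values=tuple(values), ref=ref, alts=tuple(alt.split(",")))


class TestAlleleMatch:
    def test_same_site_same_alleles(self):
        q = make_query("1", 99, 100, ref="A", alts=("G",))
        assert allele_match(q, db_vcf(100, "A", "G"))

    def test_same_site_different_alt(self):
        q = make_query("1", 99, 100, ref="A", alts=("G",))
        assert not allele_match(q, db_vcf(100, "A", "T"))

    def test_undecomposed_db_matches_on_alt_intersection(self):
        q = make_query("1", 99, 100, ref="A", alts=("G",))
        assert allele_match(q, db_vcf(100, "A", "G,T"))

    def test_position_mismatch(self):
        q = make_query("1", 99, 100, ref="A", alts=("G",))
        assert not allele_match(q, db_vcf(101, "A", "G"))

    def test_ref_mismatch(self):
        q = make_query("1", 99, 100, ref="A", alts=("G",))
        assert not allele_match(q, db_vcf(100, "C", "G"))

    def test_symbolic_alleles_bypass_comparison(self):
        q = make_query("1", 99, 2000, ref="A", alts=("<DEL>",))
        assert allele_match(q, db_vcf(100, "C", "T"))
        q2 = make_query("1", 99, 100, ref="A", alts=("G",))
        assert allele_match(q2, db_vcf(100, "C", "<DUP>"))

    def test_non_vcf_records_bypass(self):
        q = make_query("1", 99, 100, ref="A", alts=("G",))
        bed = AnnoRecord(chrom="1", start=0, end=500, values=("7",))
        assert allele_match(q, bed)

    def test_match_implies_positional_overlap(self, rng):
        # allele match can never hold without interval overlap
        from sweepanno.core import GenomicInterval, overlaps
        for _ in range(500):
            qpos = rng.randrange(1, 50)
            dpos = rng.randrange(1, 50)
            ref = rng.choice(["A", "AT", "ATG"])
            q = make_query("1", qpos - 1, qpos - 1 + len(ref), ref=ref,
                           alts=("G",))
            db = db_vcf(dpos, ref, rng.choice(["G", "T"]))
            if allele_match(q, db):
                assert overlaps(q.interval,
                                GenomicInterval("1", db.start, db.end))


class TestSummarize:
    def test_max_picks_largest(self):
        assert summarize("max", ["0.1", "0.30", "0.25"]) == 0.30

    @given(value=st.one_of(
        st.floats(allow_nan=False, allow_infinity=False).map(str),
        st.text(alphabet="abcXYZ_.-", min_size=1, max_size=8)),
        op=st.sampled_from(sorted(BUILTIN_OPS - {"count", "flag"})))
    def test_singleton_identity_for_every_value_op(self, value, op):
        # with one overlap, the choice of operation cannot change the value
        assert summarize(op, [value]) == value

    def test_count_and_flag_are_not_identity(self):
        assert summarize("count", ["0.5"]) == 1
        assert summarize("flag", ["0.5"]) is True

    @pytest.mark.parametrize("op,values,expected", [
        ("concat", ["benign", "pathogenic"], ["benign", "pathogenic"]),
        ("uniq", ["A", "A", "B"], ["A", "B"]),
        ("first", ["a", "b", "c"], "a"),
        ("min", ["3", "1.5", "2"], 1.5),
        ("sum", ["1", "2", "4"], 7),
        ("mean", ["1", "2"], 1.5),
        ("count", ["x", "y", "z"], 3),
    ])
    def test_multi_value_reductions(self, op, values, expected):
        assert summarize(op, values) == expected

    def test_empty_bundle_emits_nothing(self):
        for op in BUILTIN_OPS:
            assert summarize(op, []) is None or op == "count"
        assert summarize("count", []) is None
        assert summarize("count", [], emit_empty=True) == 0

    def test_non_numeric_values_warn_not_crash(self, caplog):
        with caplog.at_level(logging.WARNING, logger="sweepanno"):
            assert summarize("mean", ["1.0", "oops", "3.0"]) == 2.0
            assert summarize("max", ["oops", "nope"]) is None
        assert any("non-numeric" in r.message for r in caplog.records)

    def test_permutation_invariance_of_order_free_ops(self, rng):
        values = [str(rng.randrange(100)) for _ in range(8)]
        shuffled = values[:]
        rng.shuffle(shuffled)
        for op in ("mean", "min", "max", "sum", "count"):
            assert summarize(op, values) == summarize(op, shuffled)
        assert set(summarize("uniq", values)) == set(summarize("uniq", shuffled))
        # concat is covariant with bundle order
        assert summarize("concat", values) == values
        assert summarize("concat", shuffled) == shuffled

    def test_script_op_applies_user_function(self):
        env = {"span": lambda vals: max(float(v) for v in vals)
               - min(float(v) for v in vals)}
        assert summarize("script:span", ["1", "5", "3"],
                         script_env=env) == 4.0
        validate_op("script:span", env)
        with pytest.raises(ValueError, match="unknown"):
            validate_op("script:absent", env)
        with pytest.raises(ValueError, match="unknown operation"):
            validate_op("median", env)


class TestAnnotateRecord:
    def spec(self, **kw):
        defaults = dict(path="c.vcf", format="VCF", fields=("CLNSIG",),
                        names=("clinvar_sig",), ops=("concat",), source_id=1)
        defaults.update(kw)
        return AnnotationSourceSpec(**defaults)

    def test_single_overlap_pipeline(self):
        q = make_query("1", 99, 100)
        bundle = AnnotationBundle()
        bundle.add("clinvar_sig", "pathogenic")
        out = annotate_record(q, bundle, [self.spec()])
        assert out == {"clinvar_sig": "pathogenic"}

    def test_sv_max_over_multiple_bed_scores(self):
        q = make_query("1", 999, 5000, alts=("<DEL>",))
        spec = self.spec(format="BED", fields=None, columns=(4,),
                         names=("sv_score",), ops=("max",))
        bundle = AnnotationBundle()
        for v in ("1", "5", "3"):
            bundle.add("sv_score", v)
        assert annotate_record(q, bundle, [spec]) == {"sv_score": 5}

    def test_no_overlaps_yields_empty_map(self):
        q = make_query("1", 99, 100)
        assert annotate_record(q, AnnotationBundle(), [self.spec()]) == {}

    def test_renaming_is_pure_relabeling(self):
        q = make_query("1", 99, 100)
        bundle = AnnotationBundle()
        bundle.add("exac_aaf", "0.01")
        bundle2 = AnnotationBundle()
        bundle2.add("AF", "0.01")
        renamed = annotate_record(
            q, bundle, [self.spec(fields=("AF",), names=("exac_aaf",),
                                  ops=("self",))])
        plain = annotate_record(
            q, bundle2, [self.spec(fields=("AF",), names=("AF",),
                                   ops=("self",))])
        assert list(renamed.values()) == list(plain.values())

    def test_names_emitted_in_configuration_order(self):
        q = make_query("1", 99, 100)
        specs = [
            self.spec(fields=("B", "A"), names=("b_out", "a_out"),
                      ops=("self", "self")),
            self.spec(path="d.vcf", fields=("Z",), names=("z_out",),
                      ops=("self",), source_id=2),
        ]
        bundle = AnnotationBundle()
        for name in ("z_out", "a_out", "b_out"):
            bundle.add(name, "1")
        out = annotate_record(q, bundle, specs)
        assert list(out) == ["b_out", "a_out", "z_out"]
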