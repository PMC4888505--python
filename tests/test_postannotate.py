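import math
import random
from statistics import NormalDist

import pytest

from sweepanno.postannotate import (
    ExpressionError,
    PostAnnotationSpec,
    base_function_table,
    builtin_af_conf_lower,
    compile_expression,
    evaluate_post,
    load_script,
)

FUNCS = base_function_table()


def wilson_lower_oracle(k, n, conf=0.95):
    """Independent closed-form Wilson lower bound (textbook transcription)."""
    z = NormalDist().inv_cdf((1 + conf) / 2)
    p = k / n
    return max(0.0, (2 * n * p + z * z
                     - z * math.sqrt(z * z + 4 * n * p * (1 - p)))
               / (2 * (n + z * z)))


class TestAfConfLower:
    def test_zero_successes_gives_zero(self):
        assert builtin_af_conf_lower(0, 100) == 0.0

    def test_half_at_n100_is_just_above_forty_percent(self):
        # Wilson closed form with z = 1.959964 places 50/100 near 0.4038
        v = builtin_af_conf_lower(50, 100)
        assert 0.40 < v < 0.50
        assert abs(v - wilson_lower_oracle(50, 100)) < 1e-9

    def test_matches_oracle_on_grid(self):
        for n in (1, 2, 10, 37, 100, 1000, 5008):
            for k in {0, 1, n // 3, n // 2, n - 1, n}:
                got = builtin_af_conf_lower(k, n)
                assert abs(got - wilson_lower_oracle(k, n)) < 1e-9, (k, n)

    def test_monotone_in_alt_count_and_below_point_estimate(self):
        n = 200
        prev = -1.0
        for k in range(0, n + 1, 5):
            v = builtin_af_conf_lower(k, n)
            assert v >= prev
            assert v <= k / n + 1e-12
            prev = v

    def test_all_successes_asymptotics(self):
        # at k = n the Wilson lower bound is exactly 1 / (1 + z^2/n),
        # i.e. about 1 - z^2/n for large n — strictly below 1
        n = 100_000
        z = NormalDist().inv_cdf(0.975)
        v = builtin_af_conf_lower(n, n)
        assert 1 - 2 * z * z / n < v < 1.0
        assert abs(v - 1 / (1 + z * z / n)) < 1e-12

    def test_zero_total_yields_absent(self):
        assert builtin_af_conf_lower(5, 0) is None


class TestEvaluatePost:
    def aaf_spec(self):
        return PostAnnotationSpec(
            fields=("exac_alts", "exac_total"), name="exac_aaf",
            op="first(exac_alts) / exac_total", value_type="Float")

    def test_alt_over_total(self):
        v = evaluate_post(self.aaf_spec(), {"exac_alts": "10",
                                            "exac_total": "100"}, FUNCS)
        assert v == pytest.approx(0.1)

    def test_first_element_of_multi_valued_field(self):
        v = evaluate_post(self.aaf_spec(), {"exac_alts": "10,3",
                                            "exac_total": "100"}, FUNCS)
        assert v == pytest.approx(0.1)

    def test_zero_numerator(self):
        v = evaluate_post(self.aaf_spec(), {"exac_alts": "0",
                                            "exac_total": "100"}, FUNCS)
        assert v == 0.0

    def test_absent_input_gives_absent_output_no_error(self):
        assert evaluate_post(self.aaf_spec(), {"exac_alts": "10"}, FUNCS) is None

    def test_runtime_error_warns_and_drops_key(self, caplog):
        spec = PostAnnotationSpec(fields=("a",), name="bad", op="a / 0")
        with caplog.at_level("WARNING", logger="sweepanno"):
            assert evaluate_post(spec, {"a": "1"}, FUNCS) is None
        assert any("bad" in r.message for r in caplog.records)

    def test_type_coercion(self):
        spec = PostAnnotationSpec(fields=("x",), name="n", op="x * 2",
                                  value_type="Integer")
        assert evaluate_post(spec, {"x": "3"}, FUNCS) == 6
        flag = PostAnnotationSpec(fields=("x",), name="common", op="x > 0.05",
                                  value_type="Flag")
        assert evaluate_post(flag, {"x": "0.2"}, FUNCS) is True
        assert evaluate_post(flag, {"x": "0.001"}, FUNCS) is None

    def test_script_function_called_with_fields(self, tmp_path):
        script = tmp_path / "fn.py"
        script.write_text(
            "def af_ratio(ac, an):\n"
            "    return (ac[0] if isinstance(ac, list) else ac) / an\n")
        funcs = dict(FUNCS)
        funcs.update(load_script(str(script)))
        spec = PostAnnotationSpec(fields=("AC", "AN"), name="aaf",
                                  op="script:af_ratio", value_type="Float")
        assert evaluate_post(spec, {"AC": "25,5", "AN": "100"}, funcs) == 0.25

    def test_builtin_wilson_available_in_expressions(self):
        spec = PostAnnotationSpec(
            fields=("AC", "AN"), name="af_lb",
            op="af_conf_lower(first(AC), AN)", value_type="Float")
        v = evaluate_post(spec, {"AC": "50", "AN": "100"}, FUNCS)
        assert abs(v - wilson_lower_oracle(50, 100)) < 1e-9


class TestExpressionSandbox:
    def test_invalid_syntax_rejected_at_compile_time(self):
        with pytest.raises(ExpressionError, match="invalid expression"):
            compile_expression("a +* b", ("a", "b"), FUNCS)

    @pytest.mark.parametrize("expr", [
        "__import__('os')",
        "open('/etc/passwd')",
        "a.__class__",
        "[x for x in a]",
        "lambda: 1",
        "(f := 2)",
    ])
    def test_dangerous_constructs_rejected(self, expr):
        with pytest.raises(ExpressionError):
            compile_expression(expr, ("a",), FUNCS)

    def test_unknown_name_rejected(self):
        with pytest.raises(ExpressionError, match="unknown name"):
            compile_expression("a + nope", ("a",), FUNCS)

    def test_random_expressions_never_mutate_other_keys(self, rng):
        # evaluation must be pure with respect to the INFO map
        fields = ("a", "b")
        ops = ["a + b", "a * b - 2", "max(a, b)", "a / (b + 1)",
               "first(a) if b > 0 else b", "sqrt(abs(a))"]
        for _ in range(2000):
            spec = PostAnnotationSpec(fields=fields, name="out",
                                      op=rng.choice(ops))
            info = {"a": str(rng.randrange(-50, 50)),
                    "b": str(rng.randrange(-50, 50)), "DP": "7"}
            snapshot = dict(info)
            evaluate_post(spec, info, FUNCS)
            assert info == snapshot


class TestDeclarationOrder:
    def test_later_blocks_see_earlier_outputs(self):
        s1 = PostAnnotationSpec(fields=("AC", "AN"), name="aaf",
                                op="first(AC) / AN")
        s2 = PostAnnotationSpec(fields=("aaf",), name="rare",
                                op="aaf < 0.01", value_type="Flag")
        info = {"AC": "1", "AN": "1000"}
        v1 = evaluate_post(s1, info, FUNCS)
        info["aaf"] = v1
        assert evaluate_post(s2, info, FUNCS) is True

    def test_permuting_independent_blocks_leaves_output_unchanged(self):
        a = PostAnnotationSpec(fields=("x",), name="double", op="x * 2")
        b = PostAnnotationSpec(fields=("y",), name="half", op="y / 2")
        info = {"x": "3", "y": "10"}

        def run(order):
            out = {}
            view = dict(info)
            for spec in order:
                v = evaluate_post(spec, view, FUNCS)
                out[spec.name] = v
                view[spec.name] = v
            return out

        assert run([a, b]) == run([b, a])
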