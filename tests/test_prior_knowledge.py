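"""Prior-knowledge grammar: bounds, tie expressions, table parsing, compilation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from amaresfit.prior_knowledge import (
    Bound,
    ConstraintExpr,
    PriorKnowledgeError,
    compile_parameters,
    param_name,
    parse_bound,
    parse_expression,
    parse_prior_knowledge,
    prior_to_rows,
)

CARRIER = 120.645


class TestParseBound:
    @pytest.mark.parametrize(
        "text, lower, upper, fixed",
        [
            ("(-180, 180)", -180.0, 180.0, None),
            ("(−180, 180)", -180.0, 180.0, None),  # Unicode minus
            ("(0,", 0.0, None, None),
            ("(0,)", 0.0, None, None),
            (", 180)", None, 180.0, None),
            ("180)", None, 180.0, None),
            ("(, 180)", None, 180.0, None),
            ("0", None, None, 0.0),
            (" 58.12 ", None, None, 58.12),
        ],
    )
    def test_grammar(self, text, lower, upper, fixed):
        bound = parse_bound(text)
        assert bound.lower == lower
        assert bound.upper == upper
        assert bound.fixed == fixed

    @pytest.mark.parametrize("text", ["", "(1, 2, 3)", "(,)", "()", "(abc,"])
    def test_malformed_rejected(self, text):
        with pytest.raises(PriorKnowledgeError):
            parse_bound(text)

    def test_expression_in_bounds_block_rejected(self):
        with pytest.raises(PriorKnowledgeError, match="not supported inside the Bounds"):
            parse_bound("BATP/2")

    def test_inverted_range_rejected(self):
        with pytest.raises(PriorKnowledgeError):
            parse_bound("(10, -10)")

    def test_serialization_round_trip(self):
        for text in ["(-16.3, -16.0)", "(0,", ", 5)", "58.12"]:
            bound = parse_bound(text)
            assert parse_bound(bound.to_cell()) == bound


class TestParseExpression:
    KNOWN = ["BATP", "AATP"]

    def test_numeric_literal(self):
        assert parse_expression("1.41", "amplitude", self.KNOWN) == 1.41

    def test_ratio_tie(self):
        expr = parse_expression("BATP/2", "amplitude", self.KNOWN)
        assert expr.operation == "scale"
        assert expr.operand == 2.0
        assert expr.evaluate(1.41) == pytest.approx(0.705)

    def test_hz_offset_tie(self):
        expr = parse_expression("BATP-15Hz", "chemicalshift", self.KNOWN)
        assert expr.operation == "offset_hz"
        assert expr.operand == -15.0
        assert expr.evaluate(-16.15, carrier_mhz=CARRIER) == pytest.approx(
            -16.15 - 15.0 / CARRIER
        )

    def test_identity_tie(self):
        expr = parse_expression("AATP", "amplitude", self.KNOWN)
        assert expr.operation == "identity"
        assert expr.evaluate(1.545) == 1.545

    def test_ppm_offset_tie(self):
        expr = parse_expression("BATP+0.3", "chemicalshift", self.KNOWN)
        assert expr.operation == "offset_ppm"
        assert expr.evaluate(-16.15) == pytest.approx(-15.85)

    def test_forward_reference_rejected(self):
        with pytest.raises(PriorKnowledgeError, match="must precede"):
            parse_expression("GATP/2", "amplitude", self.KNOWN)

    def test_embedded_digits_rejected(self):
        with pytest.raises(PriorKnowledgeError, match="trailing"):
            parse_expression("BA2TP/2", "amplitude", self.KNOWN + ["BA2TP"])

    def test_offsets_only_in_chemicalshift_row(self):
        with pytest.raises(PriorKnowledgeError, match="chemicalshift"):
            parse_expression("BATP+5", "linewidth", self.KNOWN)


class TestParseTable:
    def test_example_table_structure(self, table1_pk):
        assert table1_pk.names == ["BATP", "BATP2", "BATP3", "AATP", "AATP2"]
        assert table1_pk.multiplet_groups == {
            "BATP": ["BATP", "BATP2", "BATP3"],
            "AATP": ["AATP", "AATP2"],
        }

    def test_comments_are_ignored(self, table1_rows):
        without = [r for r in table1_rows if not (r and r[0].strip().startswith("#"))]
        pk_with = parse_prior_knowledge(table1_rows, carrier_mhz=CARRIER)
        pk_without = parse_prior_knowledge(without, carrier_mhz=CARRIER)
        assert pk_with == pk_without
        assert len(pk_with.peaks) == 5

    def test_dependent_peak_left_of_source_rejected(self, table1_rows):
        rows = []
        for row in table1_rows:
            row = list(row)
            if len(row) > 2 and not (row and row[0].strip().startswith("#")):
                row[1], row[2] = row[2], row[1]  # put BATP2 before BATP
            rows.append(row)
        with pytest.raises(PriorKnowledgeError, match="must precede"):
            parse_prior_knowledge(rows, carrier_mhz=CARRIER)

    def test_missing_bounds_block_rejected(self, table1_rows):
        head = []
        for row in table1_rows:
            if row and row[0].strip().lower() == "bounds":
                break
            head.append(row)
        with pytest.raises(PriorKnowledgeError, match="Bounds"):
            parse_prior_knowledge(head, carrier_mhz=CARRIER)

    def test_duplicate_peak_name_rejected(self, table1_rows):
        rows = [list(r) for r in table1_rows]
        for row in rows:
            if row and row[0].strip().lower() == "index":
                row[2] = row[1]
        with pytest.raises(PriorKnowledgeError, match="duplicate"):
            parse_prior_knowledge(rows, carrier_mhz=CARRIER)

    def test_round_trip_through_the_dialect(self, table1_pk):
        reparsed = parse_prior_knowledge(prior_to_rows(table1_pk), carrier_mhz=CARRIER)
        assert reparsed == table1_pk


class TestCompileParameters:
    def test_fixed_g_classification_has_seven_free(self, table1_fixed_g_pk):
        compiled = compile_parameters(table1_fixed_g_pk)
        assert compiled.n_free == 7
        assert set(compiled.free_names) == {
            "BATP_amp", "BATP_cs", "BATP_lw", "BATP_phase",
            "AATP_amp", "AATP_cs", "AATP_lw",
        }
        for name in ("BATP_g", "BATP2_g", "AATP_g"):
            assert compiled.classification[name] in ("fixed", "tied")

    def test_printed_bounds_make_g_free(self, table1_pk):
        # as printed, g has range bounds (0, 1) and is therefore free
        compiled = compile_parameters(table1_pk)
        assert compiled.classification["BATP_g"] == "free"
        assert compiled.n_free == 12

    def test_all_bare_numbers_without_bounds_are_fixed(self):
        rows = [
            ["Index", "PCR"],
            ["Initial Values"],
            ["amplitude", "1.0"],
            ["chemicalshift", "0.0"],
            ["linewidth", "8.0"],
            ["phase", "0"],
            ["g", "0"],
            ["Bounds"],
        ]
        compiled = compile_parameters(parse_prior_knowledge(rows, carrier_mhz=CARRIER))
        assert compiled.n_free == 0
        assert all(c == "fixed" for c in compiled.classification.values())

    def test_scale_tie_evaluates_at_the_solution(self, table1_fixed_g_pk):
        compiled = compile_parameters(table1_fixed_g_pk)
        params = compiled.fresh()
        params["BATP_amp"].value = 1.41
        params.update_constraints()
        assert params["BATP2_amp"].value == pytest.approx(0.705)

    @given(
        amp=st.floats(0.1, 10),
        cs=st.floats(-16.3, -16.0),
        lw=st.floats(54.4, 61.9),
        phase=st.floats(-180, 180),
    )
    @settings(max_examples=25, deadline=None)
    def test_ties_hold_anywhere_in_parameter_space(
        self, table1_fixed_g_pk, amp, cs, lw, phase
    ):
        compiled = compile_parameters(table1_fixed_g_pk)
        params = compiled.fresh()
        params["BATP_amp"].value = amp
        params["BATP_cs"].value = cs
        params["BATP_lw"].value = lw
        params["BATP_phase"].value = phase
        params.update_constraints()
        values = {name: par.value for name, par in params.items()}
        for name, expr in compiled.ties.items():
            assert params[name].value == pytest.approx(
                compiled.evaluate_tie(name, values), rel=1e-12
            )
        # spot-check the defining expressions directly
        assert params["BATP2_amp"].value == pytest.approx(amp / 2, rel=1e-12)
        assert params["BATP2_cs"].value == pytest.approx(cs - 15.0 / CARRIER, rel=1e-12)
        assert params["BATP3_cs"].value == pytest.approx(cs + 15.0 / CARRIER, rel=1e-12)
        assert params["AATP2_phase"].value == pytest.approx(phase, rel=1e-12)


class TestBoundContainer:
    def test_exclusive_forms(self):
        with pytest.raises(PriorKnowledgeError):
            Bound(lower=0.0, fixed=1.0)

    def test_clip(self):
        bound = Bound(lower=0.0, upper=2.0)
        assert bound.clip(-1.0) == 0.0
        assert bound.clip(5.0) == 2.0
        assert Bound(fixed=3.0).clip(99.0) == 3.0


def test_constraint_expr_serialization_round_trip():
    for cell, field in [
        ("BATP/2", "amplitude"),
        ("BATP*1.5", "amplitude"),
        ("BATP-15Hz", "chemicalshift"),
        ("BATP+0.3", "chemicalshift"),
        ("BATP", "linewidth"),
    ]:
        expr = parse_expression(cell, field, ["BATP"])
        assert isinstance(expr, ConstraintExpr)
        again = parse_expression(expr.to_cell(), field, ["BATP"])
        assert again == expr
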