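"""Unit and property tests for the logical-network engine."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from gclogic.logic import (
    And,
    Atom,
    Component,
    DefinitionError,
    LevelRule,
    LogicalNetwork,
    ModelParseError,
    Not,
    Or,
    State,
    UsageError,
    apply_clamps,
    enumerate_fixpoints,
    evaluate_expression,
    expression_to_str,
    is_fixpoint,
    model_from_text,
    model_to_text,
    parse_expression,
    synchronous_step,
    target_level,
)
from gclogic.gc_model import build_gc_network


# ---------------------------------------------------------------------------
# Expressions
# ---------------------------------------------------------------------------

class TestExpressions:
    def test_atom_reads_threshold(self):
        assert evaluate_expression(Atom("BCR"), {"BCR": 1}) is True
        assert evaluate_expression(Atom("BCR"), {"BCR": 0}) is False
        assert evaluate_expression(Atom("NFkB", 2), {"NFkB": 1}) is False
        assert evaluate_expression(Atom("NFkB", 2), {"NFkB": 2}) is True

    def test_bcl2_rule_blocked_by_bcl6(self):
        # survival rule: (PI3K | NFkB) & !BCL6 is off while BCL6 is active
        expr = parse_expression("(PI3K | NFkB) & !BCL6")
        assert evaluate_expression(expr, {"PI3K": 1, "NFkB": 0, "BCL6": 1}) is False
        assert evaluate_expression(expr, {"PI3K": 1, "NFkB": 0, "BCL6": 0}) is True

    @pytest.mark.parametrize("level", [0, 1])
    def test_tautology(self, level):
        expr = Or((Not(Atom("A")), Atom("A")))
        assert evaluate_expression(expr, {"A": level}) is True

    def test_unknown_component_is_definition_error(self):
        with pytest.raises(DefinitionError):
            evaluate_expression(Atom("GHOST"), {"A": 1})

    @given(
        st.recursive(
            st.builds(Atom, st.sampled_from(["A", "B", "C"]), st.integers(1, 2)),
            lambda c: st.one_of(
                st.builds(Not, c),
                st.builds(lambda ops: And(tuple(ops)), st.lists(c, min_size=2, max_size=3)),
                st.builds(lambda ops: Or(tuple(ops)), st.lists(c, min_size=2, max_size=3)),
            ),
            max_leaves=12,
        ),
        st.dictionaries(st.sampled_from(["A", "B", "C"]), st.integers(0, 2),
                        min_size=3, max_size=3),
    )
    @settings(max_examples=60, derandomize=True)
    def test_text_form_is_canonical_and_semantics_preserving(self, expr, state):
        text = expression_to_str(expr)
        reparsed = parse_expression(text)
        assert expression_to_str(reparsed) == text
        assert evaluate_expression(reparsed, state) == evaluate_expression(expr, state)

    @pytest.mark.parametrize("bad", ["", "A &", "(A | B", "A ? B", "2 & A"])
    def test_malformed_expressions_rejected(self, bad):
        with pytest.raises(ModelParseError):
            parse_expression(bad)


# ---------------------------------------------------------------------------
# Update semantics
# ---------------------------------------------------------------------------

class TestUpdate:
    def test_highest_satisfied_level_wins(self, gc_network):
        # IKK complex: CBM branch alone gives level 1, TRAF6 drives level 2
        both = gc_network.state({"CBM": 1, "TRAF6": 1})
        assert target_level(gc_network, "IKKc", both) == 2
        cbm_only = gc_network.state({"CBM": 1})
        assert target_level(gc_network, "IKKc", cbm_only) == 1
        assert target_level(gc_network, "IKKc", gc_network.state({})) == 0

    def test_clamp_dominates_rule(self, gc_network):
        clamped = apply_clamps(gc_network, {"IKKc": 0})
        both = clamped.state({"CBM": 1, "TRAF6": 1})
        assert target_level(clamped, "IKKc", both) == 0

    def test_first_step_from_resting_cell(self, gc_network):
        # with only the BCR engaged, the first synchronous step activates
        # exactly the receptor-proximal kinases SYK and BTK
        start = gc_network.state({"BCR": 1})
        after = synchronous_step(gc_network, start)
        active = {name for name, lvl in after if lvl > 0}
        assert active == {"BCR", "SYK", "BTK"}

    def test_single_activation_chain(self):
        net = LogicalNetwork(
            (Component("A", is_input=True), Component("B")),
            {"B": LevelRule(((1, Atom("A")),))},
            clamps={"A": 1},
        )
        after = synchronous_step(net, net.state({"A": 1, "B": 0}))
        assert after["B"] == 1

    def test_fixpoint_is_stable_under_step(self, gc_network):
        fp = enumerate_fixpoints(gc_network, {"BCR": 1, "CD40": 1, "IL21/4": 1})[0]
        assert synchronous_step(gc_network, fp) == fp
        assert is_fixpoint(gc_network, fp)

    def test_resting_state_is_fixpoint_but_ectopic_myc_is_not(self, gc_network):
        zero = gc_network.state({})
        assert is_fixpoint(gc_network, zero)
        assert not is_fixpoint(gc_network, gc_network.state({"MYC": 1}))

    def test_empty_network_state_is_fixpoint(self):
        net = LogicalNetwork((), {})
        assert is_fixpoint(net, State((), ()))


# ---------------------------------------------------------------------------
# Fixpoint enumeration
# ---------------------------------------------------------------------------

class TestEnumeration:
    def test_negative_self_loop_has_no_fixpoint(self):
        net = LogicalNetwork(
            (Component("A"),), {"A": LevelRule(((1, Not(Atom("A"))),))}
        )
        assert enumerate_fixpoints(net, {}) == []

    def test_missing_input_assignment_is_usage_error(self, gc_network):
        with pytest.raises(UsageError):
            enumerate_fixpoints(gc_network, {"BCR": 1})

    def test_non_input_in_assignment_is_usage_error(self, gc_network):
        with pytest.raises(UsageError):
            enumerate_fixpoints(
                gc_network, {"BCR": 0, "CD40": 0, "IL21/4": 0, "MYC": 1}
            )

    def test_assignment_conflicting_with_input_clamp_is_usage_error(self, gc_network):
        clamped = apply_clamps(gc_network, {"BCR": 1})
        with pytest.raises(UsageError):
            enumerate_fixpoints(clamped, {"BCR": 0, "CD40": 0, "IL21/4": 0})

    def test_results_in_lexicographic_order(self):
        # two-way toggle switch: mutual inhibition has the two exclusive
        # fixpoints, returned in state-vector order
        net = LogicalNetwork(
            (Component("A"), Component("B")),
            {
                "A": LevelRule(((1, Not(Atom("B"))),)),
                "B": LevelRule(((1, Not(Atom("A"))),)),
            },
        )
        fps = enumerate_fixpoints(net, {})
        assert [fp.levels for fp in fps] == [(0, 1), (1, 0)]

    def test_fixpoints_invariant_to_component_order(self, gc_network):
        reordered = LogicalNetwork(
            tuple(reversed(gc_network.components)), gc_network.rules
        )
        for triple in itertools.product((0, 1), repeat=3):
            inputs = dict(zip(("BCR", "CD40", "IL21/4"), triple))
            a = [fp.as_dict() for fp in enumerate_fixpoints(gc_network, inputs)]
            b = [fp.as_dict() for fp in enumerate_fixpoints(reordered, inputs)]
            assert sorted(a, key=sorted) == sorted(b, key=sorted)

    def test_fixpoint_levels_within_bounds(self, gc_network):
        for triple in itertools.product((0, 1), repeat=3):
            inputs = dict(zip(("BCR", "CD40", "IL21/4"), triple))
            for fp in enumerate_fixpoints(gc_network, inputs):
                for comp in gc_network.components:
                    assert 0 <= fp[comp.name] <= comp.max_level


# ---------------------------------------------------------------------------
# Clamping
# ---------------------------------------------------------------------------

class TestClamps:
    def test_original_network_unchanged(self, gc_network):
        before = dict(gc_network.clamps)
        apply_clamps(gc_network, {"ERK": 1})
        assert dict(gc_network.clamps) == before

    def test_ectopic_erk_is_always_active(self, gc_network):
        clamped = apply_clamps(gc_network, {"ERK": 1})
        for state in (clamped.state({}), clamped.state({"RAF": 1, "STAT": 1})):
            assert target_level(clamped, "ERK", state) == 1

    def test_empty_clamp_set_is_identity(self, gc_network):
        assert apply_clamps(gc_network, {}) == gc_network

    def test_later_clamps_replace_earlier(self, gc_network):
        net = apply_clamps(apply_clamps(gc_network, {"BCL2": 1}), {"BCL2": 0})
        assert net.clamps["BCL2"] == 0

    @given(
        st.dictionaries(
            st.sampled_from(["ERK", "MYC", "BCL6", "NFkB", "IKKc"]),
            st.integers(0, 1),
            max_size=3,
        )
    )
    @settings(max_examples=30, derandomize=True)
    def test_clamp_idempotence(self, clamps):
        net = build_gc_network()
        once = apply_clamps(net, clamps)
        assert apply_clamps(once, clamps) == once

    def test_out_of_range_clamp_rejected(self, gc_network):
        with pytest.raises(DefinitionError):
            apply_clamps(gc_network, {"MYC": 2})
        with pytest.raises(DefinitionError):
            apply_clamps(gc_network, {"GHOST": 1})


# ---------------------------------------------------------------------------
# Model text format
# ---------------------------------------------------------------------------

class TestModelFormat:
    def test_write_read_write_is_byte_stable(self, gc_network):
        text = model_to_text(gc_network)
        assert model_to_text(model_from_text(text)) == text
        assert model_from_text(text) == gc_network

    def test_clamped_network_round_trips(self, gc_network):
        clamped = apply_clamps(gc_network, {"ERK": 1, "NFkB": 2})
        text = model_to_text(clamped)
        assert model_from_text(text) == clamped
        assert "clamp=1" in text and "clamp=2" in text

    def test_parse_error_reports_line_number(self):
        with pytest.raises(ModelParseError, match="line 2"):
            model_from_text("A : 1 : input\nB : x : input\n")

    def test_unknown_reference_rejected(self):
        with pytest.raises(DefinitionError):
            model_from_text("A : 1 : 1 <- GHOST\n")

    def test_boolean_component_needs_single_level_rule(self):
        with pytest.raises((DefinitionError, ModelParseError)):
            model_from_text("A : 1 : input\nB : 1 : 2 <- A ; 1 <- A\n")
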