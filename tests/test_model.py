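import itertools

import numpy as np
import pytest

from hillcube import (
    BooleanModel,
    LogicOperators,
    ModelError,
    UpdateRule,
    build_generic_rule,
    expression_to_rule,
    parse_boolean_equations,
    parse_expression,
    random_boolean_model,
    rule_to_expression,
    serialize_boolean_equations,
)
from hillcube.model import MAX_INDEGREE

from conftest import random_rule


class TestExpressionToRule:
    def test_or_single_zero_corner(self):
        rule = expression_to_rule(parse_expression("a || b"), ("a", "b"))
        assert rule.table.tolist() == [[0, 1], [1, 1]]

    def test_constant_one(self):
        rule = expression_to_rule(parse_expression("1"), ())
        assert rule.indegree == 0 and int(rule.table) == 1

    def test_fig3b_rule_single_one(self):
        # (A or C) and not (B or C): true only when A on, B and C off
        expr = parse_expression("(A || C) && ~(B || C)")
        rule = expression_to_rule(expr, ("A", "B", "C"))
        expected = np.zeros((2, 2, 2), dtype=int)
        expected[1, 0, 0] = 1
        assert rule.table.tolist() == expected.tolist()

    def test_missing_variable_rejected(self):
        with pytest.raises(ModelError, match="missing"):
            expression_to_rule(parse_expression("a && b"), ("a",))

    def test_duplicate_inputs_rejected(self):
        with pytest.raises(ModelError, match="duplicate"):
            expression_to_rule(parse_expression("a"), ("a", "a"))

    def test_indegree_cap(self):
        names = tuple(f"v{i}" for i in range(MAX_INDEGREE + 1))
        expr = parse_expression(" || ".join(names))
        with pytest.raises(ModelError, match="in-degree"):
            expression_to_rule(expr, names)


class TestGenericRule:
    def test_fig3b_example(self):
        expr = build_generic_rule(["A", "C"], ["B", "C"])
        assert expr.to_text() == "(A || C) && ~(B || C)"

    def test_single_activator(self):
        assert build_generic_rule(["A"], []).to_text() == "A"

    def test_and_combined_activators(self):
        ops = LogicOperators("AND", "AND", "OR")
        rule = expression_to_rule(
            build_generic_rule(["A", "B"], ["I"], ops), ("A", "B", "I")
        )
        expected = np.zeros((2, 2, 2), dtype=int)
        expected[1, 1, 0] = 1
        assert rule.table.tolist() == expected.tolist()

    def test_pure_inhibitor(self):
        expr = build_generic_rule([], ["I", "J"])
        rule = expression_to_rule(expr, ("I", "J"))
        assert rule.table.tolist() == [[1, 0], [0, 0]]

    def test_both_empty_rejected(self):
        with pytest.raises(ModelError):
            build_generic_rule([], [])

    def test_default_semantics_exhaustive(self):
        """Default triple: output on iff >=1 activator on and no inhibitor
        on, for all activator/inhibitor set sizes up to 3."""
        for m, n in itertools.product(range(4), range(4)):
            if m == 0 and n == 0:
                continue
            acts = [f"A{i}" for i in range(m)]
            inhs = [f"I{i}" for i in range(n)]
            expr = build_generic_rule(acts, inhs)
            for bits in itertools.product((0, 1), repeat=m + n):
                env = dict(zip(acts + inhs, bits))
                want = (
                    (any(env[a] for a in acts) if acts else True)
                    and not any(env[i] for i in inhs)
                )
                assert expr.evaluate(env) == int(want)


def test_rule_expression_round_trip():
    """Sum-of-products read-off re-tabulates to the identical table."""
    rng = np.random.default_rng(42)
    for _ in range(200):
        rule = random_rule(rng, int(rng.integers(0, 5)))
        back = expression_to_rule(rule_to_expression(rule), rule.inputs)
        assert np.array_equal(back.table, rule.table)


def test_serialize_parse_round_trip():
    """Equation-text round trip preserves every rule's Boolean function
    (constant tables may lose vacuous inputs, so compare semantically)."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        model = random_boolean_model(5, 3, rng)
        back = parse_boolean_equations(serialize_boolean_equations(model))
        assert set(back.species) == set(model.species)
        for name, rule in model.rules.items():
            back_rule = back.rules[name]
            for bits in itertools.product((0, 1), repeat=rule.indegree):
                env = dict(zip(rule.inputs, bits))
                got = back_rule(tuple(env[i] for i in back_rule.inputs))
                assert got == rule(bits)


class TestRandomModel:
    def test_reproducible(self):
        a = random_boolean_model(6, 3, seed=11)
        b = random_boolean_model(6, 3, seed=11)
        assert a.species == b.species
        for name in a.species:
            assert a.rules[name] == b.rules[name]

    def test_zero_indegree_all_constant(self):
        model = random_boolean_model(5, 0, seed=0)
        assert all(r.indegree == 0 for r in model.rules.values())

    def test_constant_rule_fraction_matches_binomial(self):
        """With in-degree uniform on {0,1,2}: P(constant table) =
        (1 + 2/4 + 2/16)/3 = 13/24; 4000 draws within 3 standard errors."""
        rng = np.random.default_rng(123)
        n_const = n_total = 0
        for _ in range(1000):
            model = random_boolean_model(4, 2, rng)
            for rule in model.rules.values():
                n_total += 1
                vals = np.unique(rule.table)
                n_const += int(len(vals) == 1)
        p = 13 / 24
        se = np.sqrt(p * (1 - p) / n_total)
        assert abs(n_const / n_total - p) < 3 * se

    def test_invalid_counts(self):
        with pytest.raises(ModelError):
            random_boolean_model(0, 0, seed=1)
        with pytest.raises(ModelError):
            random_boolean_model(3, 4, seed=1)


class TestModelValidation:
    def test_rule_must_reference_declared_species(self):
        rule = UpdateRule("X", ("Z",), np.array([0, 1]))
        with pytest.raises(ModelError, match="undeclared"):
            BooleanModel(("X",), {"X": rule})

    def test_input_species_listed(self):
        model = parse_boolean_equations("A = B")
        assert model.input_species == ("B",)

    def test_rename_preserves_tables(self, or_switch):
        renamed = or_switch.rename({"X": "Gata1", "Y": "Pu1"})
        assert renamed.species == ("Gata1", "Pu1")
        assert np.array_equal(
            renamed.rules["Gata1"].table, or_switch.rules["X"].table
        )
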