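"""Boolean model representation: update rules as truth-table hypercubes.

A Boolean model holds ``N`` named species and at most one update rule per
species.  A rule stores an ordered input list and a ``2^d`` truth table kept
as a d-dimensional array with edge length 2 ("hypercube"), indexed by the
input tuple with the *first* input as the slowest-varying axis.  Species
without a rule are constant model inputs: their value never changes in the
discrete dynamics and their continuous derivative is pinned to zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .expr import (
    And,
    BooleanExpression,
    Const,
    ExpressionError,
    Not,
    Or,
    Var,
    parse_expression,
)

#: Hard cap on rule in-degree; table size grows as 2^d.
MAX_INDEGREE = 16


class ModelError(ValueError):
    """Invalid model structure."""


@dataclass(frozen=True)
class LogicOperators:
    """The generic-logic operator triple for interaction-graph import.

    With activators A_1..A_m and inhibitors I_1..I_n the rule reads
    ``(A_1 op_act ... op_act A_m) op_mix NOT(I_1 op_inh ... op_inh I_n)``.
    The default (OR, AND, OR) activates the target iff at least one
    activator and no inhibitor is active.
    """

    activator_combiner: str = "OR"
    activator_inhibitor_combiner: str = "AND"
    inhibitor_combiner: str = "OR"

    def __post_init__(self):
        for name in ("activator_combiner", "activator_inhibitor_combiner", "inhibitor_combiner"):
            value = getattr(self, name)
            if value not in ("AND", "OR"):
                raise ModelError(f"{name} must be 'AND' or 'OR', got {value!r}")


DEFAULT_OPERATORS = LogicOperators()


@dataclass(frozen=True)
class UpdateRule:
    """Update rule for one species: ordered inputs + 2^d truth table."""

    target: str
    inputs: tuple[str, ...]
    table: np.ndarray = field(compare=False)

    def __post_init__(self):
        inputs = tuple(self.inputs)
        object.__setattr__(self, "inputs", inputs)
        if len(set(inputs)) != len(inputs):
            raise ModelError(f"rule for {self.target!r} has duplicate inputs")
        if len(inputs) > MAX_INDEGREE:
            raise ModelError(
                f"rule for {self.target!r} has in-degree {len(inputs)} > cap "
                f"{MAX_INDEGREE}; truth tables grow as 2^d"
            )
        table = np.asarray(self.table, dtype=np.uint8).reshape((2,) * len(inputs))
        if table.size and not np.isin(table, (0, 1)).all():
            raise ModelError(f"rule for {self.target!r}: table entries must be 0/1")
        object.__setattr__(self, "table", table)

    @property
    def indegree(self) -> int:
        return len(self.inputs)

    def __call__(self, values: tuple[int, ...]) -> int:
        """Evaluate the Boolean function at an input tuple."""
        return int(self.table[tuple(values)])

    def __eq__(self, other):
        if not isinstance(other, UpdateRule):
            return NotImplemented
        return (
            self.target == other.target
            and self.inputs == other.inputs
            and np.array_equal(self.table, other.table)
        )


@dataclass(frozen=True)
class BooleanModel:
    """Ordered species list plus at most one :class:`UpdateRule` each."""

    species: tuple[str, ...]
    rules: dict[str, UpdateRule]

    def __post_init__(self):
        species = tuple(self.species)
        object.__setattr__(self, "species", species)
        if len(set(species)) != len(species):
            raise ModelError("duplicate species names")
        declared = set(species)
        for name, rule in self.rules.items():
            if name != rule.target:
                raise ModelError(f"rule keyed {name!r} targets {rule.target!r}")
            if name not in declared:
                raise ModelError(f"rule target {name!r} is not a declared species")
            missing = [s for s in rule.inputs if s not in declared]
            if missing:
                raise ModelError(
                    f"rule for {name!r} references undeclared species {missing}"
                )

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def input_species(self) -> tuple[str, ...]:
        """Species without an update rule (constant model inputs)."""
        return tuple(s for s in self.species if s not in self.rules)

    def interactions(self) -> list[tuple[str, str]]:
        """All (target, input) regulator pairs, in declaration order."""
        return [(t, i) for t in self.species if t in self.rules
                for i in self.rules[t].inputs]

    def index(self, name: str) -> int:
        return self.species.index(name)

    def rename(self, mapping: dict[str, str]) -> "BooleanModel":
        """Return a copy with species renamed via ``mapping`` (identity for
        names not listed)."""
        def m(s: str) -> str:
            return mapping.get(s, s)

        rules = {
            m(t): UpdateRule(m(t), tuple(m(i) for i in r.inputs), r.table)
            for t, r in self.rules.items()
        }
        return BooleanModel(tuple(m(s) for s in self.species), rules)


# --- expression <-> rule -------------------------------------------------

def expression_to_rule(
    expr: BooleanExpression, input_order: list[str] | tuple[str, ...], target: str = ""
) -> UpdateRule:
    """Tabulate an expression over all 2^d assignments of ``input_order``.

    ``input_order`` must contain every variable of ``expr`` exactly once;
    extra names are allowed (the table is then constant along those axes).
    """
    inputs = tuple(input_order)
    if len(set(inputs)) != len(inputs):
        raise ModelError("input_order contains duplicates")
    missing = [v for v in expr.variables() if v not in inputs]
    if missing:
        raise ModelError(f"input_order is missing used variables {missing}")
    d = len(inputs)
    table = np.empty((2,) * d, dtype=np.uint8)
    for assignment in itertools.product((0, 1), repeat=d):
        env = dict(zip(inputs, assignment))
        table[assignment] = expr.evaluate(env)
    return UpdateRule(target or "_", inputs, table)


def rule_to_expression(rule: UpdateRule) -> BooleanExpression:
    """Sum-of-products read-off of a truth table.

    One conjunctive minterm per table entry equal to 1, OR-ed together;
    all-zero tables give the constant 0, a 1-entry d=0 table the constant 1.
    """
    if rule.indegree == 0:
        return Const(int(rule.table))
    terms: list[BooleanExpression] = []
    for assignment in itertools.product((0, 1), repeat=rule.indegree):
        if not rule.table[assignment]:
            continue
        literals = [
            Var(name) if bit else Not(Var(name))
            for name, bit in zip(rule.inputs, assignment)
        ]
        term = literals[0]
        for lit in literals[1:]:
            term = And(term, lit)
        terms.append(term)
    if not terms:
        return Const(0)
    expr = terms[0]
    for term in terms[1:]:
        expr = Or(expr, term)
    return expr


def build_generic_rule(
    activators: list[str],
    inhibitors: list[str],
    ops: LogicOperators = DEFAULT_OPERATORS,
) -> BooleanExpression:
    """Combine activators and inhibitors with the generic operator triple.

    Returns ``(A_1 op ... op A_m) mix NOT(I_1 op ... op I_n)``; a side that
    is empty is dropped together with the mixing operator.  A species may
    appear in both lists and is kept in both.
    """
    if not activators and not inhibitors:
        raise ModelError("generic rule needs at least one activator or inhibitor")

    def combine(names: list[str], op: str) -> BooleanExpression:
        node: BooleanExpression = Var(names[0])
        ctor = And if op == "AND" else Or
        for name in names[1:]:
            node = ctor(node, Var(name))
        return node

    act = combine(list(activators), ops.activator_combiner) if activators else None
    inh = (
        Not(combine(list(inhibitors), ops.inhibitor_combiner))
        if inhibitors
        else None
    )
    if act is None:
        return inh
    if inh is None:
        return act
    ctor = And if ops.activator_inhibitor_combiner == "AND" else Or
    return ctor(act, inh)


# --- equation text -------------------------------------------------------

def parse_boolean_equations(text: str) -> BooleanModel:
    """Parse multi-line rule text (one ``Name = expression`` per line).

    ``#`` starts a comment; blank lines are skipped.  The model's species
    are every name appearing anywhere, left-hand sides first in file order,
    then right-hand-side-only names in order of first appearance.
    """
    rules: dict[str, UpdateRule] = {}
    lhs_order: list[str] = []
    rhs_order: list[str] = []  # first-appearance order of RHS names
    any_line = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        any_line = True
        if "=" not in line:
            raise ExpressionError("expected 'Name = expression'", lineno)
        lhs, rhs = line.split("=", 1)
        lhs = lhs.strip()
        if not lhs or not lhs.replace("_", "a")[0].isalpha() or " " in lhs:
            raise ExpressionError(f"invalid left-hand side {lhs!r}", lineno)
        if lhs in rules:
            raise ExpressionError(f"duplicate rule for {lhs!r}", lineno)
        expr = parse_expression(rhs, line=lineno)
        inputs = expr.variables()
        rules[lhs] = expression_to_rule(expr, inputs, target=lhs)
        lhs_order.append(lhs)
        for name in inputs:
            if name not in rhs_order:
                rhs_order.append(name)
    if not any_line:
        raise ExpressionError("empty input: no equations found")
    # left-hand sides in file order, then RHS-only names by first appearance
    species = tuple(lhs_order) + tuple(n for n in rhs_order if n not in rules)
    return BooleanModel(species, rules)


def serialize_boolean_equations(model: BooleanModel) -> str:
    """Render a model back to equation text (sum-of-products rules).

    ``parse_boolean_equations(serialize_boolean_equations(m))`` reproduces
    the same truth tables.  Inputless species are emitted as a trailing
    comment so the species set survives the round trip.
    """
    lines = [
        f"{name} = {rule_to_expression(model.rules[name]).to_text()}"
        for name in model.species
        if name in model.rules
    ]
    orphans = [s for s in model.input_species if s not in _mentioned(model)]
    if orphans:
        # keep the species visible: X = X is the identity, value never changes
        lines += [f"{s} = {s}" for s in orphans]
    return "\n".join(lines) + "\n"


def _mentioned(model: BooleanModel) -> set[str]:
    used: set[str] = set(model.rules)
    for rule in model.rules.values():
        used.update(rule.inputs)
    return used


# --- random fixtures -----------------------------------------------------

def random_boolean_model(
    n_species: int,
    max_indegree: int,
    seed: int | np.random.Generator,
    names: list[str] | None = None,
) -> BooleanModel:
    """Draw a random Boolean model, reproducibly for a fixed seed.

    Each species independently receives a uniform in-degree d in
    ``{0, ..., max_indegree}``, d distinct inputs sampled uniformly without
    replacement, and a uniform random 2^d truth table.
    """
    if n_species < 1:
        raise ModelError("n_species must be >= 1")
    if not 0 <= max_indegree <= n_species:
        raise ModelError("max_indegree must be in [0, n_species]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if names is None:
        names = [f"S{i + 1}" for i in range(n_species)]
    elif len(names) != n_species:
        raise ModelError("names length must equal n_species")
    rules: dict[str, UpdateRule] = {}
    for name in names:
        d = int(rng.integers(0, max_indegree + 1))
        inputs = tuple(names[j] for j in rng.choice(n_species, size=d, replace=False))
        table = rng.integers(0, 2, size=2**d, dtype=np.uint8)
        rules[name] = UpdateRule(name, inputs, table)
    return BooleanModel(tuple(names), rules)
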