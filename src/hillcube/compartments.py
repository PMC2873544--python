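"""Multicompartment expansion: a linear row of C coupled model copies.

Each compartment carries the full single-cell rule set.  Species flagged
as *intercompartmental* (secreted factors) act on the neighboring
compartments: wherever a flagged species S appears as a rule input in
compartment c, it is replaced by the OR of S's copies in the existing
neighbors c−1 and c+1 (one neighbor at the row ends).  Non-flagged inputs
map to the same-compartment copy.  Copies are named ``<species>_<c>`` with
1-based compartment index, ordered compartment-major.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .expr import BooleanExpression, Const, Not, Or, Var, And
from .model import BooleanModel, ModelError, expression_to_rule, rule_to_expression

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CompartmentSpec:
    """Row length C and the set of intercompartmental species.

    ``include_self`` adds the compartment's own copy to the neighbor OR
    (default off: a secreted factor acts only on the two adjacent cells).
    """

    n_compartments: int
    intercompartment: frozenset[str] = field(default_factory=frozenset)
    include_self: bool = False

    def __post_init__(self):
        if self.n_compartments < 1:
            raise ModelError("n_compartments must be >= 1")
        object.__setattr__(
            self, "intercompartment", frozenset(self.intercompartment)
        )


def compartment_name(species: str, c: int) -> str:
    return f"{species}_{c}"


def expand_multicompartment(
    model: BooleanModel, spec: CompartmentSpec
) -> BooleanModel:
    """Expand a single-cell model into N·C species with substituted rules."""
    unknown = spec.intercompartment - set(model.species)
    if unknown:
        raise ModelError(
            f"intercompartment flags on unknown species {sorted(unknown)}"
        )
    C = spec.n_compartments
    species = tuple(
        compartment_name(s, c) for c in range(1, C + 1) for s in model.species
    )
    rules = {}
    for c in range(1, C + 1):
        for name in model.species:
            rule = model.rules.get(name)
            if rule is None:
                continue
            target = compartment_name(name, c)
            substitution: dict[str, BooleanExpression] = {}
            new_inputs: list[str] = []
            for inp in rule.inputs:
                copies = [
                    compartment_name(inp, nb)
                    for nb in _neighborhood(c, C, spec.include_self)
                ] if inp in spec.intercompartment else [compartment_name(inp, c)]
                new_inputs.extend(copies)
                if not copies:
                    logger.warning(
                        "flagged species %s in a %d-compartment row has no "
                        "neighbors; substituting constant 0", inp, C,
                    )
                    substitution[inp] = Const(0)
                else:
                    node: BooleanExpression = Var(copies[0])
                    for copy in copies[1:]:
                        node = Or(node, Var(copy))
                    substitution[inp] = node
            expr = _substitute(rule_to_expression(rule), substitution)
            rules[target] = expression_to_rule(expr, new_inputs, target=target)
    return BooleanModel(species, rules)


def replicate_state(state, n_compartments: int) -> tuple:
    """Replicate a single-cell state across all compartments (compartment-
    major order, matching the expanded species list)."""
    return tuple(state) * n_compartments


def _neighborhood(c: int, C: int, include_self: bool) -> list[int]:
    nbs = [nb for nb in (c - 1, c + 1) if 1 <= nb <= C]
    if include_self:
        nbs.insert(1 if c > 1 else 0, c)
    return nbs


def _substitute(
    expr: BooleanExpression, mapping: dict[str, BooleanExpression]
) -> BooleanExpression:
    if isinstance(expr, Var):
        return mapping.get(expr.name, expr)
    if isinstance(expr, Const):
        return expr
    if isinstance(expr, Not):
        return Not(_substitute(expr.operand, mapping))
    if isinstance(expr, And):
        return And(_substitute(expr.left, mapping), _substitute(expr.right, mapping))
    if isinstance(expr, Or):
        return Or(_substitute(expr.left, mapping), _substitute(expr.right, mapping))
    raise TypeError(f"unknown expression node {type(expr).__name__}")
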