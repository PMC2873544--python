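"""Interaction-graph and hypergraph import from GraphML.

Dialect: nodes are species (their ``label`` attribute, falling back to the
node id, names the species) or AND-hypernodes (label exactly ``&``); every
edge carries a ``sign`` attribute, ``+`` for activation and ``-`` for
inhibition.

Plain nodes with several regulators combine them through the generic
operator triple (:class:`~hillcube.model.LogicOperators`).  When any input
arrives through an ``&`` node, the rule is read in sum-of-products form
instead: each ``&`` node contributes one conjunctive term (inhibiting edges
negate their source inside the term, and an inhibiting edge leaving the
``&`` node negates the whole term), direct edges contribute single-literal
terms, and all terms are OR-combined.
"""

from __future__ import annotations

import networkx as nx

from .expr import And, BooleanExpression, Not, Or, Var
from .model import (
    BooleanModel,
    DEFAULT_OPERATORS,
    LogicOperators,
    ModelError,
    UpdateRule,
    build_generic_rule,
    expression_to_rule,
)

HYPERNODE_LABEL = "&"


def import_interaction_graph(
    graph: nx.DiGraph | str,
    default_ops: LogicOperators = DEFAULT_OPERATORS,
) -> BooleanModel:
    """Convert a GraphML document (path/string) or a networkx digraph."""
    if isinstance(graph, str):
        if "<" in graph:  # document text rather than a path
            graph = nx.parse_graphml(graph)
        else:
            graph = nx.read_graphml(graph)
    if not graph.is_directed():
        raise ModelError("interaction graph must be directed")

    label = {
        node: str(data.get("label", node)) for node, data in graph.nodes(data=True)
    }
    hypernodes = {n for n, lab in label.items() if lab == HYPERNODE_LABEL}
    species = [label[n] for n in graph.nodes if n not in hypernodes]
    if len(set(species)) != len(species):
        raise ModelError("duplicate species labels in graph")

    def in_edges(node):
        edges = []
        for u, _, data in graph.in_edges(node, data=True):
            if "sign" not in data:
                raise ModelError(
                    f"edge {label[u]!r} -> {label[node]!r} lacks the 'sign' "
                    "attribute ('+' or '-')"
                )
            sign = str(data["sign"])
            if sign not in ("+", "-"):
                raise ModelError(
                    f"edge {label[u]!r} -> {label[node]!r} has sign {sign!r}; "
                    "expected '+' or '-'"
                )
            edges.append((u, sign))
        return edges

    for h in hypernodes:
        if graph.in_degree(h) == 0 or graph.out_degree(h) == 0:
            raise ModelError("'&' hypernode with no inputs or no output")

    def hyper_term(node, active: frozenset) -> BooleanExpression:
        """Conjunction contributed by an '&' node, expanding chained '&'s."""
        if node in active:
            raise ModelError("cyclic chain of '&' hypernodes")
        term: BooleanExpression | None = None
        for src, sign in in_edges(node):
            if src in hypernodes:
                lit = hyper_term(src, active | {node})
            else:
                lit = Var(label[src])
            if sign == "-":
                lit = Not(lit)
            term = lit if term is None else And(term, lit)
        return term

    rules: dict[str, UpdateRule] = {}
    for node in graph.nodes:
        if node in hypernodes:
            continue
        edges = in_edges(node)
        if not edges:
            continue  # source node: species stays a constant input
        name = label[node]
        if any(src in hypernodes for src, _ in edges):
            terms: list[BooleanExpression] = []
            for src, sign in edges:
                if src in hypernodes:
                    term = hyper_term(src, frozenset())
                    if sign == "-":
                        term = Not(term)
                else:
                    term = Not(Var(label[src])) if sign == "-" else Var(label[src])
                terms.append(term)
            expr = terms[0]
            for term in terms[1:]:
                expr = Or(expr, term)
        else:
            activators = [label[src] for src, sign in edges if sign == "+"]
            inhibitors = [label[src] for src, sign in edges if sign == "-"]
            expr = build_generic_rule(activators, inhibitors, default_ops)
        rules[name] = expression_to_rule(expr, expr.variables(), target=name)

    return BooleanModel(tuple(species), rules)


def stg_to_graphml(stg: nx.DiGraph, path: str) -> None:
    """Write a state-transition graph to GraphML (states as '0101' ids)."""
    renamed = nx.relabel_nodes(
        stg, {node: "".join(map(str, node)) for node in stg.nodes}
    )
    nx.write_graphml(renamed, path)
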