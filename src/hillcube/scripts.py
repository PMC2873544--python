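"""Plain-text ODE script export with pluggable dialect templates.

Dialects render the converted right-hand sides as human-readable infix
expressions.  Each Hill transform is assigned to one local variable
``f_<target>_<input>`` so every (target, input) Hill term appears exactly
once per script; the corner-sum activation then references those
variables.  Output is deterministic: same model + parameters = identical
text.

Built-in dialects: ``matlab``, ``r`` (deSolve convention) and ``python``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .model import BooleanModel, ModelError, UpdateRule
from .ode import ParameterSet, default_parameters, _complete_hill, _complete_tau


@dataclass(frozen=True)
class Dialect:
    """Rendering conventions of one target language."""

    name: str
    power: str  # power operator with {x} and {n} slots
    state: str  # state element access with {i} slot (1- or 0-based)
    base: int  # first index
    assign: str  # local assignment with {lhs} and {rhs}
    deriv: str  # derivative assignment with {i} and {rhs}
    header: str  # with {n} (species count) and {names} slots
    footer: str
    comment: str


DIALECTS: dict[str, Dialect] = {
    "matlab": Dialect(
        name="matlab",
        power="{x}^{n}",
        state="x({i})",
        base=1,
        assign="{lhs} = {rhs};",
        deriv="dx({i}) = {rhs};",
        header="function dx = odefun(t, x)\n% species: {names}\ndx = zeros({n}, 1);",
        footer="end",
        comment="% ",
    ),
    "r": Dialect(
        name="r",
        power="{x}^{n}",
        state="x[{i}]",
        base=1,
        assign="{lhs} <- {rhs}",
        deriv="dx[{i}] <- {rhs}",
        header="odefun <- function(t, x, parms) {{\n# species: {names}\ndx <- numeric({n})",
        footer="list(dx)\n}",
        comment="# ",
    ),
    "python": Dialect(
        name="python",
        power="{x}**{n}",
        state="x[{i}]",
        base=0,
        assign="{lhs} = {rhs}",
        deriv="dx[{i}] = {rhs}",
        header="def odefun(t, x):\n    # species: {names}",
        footer="",
        comment="# ",
    ),
}


def register_dialect(dialect: Dialect) -> None:
    DIALECTS[dialect.name] = dialect


def _fmt(value: float) -> str:
    return repr(float(value))


def to_script(
    model: BooleanModel,
    method: str,
    params: ParameterSet | None = None,
    dialect: str = "matlab",
) -> str:
    """Render the converted system as an ODE script in the given dialect."""
    if method not in ("boolecube", "hillcube", "hillcubenorm"):
        raise ModelError(f"unknown method {method!r}")
    try:
        dia = DIALECTS[dialect]
    except KeyError:
        raise ModelError(
            f"unknown dialect {dialect!r}; registered: {sorted(DIALECTS)}"
        ) from None
    if params is None:
        params = default_parameters(model)
    index = {s: i for i, s in enumerate(model.species)}

    def state(name: str) -> str:
        return dia.state.format(i=index[name] + dia.base)

    lines: list[str] = [
        dia.header.format(n=model.n_species, names=", ".join(model.species))
    ]
    body: list[str] = []
    for name in model.species:
        rule = model.rules.get(name)
        tau = _complete_tau(params, name)
        if rule is None:
            body.append(dia.comment + f"{name} is a constant model input")
            body.append(dia.deriv.format(i=index[name] + dia.base, rhs="0"))
            continue
        term_names: dict[str, str] = {}
        if method != "boolecube":
            for inp in rule.inputs:
                hp = _complete_hill(params, name, inp)
                xn = dia.power.format(x=state(inp), n=_fmt(hp.n))
                kn = dia.power.format(x=f"({_fmt(hp.k)})", n=_fmt(hp.n))
                if method == "hillcubenorm":
                    rhs = f"{xn} * (1 + {kn}) / ({xn} + {kn})"
                else:
                    rhs = f"{xn} / ({xn} + {kn})"
                var = f"f_{name}_{inp}"
                body.append(dia.assign.format(lhs=var, rhs=rhs))
                term_names[inp] = var
        else:
            term_names = {inp: state(inp) for inp in rule.inputs}
        activation = _corner_sum(rule, term_names)
        body.append(
            dia.deriv.format(
                i=index[name] + dia.base,
                rhs=f"(({activation}) - {state(name)}) / {_fmt(tau)}",
            )
        )
    if dia.name == "python":
        body.insert(0, f"dx = [0.0] * {model.n_species}")
        body.append("return dx")
        lines.extend("    " + b for b in body)
    else:
        lines.extend(body)
    if dia.footer:
        lines.append(dia.footer)
    return "\n".join(lines) + "\n"


def _corner_sum(rule: UpdateRule, term: dict[str, str]) -> str:
    if rule.indegree == 0:
        return str(int(rule.table))
    products = []
    for corner in itertools.product((0, 1), repeat=rule.indegree):
        if not rule.table[corner]:
            continue
        factors = [
            term[inp] if bit else f"(1 - {term[inp]})"
            for inp, bit in zip(rule.inputs, corner)
        ]
        products.append(" * ".join(factors))
    return " + ".join(products) if products else "0"
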