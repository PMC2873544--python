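"""SBML Level 3 Version 2 export of the converted continuous system.

The ODE is phenomenological, not mass-action chemistry, so every species
gets a *rate rule* rather than reactions: dx/dt = (activation − x) / τ.
The activation MathML is emitted fully expanded — an explicit corner sum
over the truth table with the per-interaction Hill transform written out —
so the exported document is self-contained and portable to any
SBML-capable simulator.

Identifier conventions: species keep their (sanitized) names; global
parameters are ``tau_<species>``, ``n_<target>_<input>`` and
``k_<target>_<input>``.
"""

from __future__ import annotations

import itertools
import logging
import re
import xml.etree.ElementTree as ET

from .model import BooleanModel, ModelError
from .ode import ParameterSet, default_parameters, _complete_hill, _complete_tau

logger = logging.getLogger(__name__)

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"

_SID_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def sanitize_sbml_ids(names) -> dict[str, str]:
    """Map each name to a valid, unique SBML SId; identity where possible."""
    mapping: dict[str, str] = {}
    used: set[str] = set()
    for name in names:
        sid = re.sub(r"[^A-Za-z0-9_]", "_", name)
        if not sid or not _SID_RE.match(sid):
            sid = "_" + sid
        base = sid
        suffix = 1
        while sid in used:
            suffix += 1
            sid = f"{base}_{suffix}"
        used.add(sid)
        mapping[name] = sid
    changed = {k: v for k, v in mapping.items() if k != v}
    if changed:
        logger.warning("sanitized species ids for SBML export: %s", changed)
    return mapping


# --- MathML construction -------------------------------------------------

def _m(tag: str, *children: ET.Element, text: str | None = None,
       **attrib: str) -> ET.Element:
    el = ET.Element(f"{{{MATHML_NS}}}{tag}", attrib)
    if text is not None:
        el.text = text
    el.extend(children)
    return el


def _apply(op: str, *args: ET.Element) -> ET.Element:
    return _m("apply", _m(op), *args)


def _ci(name: str) -> ET.Element:
    return _m("ci", text=f" {name} ")


def _cn(value: float) -> ET.Element:
    if float(value) == int(value):
        return _m("cn", text=f" {int(value)} ", type="integer")
    return _m("cn", text=f" {value!r} ")


def _hill_math(x: ET.Element, n_id: str, k_id: str, normalized: bool) -> ET.Element:
    """x^n / (x^n + k^n), optionally times (1 + k^n) for normalization."""
    xn = _apply("power", x, _ci(n_id))
    kn = _apply("power", _ci(k_id), _ci(n_id))
    numerator = xn
    if normalized:
        numerator = _apply("times", xn, _apply("plus", _cn(1), _m_copy(kn)))
    return _apply("divide", numerator, _apply("plus", _m_copy(xn), _m_copy(kn)))


def _m_copy(el: ET.Element) -> ET.Element:
    return ET.fromstring(ET.tostring(el))


def _activation_math(rule, method: str, ids: dict[str, str]) -> ET.Element:
    """Corner sum Σ_{c:B(c)=1} Π_j g_j^(c_j) with g per the method tag."""
    d = rule.indegree
    target = rule.target

    def g(inp: str) -> ET.Element:
        x = _ci(ids[inp])
        if method == "boolecube":
            return x
        return _hill_math(
            x,
            f"n_{ids[target]}_{ids[inp]}",
            f"k_{ids[target]}_{ids[inp]}",
            normalized=(method == "hillcubenorm"),
        )

    terms: list[ET.Element] = []
    for corner in itertools.product((0, 1), repeat=d):
        if not rule.table[corner]:
            continue
        factors = [
            _m_copy(g(inp)) if bit else _apply("minus", _cn(1), _m_copy(g(inp)))
            for inp, bit in zip(rule.inputs, corner)
        ]
        if not factors:  # constant-1 rule, d = 0
            terms.append(_cn(1))
        elif len(factors) == 1:
            terms.append(factors[0])
        else:
            terms.append(_apply("times", *factors))
    if not terms:
        return _cn(0)
    if len(terms) == 1:
        return terms[0]
    return _apply("plus", *terms)


# --- document ------------------------------------------------------------

def to_sbml(
    model: BooleanModel,
    method: str,
    params: ParameterSet | None = None,
    model_id: str = "converted_model",
) -> str:
    """Render the converted system as an SBML L3V2 document string."""
    if method not in ("boolecube", "hillcube", "hillcubenorm"):
        raise ModelError(f"unknown method {method!r}")
    if params is None:
        params = default_parameters(model)
    ids = sanitize_sbml_ids(model.species)

    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    sbml = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "2"})
    mdl = ET.SubElement(sbml, f"{{{SBML_NS}}}model", {"id": model_id})

    comps = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(
        comps, f"{{{SBML_NS}}}compartment",
        {"id": "cell", "spatialDimensions": "3", "size": "1", "constant": "true"},
    )

    species_el = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfSpecies")
    for name in model.species:
        ET.SubElement(
            species_el, f"{{{SBML_NS}}}species",
            {
                "id": ids[name], "compartment": "cell", "initialAmount": "0.5",
                "hasOnlySubstanceUnits": "true", "boundaryCondition": "false",
                "constant": "false",
            },
        )

    params_el = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfParameters")

    def add_param(pid: str, value: float) -> None:
        ET.SubElement(
            params_el, f"{{{SBML_NS}}}parameter",
            {"id": pid, "value": repr(float(value)), "constant": "true"},
        )

    for name in model.species:
        add_param(f"tau_{ids[name]}", _complete_tau(params, name))
    if method != "boolecube":
        for target, input_ in model.interactions():
            hp = _complete_hill(params, target, input_)
            add_param(f"n_{ids[target]}_{ids[input_]}", hp.n)
            add_param(f"k_{ids[target]}_{ids[input_]}", hp.k)

    rules_el = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfRules")
    for name in model.species:
        rule = model.rules.get(name)
        rate = ET.SubElement(
            rules_el, f"{{{SBML_NS}}}rateRule", {"variable": ids[name]}
        )
        math = ET.SubElement(rate, f"{{{MATHML_NS}}}math")
        if rule is None:
            math.append(_cn(0))  # constant model input
            continue
        rhs = _apply(
            "divide",
            _apply("minus", _activation_math(rule, method, ids), _ci(ids[name])),
            _ci(f"tau_{ids[name]}"),
        )
        math.append(rhs)

    ET.indent(sbml)
    return '<?xml version="1.0" encoding="UTF-8"?>\n' + ET.tostring(
        sbml, encoding="unicode"
    ) + "\n"
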