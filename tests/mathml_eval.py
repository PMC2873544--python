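"""Minimal MathML evaluator used to cross-validate SBML exports.

Parses the content-MathML subset the exporter emits (apply with plus,
minus, times, divide, power; ci; cn) into a closure over a symbol table.
Deliberately independent of the package's own cube/ODE evaluation path.
"""

import xml.etree.ElementTree as ET

MATHML_NS = "{http://www.w3.org/1998/Math/MathML}"
SBML_NS = "{http://www.sbml.org/sbml/level3/version2/core}"


def _strip(tag):
    return tag.split("}", 1)[1] if "}" in tag else tag


def compile_math(node):
    """MathML element -> f(env: dict[str, float]) -> float."""
    tag = _strip(node.tag)
    if tag == "math":
        children = list(node)
        assert len(children) == 1
        return compile_math(children[0])
    if tag == "ci":
        name = node.text.strip()
        return lambda env: env[name]
    if tag == "cn":
        value = float(node.text.strip())
        return lambda env: value
    if tag == "apply":
        children = list(node)
        op = _strip(children[0].tag)
        args = [compile_math(c) for c in children[1:]]
        if op == "plus":
            return lambda env: sum(a(env) for a in args)
        if op == "times":
            def product(env):
                out = 1.0
                for a in args:
                    out *= a(env)
                return out
            return product
        if op == "minus":
            if len(args) == 1:
                return lambda env: -args[0](env)
            return lambda env: args[0](env) - args[1](env)
        if op == "divide":
            return lambda env: args[0](env) / args[1](env)
        if op == "power":
            return lambda env: args[0](env) ** args[1](env)
        raise ValueError(f"unsupported MathML operator {op!r}")
    raise ValueError(f"unsupported MathML node {tag!r}")


def sbml_to_rhs(document: str):
    """Parse an exported SBML document into (species_ids, f(x) -> dx/dt)."""
    root = ET.fromstring(document)
    model = root.find(f"{SBML_NS}model")
    species = [
        el.attrib["id"]
        for el in model.find(f"{SBML_NS}listOfSpecies")
    ]
    env_const = {
        el.attrib["id"]: float(el.attrib["value"])
        for el in model.find(f"{SBML_NS}listOfParameters")
    }
    rules = {}
    for rule in model.find(f"{SBML_NS}listOfRules"):
        math = rule.find(f"{MATHML_NS}math")
        rules[rule.attrib["variable"]] = compile_math(math)

    def rhs(x):
        env = dict(env_const)
        env.update(zip(species, x))
        return [rules[s](env) for s in species]

    return species, rhs
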