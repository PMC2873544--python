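"""Native JSON persistence and tabular exports.

Model schema::

    {
      "species": ["X", "Y", ...],
      "rules": {"X": {"inputs": ["X", "Y"], "table": [1, 0, 1, 1]}, ...},
      "parameters": {"tau": {"X": 1.0},
                     "hill": {"X<-Y": {"n": 3.0, "k": 0.5}}},   # optional
      "compartments": {"compartments": 6,
                       "intercompartment": ["Fgf8"],
                       "include_self": false}                    # optional
    }

Truth tables are flattened in C order with the rule's first input as the
slowest-varying index.
"""

from __future__ import annotations

import csv
import io as _io
import json
from typing import NamedTuple

import numpy as np

from .compartments import CompartmentSpec
from .cubes import HillParameters
from .model import BooleanModel, UpdateRule
from .ode import ParameterSet


class FormatError(ValueError):
    """Schema violation; the message carries a JSON pointer to the field."""

    def __init__(self, pointer: str, message: str):
        self.pointer = pointer
        super().__init__(f"{pointer}: {message}")


class ModelBundle(NamedTuple):
    model: BooleanModel
    params: ParameterSet | None
    compartments: CompartmentSpec | None


# --- serialization -------------------------------------------------------

def model_to_dict(
    model: BooleanModel,
    params: ParameterSet | None = None,
    compartments: CompartmentSpec | None = None,
) -> dict:
    doc: dict = {
        "species": list(model.species),
        "rules": {
            name: {
                "inputs": list(rule.inputs),
                "table": [int(v) for v in rule.table.ravel()],
            }
            for name, rule in model.rules.items()
        },
    }
    if params is not None:
        doc["parameters"] = {
            "tau": {s: float(v) for s, v in params.tau.items()},
            "hill": {
                f"{t}<-{i}": {"n": float(p.n), "k": float(p.k)}
                for (t, i), p in params.hill.items()
            },
        }
    if compartments is not None:
        doc["compartments"] = {
            "compartments": compartments.n_compartments,
            "intercompartment": sorted(compartments.intercompartment),
            "include_self": compartments.include_self,
        }
    return doc


def dict_to_model(doc: dict) -> ModelBundle:
    if not isinstance(doc, dict):
        raise FormatError("/", "document must be a JSON object")
    species = doc.get("species")
    if not isinstance(species, list) or not all(isinstance(s, str) for s in species):
        raise FormatError("/species", "must be a list of species names")
    rules_doc = doc.get("rules", {})
    if not isinstance(rules_doc, dict):
        raise FormatError("/rules", "must be an object keyed by species")
    rules: dict[str, UpdateRule] = {}
    for name, entry in rules_doc.items():
        ptr = f"/rules/{name}"
        if not isinstance(entry, dict):
            raise FormatError(ptr, "must be an object")
        inputs = entry.get("inputs")
        table = entry.get("table")
        if not isinstance(inputs, list):
            raise FormatError(f"{ptr}/inputs", "must be a list")
        if not isinstance(table, list):
            raise FormatError(f"{ptr}/table", "must be a list")
        if len(table) != 2 ** len(inputs):
            raise FormatError(
                f"{ptr}/table",
                f"length {len(table)} != 2^{len(inputs)} for {len(inputs)} inputs",
            )
        if any(v not in (0, 1) for v in table):
            raise FormatError(f"{ptr}/table", "entries must be 0 or 1")
        try:
            rules[name] = UpdateRule(name, tuple(inputs), np.array(table))
        except ValueError as exc:
            raise FormatError(ptr, str(exc)) from exc
    try:
        model = BooleanModel(tuple(species), rules)
    except ValueError as exc:
        raise FormatError("/", str(exc)) from exc

    params = None
    if "parameters" in doc:
        pdoc = doc["parameters"]
        if not isinstance(pdoc, dict):
            raise FormatError("/parameters", "must be an object")
        hill: dict[tuple[str, str], HillParameters] = {}
        for key, entry in pdoc.get("hill", {}).items():
            if "<-" not in key:
                raise FormatError(
                    f"/parameters/hill/{key}", "key must be 'target<-input'"
                )
            target, input_ = key.split("<-", 1)
            try:
                hill[(target, input_)] = HillParameters(
                    float(entry["n"]), float(entry["k"])
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise FormatError(f"/parameters/hill/{key}", str(exc)) from exc
        try:
            params = ParameterSet(
                tau={s: float(v) for s, v in pdoc.get("tau", {}).items()},
                hill=hill,
            )
        except ValueError as exc:
            raise FormatError("/parameters/tau", str(exc)) from exc

    compartments = None
    if "compartments" in doc:
        cdoc = doc["compartments"]
        try:
            compartments = CompartmentSpec(
                n_compartments=int(cdoc["compartments"]),
                intercompartment=frozenset(cdoc.get("intercompartment", [])),
                include_self=bool(cdoc.get("include_self", False)),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError("/compartments", str(exc)) from exc

    return ModelBundle(model, params, compartments)


def save_model(
    path: str,
    model: BooleanModel,
    params: ParameterSet | None = None,
    compartments: CompartmentSpec | None = None,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model_to_dict(model, params, compartments), fh, indent=2)
        fh.write("\n")


def load_model(path: str) -> ModelBundle:
    with open(path, encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError("/", f"invalid JSON: {exc}") from exc
    return dict_to_model(doc)


# --- tabular exports -----------------------------------------------------

def states_to_csv(states, species, path: str | None = None) -> str:
    """One state per row, header = species names; returns the CSV text."""
    buf = _io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(species)
    for state in states:
        writer.writerow(list(state))
    text = buf.getvalue()
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def trajectory_to_csv(traj, path: str | None = None) -> str:
    """Time-course CSV: a ``t`` column followed by one column per species."""
    buf = _io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["t", *traj.species])
    for t, row in zip(traj.t, traj.y):
        writer.writerow([repr(float(t)), *[repr(float(v)) for v in row]])
    text = buf.getvalue()
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text
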