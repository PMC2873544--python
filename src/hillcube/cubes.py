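"""Continuous homologues of Boolean update functions.

Three transforms of a truth table B over the unit hypercube:

* **BooleCube** — the unique multilinear interpolation of B, exact at all
  corners:  B̄(x̄) = Σ_{c∈{0,1}^d} B(c) · Π_j (c_j x̄_j + (1−c_j)(1−x̄_j)).
* **HillCube** — the BooleCube evaluated on Hill-transformed inputs
  f(x) = x^n / (x^n + k^n), one (n, k) pair per interaction; switch-like
  but f(1) < 1, so corners are only approached.
* **normalized HillCube** — each Hill term divided by its value at 1,
  restoring exact agreement with B at every corner.

n is the Hill coefficient (cooperativity, slope; any n ≥ 1 accepted) and
k ∈ (0, 1) the threshold at which activation is half-maximal (f(k) = 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce

import numpy as np

from .model import UpdateRule

METHODS = ("boolecube", "hillcube", "hillcubenorm")


class CubeError(ValueError):
    """Invalid cube-evaluation input."""


@dataclass(frozen=True)
class HillParameters:
    """Hill coefficient n (dimensionless, ≥ 1) and threshold k ∈ (0, 1)."""

    n: float
    k: float

    def __post_init__(self):
        if not self.n >= 1:
            raise CubeError(f"Hill coefficient n must be >= 1, got {self.n}")
        if not 0 < self.k < 1:
            raise CubeError(f"Hill threshold k must be in (0, 1), got {self.k}")


@dataclass(frozen=True)
class ContinuousRule:
    """An update rule with one :class:`HillParameters` per input and a
    method tag selecting the transform."""

    rule: UpdateRule
    params: tuple[HillParameters, ...]
    method: str

    def __post_init__(self):
        if self.method not in METHODS:
            raise CubeError(f"unknown method {self.method!r}; choose from {METHODS}")
        params = tuple(self.params)
        object.__setattr__(self, "params", params)
        if self.method != "boolecube" and len(params) != self.rule.indegree:
            raise CubeError(
                f"rule {self.rule.target!r}: {len(params)} Hill parameter sets "
                f"for in-degree {self.rule.indegree}"
            )

    def __call__(self, xbar) -> float:
        return evaluate_cube(self, xbar)


def hill(x: float, p: HillParameters) -> float:
    """Sigmoidal activation x^n / (x^n + k^n); hill(0) := 0 (the limit)."""
    x = float(x)
    if x == 0.0:
        return 0.0
    xn = x**p.n
    return xn / (xn + p.k**p.n)


def boolecube(rule: UpdateRule, xbar) -> float:
    """Multilinear interpolation of ``rule.table`` at x̄ ∈ [0, 1]^d.

    Evaluated by explicit corner summation: the table is contracted with
    the outer product of the per-coordinate weights (1−x̄_j, x̄_j).
    """
    x = np.asarray(xbar, dtype=float).reshape(-1)
    if x.size != rule.indegree:
        raise CubeError(
            f"rule {rule.target!r}: expected {rule.indegree} coordinates, "
            f"got {x.size}"
        )
    if x.size and (x.min() < -1e-12 or x.max() > 1 + 1e-12):
        raise CubeError(f"input coordinates must lie in [0, 1]: {x}")
    if rule.indegree == 0:
        return float(rule.table)
    weights = reduce(
        np.multiply.outer, (np.array([1.0 - xj, xj]) for xj in x)
    )
    return float(np.sum(rule.table * weights))


def hillcube(crule: ContinuousRule, xbar) -> float:
    """BooleCube composed with per-input Hill functions."""
    x = np.asarray(xbar, dtype=float).reshape(-1)
    transformed = [hill(xj, p) for xj, p in zip(x, crule.params, strict=True)]
    return boolecube(crule.rule, transformed)


def normalized_hillcube(crule: ContinuousRule, xbar) -> float:
    """HillCube with each Hill term normalized by its value at 1, making
    the transform agree with the Boolean table at every corner."""
    x = np.asarray(xbar, dtype=float).reshape(-1)
    transformed = [
        hill(xj, p) / hill(1.0, p) for xj, p in zip(x, crule.params, strict=True)
    ]
    return boolecube(crule.rule, transformed)


def evaluate_cube(crule: ContinuousRule, xbar) -> float:
    """Dispatch on the rule's method tag."""
    if crule.method == "boolecube":
        return boolecube(crule.rule, xbar)
    if crule.method == "hillcube":
        return hillcube(crule, xbar)
    return normalized_hillcube(crule, xbar)
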