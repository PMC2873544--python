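"""Assembly of the continuous system dx̄_i/dt = (B̄_i(x̄) − x̄_i) / τ_i.

Each species follows an activation term — one of the three cube transforms
of its Boolean rule — balanced by first-order decay with life-time τ_i.
Species without a rule are constant boundary conditions by default (their
derivative is pinned to 0); with ``decay_inputs=True`` they instead decay
to zero.  Defaults mirror common practice for these conversions:
n = 3, k = 0.5 per interaction and τ = 1 per species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cubes import METHODS, ContinuousRule, HillParameters, boolecube, evaluate_cube
from .model import BooleanModel, ModelError

logger = logging.getLogger(__name__)

DEFAULT_N = 3.0
DEFAULT_K = 0.5
DEFAULT_TAU = 1.0


@dataclass
class ParameterSet:
    """Per-species life-times and per-interaction Hill parameters.

    ``hill`` is keyed by the ordered pair (target, input), so the same
    regulator may act with different (n, k) on different targets.
    """

    tau: dict[str, float] = field(default_factory=dict)
    hill: dict[tuple[str, str], HillParameters] = field(default_factory=dict)

    def __post_init__(self):
        for name, value in self.tau.items():
            if not value > 0:
                raise ModelError(f"life-time tau[{name!r}] must be > 0, got {value}")

    def set_hill(self, target: str, input_: str, n: float | None = None,
                 k: float | None = None) -> None:
        """Override n and/or k for one interaction, keeping the other value."""
        current = self.hill.get((target, input_), HillParameters(DEFAULT_N, DEFAULT_K))
        self.hill[(target, input_)] = HillParameters(
            current.n if n is None else n, current.k if k is None else k
        )


def default_parameters(model: BooleanModel) -> ParameterSet:
    """n = 3, k = 0.5 for every interaction; τ = 1 for every species."""
    return ParameterSet(
        tau={s: DEFAULT_TAU for s in model.species},
        hill={
            pair: HillParameters(DEFAULT_N, DEFAULT_K)
            for pair in model.interactions()
        },
    )


class VectorField:
    """The assembled autonomous system: callable ``vf(t, x) -> dx/dt``.

    ``x`` is the state vector ordered like ``model.species``, with values
    in [0, 1]^N.  The time argument is accepted (solver contract) but
    unused.
    """

    def __init__(
        self,
        model: BooleanModel,
        method: str,
        params: ParameterSet,
        decay_inputs: bool = False,
        _identity_hill: bool = False,
    ):
        if method not in METHODS:
            raise ModelError(f"unknown method {method!r}; choose from {METHODS}")
        self.model = model
        self.species = model.species
        self.method = method
        self.decay_inputs = decay_inputs
        self._identity_hill = _identity_hill
        index = {s: i for i, s in enumerate(model.species)}
        self._tau = np.array(
            [_complete_tau(params, s) for s in model.species], dtype=float
        )
        self._rules: list[tuple[int, np.ndarray, ContinuousRule] | None] = []
        for i, name in enumerate(model.species):
            rule = model.rules.get(name)
            if rule is None:
                self._rules.append(None)
                continue
            idx = np.array([index[inp] for inp in rule.inputs], dtype=np.intp)
            hill_params = tuple(
                _complete_hill(params, name, inp) for inp in rule.inputs
            )
            self._rules.append((i, idx, ContinuousRule(rule, hill_params, method)))

    @property
    def n_species(self) -> int:
        return len(self.species)

    def activation(self, x: np.ndarray) -> np.ndarray:
        """The continuous homologue B̄_i evaluated per species (inputless
        species report their current value, giving zero net derivative)."""
        x = np.asarray(x, dtype=float)
        out = np.empty_like(x)
        for i, entry in enumerate(self._rules):
            if entry is None:
                out[i] = x[i]
                continue
            _, idx, crule = entry
            xin = np.clip(x[idx], 0.0, 1.0)  # guard solver overshoot
            if self._identity_hill:
                out[i] = boolecube(crule.rule, xin)
            else:
                out[i] = evaluate_cube(crule, xin)
        return out

    def __call__(self, t: float, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_species,):
            raise ModelError(
                f"state has shape {x.shape}, expected ({self.n_species},)"
            )
        dx = (self.activation(x) - x) / self._tau
        for i, entry in enumerate(self._rules):
            if entry is None:
                dx[i] = -x[i] / self._tau[i] if self.decay_inputs else 0.0
        return dx


def build_vector_field(
    model: BooleanModel,
    method: str,
    params: ParameterSet | None = None,
    decay_inputs: bool = False,
) -> VectorField:
    """Build the continuous system for a model with the chosen transform.

    Missing parameter entries are completed from the defaults with a logged
    warning rather than an error.
    """
    if params is None:
        params = default_parameters(model)
    return VectorField(model, method, params, decay_inputs=decay_inputs)


def _complete_tau(params: ParameterSet, species: str) -> float:
    try:
        return params.tau[species]
    except KeyError:
        logger.warning("tau[%s] missing; using default %.3g", species, DEFAULT_TAU)
        return DEFAULT_TAU


def _complete_hill(params: ParameterSet, target: str, input_: str) -> HillParameters:
    try:
        return params.hill[(target, input_)]
    except KeyError:
        logger.warning(
            "Hill parameters for %s<-%s missing; using defaults n=%.3g k=%.3g",
            target, input_, DEFAULT_N, DEFAULT_K,
        )
        return HillParameters(DEFAULT_N, DEFAULT_K)
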