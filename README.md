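# hillcube

Qualitative Boolean models of gene regulation are easy to build — each
species is on or off, and logical rules (`X = X || ~Y`) say how regulators
combine — but they cannot express intermediate expression levels,
continuous transitions or time scales. `hillcube` converts a Boolean model
into a continuous ODE system that keeps the logical structure while adding
quantitative dynamics, for systems biologists who start from coarse
regulatory knowledge and want a simulatable, exportable model.

## The conversion

For each species *i* with Boolean update function
*B_i(x_{i1}, …, x_{id})*, the continuous system is

    dx̄_i/dt = ( B̄_i(x̄_{i1}, …, x̄_{id}) − x̄_i ) / τ_i ,   x̄ ∈ [0,1]^N

where τ_i is the species' life-time and B̄_i is a continuous homologue of
B_i, built in one of three ways:

* **BooleCube** — the unique multilinear interpolation of the truth table,

      B̄(x̄) = Σ_{c ∈ {0,1}^d} B(c) · Π_j ( c_j x̄_j + (1−c_j)(1−x̄_j) ),

  exact at every corner of the unit hypercube.
* **HillCube** — the BooleCube evaluated on Hill-transformed inputs
  f(x) = x^n / (x^n + k^n), one (n, k) per interaction: n sets the
  steepness (cooperativity), k the threshold with f(k) = 0.5.
* **normalized HillCube** — each Hill term divided by f(1), restoring
  exact corner agreement, so every Boolean steady state is an equilibrium
  of the continuous system.

Around the conversion the package provides Boolean-equation parsing,
GraphML interaction-graph/hypergraph import, synchronous Boolean analysis
(steady states, state-transition graph, attractors), expansion of a
single-cell model into a linear row of compartments coupled through
secreted factors, continuous stable-state discovery with basin labels,
an ensemble model-selection screen (does a model hold a given expression
pattern?), and export to SBML (rate rules) or MATLAB/R/Python ODE scripts.

## Worked example: the mutual inhibitory switch

Two lineage factors repress each other and activate themselves — the
classic stem-cell fate switch:

```python
import numpy as np
from hillcube import (parse_boolean_equations, boolean_steady_states,
                      build_vector_field, find_stable_states, phase_grid)

model = parse_boolean_equations("X = X || ~Y\nY = Y || ~X")
print(boolean_steady_states(model))
# [(0, 1), (1, 0), (1, 1)]

vf = build_vector_field(model, "hillcubenorm")   # defaults n=3, k=0.5, tau=1
result = find_stable_states(vf, phase_grid(11, 2))
print(result.n_states)          # 3
print(np.round(result.states))  # [[ 1.  0.]
                                #  [ 1.  1.]
                                #  [ 0.  1.]]
```

The discrete model has three fixed points; the converted continuous
system has three stable states sitting at those corners. The `(1, 1)`
state is the undecided "priming" state; the other two are the committed
lineages, and `result.labels` tells which basin each of the 121 grid
initial conditions falls into.

The same analyses are available from the shell:

```
hillcube convert switch.txt -o switch.json
hillcube steadystates switch.json
hillcube basins switch.json --method hillcubenorm --grid 11
hillcube export switch.json --to sbml -o switch.xml
```

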