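# Methods

## Model and conversion

A Boolean model is a set of N named species, each with at most one update
rule B_i over an ordered list of inputs. Rules are stored as truth-table
hypercubes: d-dimensional 0/1 arrays with edge length 2, the first input
being the slowest-varying index. This layout makes table lookups O(1) and
keeps the cost of model construction at O(2^d) in the largest in-degree d,
not in N; a configurable cap (default d ≤ 16) rejects tables that would
not fit that budget. Species without a rule are constant model inputs:
the discrete update leaves them unchanged and the continuous derivative
is pinned to 0 (a `decay_inputs` flag switches to plain decay instead,
for users who prefer unregulated species to relax to zero).

The continuous system attaches to each species the ODE

    dx̄_i/dt = (B̄_i(x̄_inputs) − x̄_i) / τ_i

with a first-order decay of life-time τ_i and one of three activation
homologues:

* `boolecube` — multilinear interpolation, evaluated by explicit corner
  summation (the truth table contracted with the outer product of the
  per-coordinate weights (1−x̄_j, x̄_j)). Transparent and exactly
  testable; no factorization tricks are attempted at these problem sizes.
* `hillcube` — corner summation over Hill-transformed inputs
  f(x) = x^n/(x^n+k^n). f(0) is defined as exactly 0 (the limit), so any
  n ≥ 1 is admissible. Since f(1) = 1/(1+k^n) < 1, corners are
  approached but not hit; for sufficiently sharp transforms a continuous
  steady state exists near every Boolean one (verified by property test
  at n = 100, and at n = 10 for the switch model).
* `hillcubenorm` — each Hill term divided by f(1). Corner agreement is
  then exact, so every Boolean steady state is an equilibrium of the
  continuous system by construction.

The identical decay form is used for all three methods; the method only
changes the activation term.

### Parameters

| parameter | meaning | default | units |
|---|---|---|---|
| n | Hill cooperativity (slope) | 3 | dimensionless |
| k | activation threshold, f(k) = 0.5 | 0.5 | fraction of maximal level |
| τ | species life-time | 1 | time |

Hill parameters are keyed by the ordered pair (target, input), so one
regulator may act with different kinetics on different targets. Missing
entries are completed from the defaults with a logged warning rather than
an error, so a bare model is always simulatable.

## Generic logic and graph import

Interaction graphs carry only activation/inhibition signs, so a rule must
be synthesized when a node has several regulators. The generic logic is
(A_1 ⊖ … ⊖ A_m) ⊙ ¬(I_1 ⊗ … ⊗ I_n) with the operator triple
(⊖, ⊙, ⊗) ∈ {AND, OR}³, default (OR, AND, OR): on iff at least one
activator and no inhibitor is active. A species listed as both activator
and inhibitor stays in both lists (no deduplication); with the default
triple such a species then acts as a vetoing inhibitor. GraphML nodes
labelled `&` are AND-hypernodes for sum-of-products rules: each `&` node
contributes one conjunctive term, direct edges contribute literals, and
terms combine by OR. The dialect is deliberately minimal (edge attribute
`sign` ∈ {+,−}, label `&`), not tied to any particular graph editor's
styling extensions.

Equation text uses `&&`, `||`, `~` (aliases AND/OR/NOT), precedence
NOT > AND > OR with left associativity — the conventional choice, fixed
here because signed-graph formats and rule texts in the wild rarely state
it.

## Discrete analysis

Synchronous updating only: all species apply their rules simultaneously.
Steady states, the state-transition graph (out-degree exactly 1) and
terminal cycles are found by exhaustive enumeration of all 2^N states
(vectorized over integer-encoded states; guarded by a limit, default
N ≤ 22). Attractors are the cycles of the successor map, found by
three-color path walking; reported states are ordered lexicographically
so outputs are deterministic.

## Multicompartment expansion

A single-cell model is replicated along a linear, non-periodic row of C
compartments (copies named `<species>_<c>`, 1-based, compartment-major
order). Wherever a species flagged intercompartmental appears as a rule
input, it is replaced by the OR of its copies in the adjacent
compartments c−1 and c+1 (one neighbor at the ends); this models a
secreted factor acting on neighboring cells. The compartment's own copy
is excluded by default — secretion acts outward — with `include_self`
for the inclusive variant, since either reading is defensible. A
single-compartment row with flags substitutes constant 0 and warns.

## Continuous analysis

Integration uses scipy's LSODA with rtol 1e−6 / atol 1e−9 (the sharp
n = 100 systems are stiff; LSODA switches automatically). Inputs to the
cube evaluation are clipped to [0,1] to absorb solver overshoot at the
boundary; forward invariance of the unit cube is property-tested.

Stable-state discovery integrates every initial condition to t_end
(default 50), keeps endpoints whose vector-field L∞ norm is below 1e−6
(a derivative criterion is robust to slow transients near saddles, where
an endpoint-difference criterion stalls), single-linkage clusters them
in the L∞ metric at tolerance 1e−2 (coarse enough to merge solver
jitter, fine enough to separate corner attractors), and takes cluster
means as representatives. Each representative is then checked for linear
stability via a central-difference Jacobian: representatives with an
eigenvalue real part above 1e−5 are excluded and their initials labelled
separately. This filter exists because trajectories started exactly on
an invariant manifold converge numerically to saddles — e.g. the
diagonal of the AND-switch in the dimer-binding regime below, whose
symmetric saddle has an unstable eigenvalue of order 1e−4 — and would
otherwise be reported as stable states. The tolerance is positive so
genuine continua of equilibria (zero eigenvalues) are kept.

The dimer-binding regime (AND switch, n = 2 everywhere, self-activation
k = 0.01, mutual inhibition k = 0.5, τ = 1) is analysed with the
non-normalized HillCube: fixed-point analysis shows the two interior
attractors with both factors appreciably expressed exist only for the
non-normalized transform (the normalized variant's attractors in this
regime sit at the (1,0)/(0,1) corners). Those interior attractors are
weakly attracting (leading eigenvalue ≈ −1.2e−3), so the grid analysis
integrates to t_end = 5000 — long enough for endpoints to meet the
derivative tolerance, the analogue of simulating "until the system has
settled".

Activity read-out: a species is on iff x̄_i > threshold, strictly; the
default threshold is the global 0.5 (equal to the default k), and a
per-species mode uses each species' mean k over the interactions it
drives. The pattern-maintenance predicate embeds an on/off pattern as
the continuous initial state (on→1, off→0), integrates (default
t_end = 10, several life-times — enough for a wrong constant rule to
cross threshold since deviations relax like e^(−t/τ)), and accepts the
model iff the endpoint's activity pattern equals the target everywhere.

## Synthetic data and what the tests show

Random Boolean models (uniform in-degree up to a cap, uniform random
inputs and truth tables) drive the property tests; they probe logical
and dynamical correctness across rule space, not biological realism — no
degree-distribution, canalization or sign structure of real regulatory
networks is emulated, so passing tests certify the conversion machinery,
not any biological claim. The multicompartment selection screen is
exercised on constructed boundary-pattern fixtures: nine 4-species
variants (files/functions labelled MHB-style; built around mutual
Otx2/Gbx2 inhibition and intercompartmental mutual Fgf8/Wnt1
maintenance, the replicated 6-compartment pattern verified to be a
discrete fixed point by computation) against 100 random 4-species
models. The screen sizes (9 + 100, t_end = 10) are the package's fixture
choice; the discriminative result — all constructed models maintain the
pattern, random ones essentially never do — is the tested property.

## Export

SBML Level 3 Version 2 uses one rate rule per species rather than
reactions: the converted system is a phenomenological ODE, not
mass-action chemistry, and rate rules state exactly that. Activation
MathML is emitted fully expanded (corner sum over Hill-transformed
inputs) so documents are self-contained; parameters are global
(`tau_X`, `n_X_Y`, `k_X_Y`) and species ids are sanitized to valid SIds
with a reported mapping. The test suite re-parses exported documents
with an independent MathML interpreter and integrates them, requiring
endpoint agreement with the package's own integration to 1e−4. Script
export (MATLAB, R, Python dialects; pluggable templates) assigns each
Hill term to one local variable per (target, input) so scripts stay
readable; the Python dialect is additionally exec'd in tests and checked
pointwise against the vector field.

## Known limitations

* Exhaustive discrete analysis is exponential in N (limit 22); there is
  no sampling-based attractor search.
* Only synchronous discrete updating; no asynchronous or probabilistic
  schemes.
* Rows of compartments are 1-D and non-periodic; no 2-D grids or
  diffusion gradients.
* No parameter fitting, bifurcation analysis or continuation — exported
  SBML/scripts are the intended bridge to tools that do these.
* `find_stable_states` only sees attractors reachable from the supplied
  initials; limit cycles are reported as non-converged, not
  characterized.
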