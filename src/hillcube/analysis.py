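"""Continuous analysis: integration, stable states, basins, pattern screen.

Stable-state discovery integrates a set of initial conditions, keeps the
endpoints whose vector-field norm is below a convergence tolerance,
single-linkage clusters them in the L∞ metric, and verifies linear
stability of each cluster representative with a finite-difference
Jacobian.  Endpoints parked at unstable equilibria (e.g. trajectories
started exactly on a saddle's invariant manifold) are thereby excluded
from the reported stable states; their initials keep a distinct label.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.integrate import solve_ivp
from scipy.spatial.distance import pdist

from .model import BooleanModel, ModelError
from .ode import ParameterSet, VectorField, build_vector_field

#: Basin label for initial conditions that did not converge by t_end.
UNCONVERGED = -1
#: Basin label for endpoints resting at a non-stable equilibrium.
UNSTABLE = -2


@dataclass
class Trajectory:
    """Time grid and state matrix (time × species) of one integration."""

    t: np.ndarray
    y: np.ndarray
    species: tuple[str, ...]

    def endpoint(self) -> np.ndarray:
        return self.y[-1]


@dataclass
class StableStateSet:
    """Clustered continuous stable states with basin labels per initial.

    ``labels[i]`` indexes ``states`` for the i-th initial condition, or is
    :data:`UNCONVERGED` / :data:`UNSTABLE`.
    """

    states: np.ndarray  # (n_states, N) cluster-mean representatives
    labels: np.ndarray  # (n_initials,) int
    initials: np.ndarray  # (n_initials, N)
    cluster_tol: float
    species: tuple[str, ...]

    @property
    def n_states(self) -> int:
        return len(self.states)


def integrate(
    vf: VectorField,
    x0,
    t_end: float,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    t_eval=None,
    method: str = "LSODA",
) -> Trajectory:
    """Adaptive-step integration of the system from ``x0`` over [0, t_end].

    The returned grid includes t = 0 and t = t_end.
    """
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (vf.n_species,):
        raise ModelError(f"x0 has shape {x0.shape}, expected ({vf.n_species},)")
    if not t_end > 0:
        raise ModelError("t_end must be > 0")
    sol = solve_ivp(
        vf, (0.0, float(t_end)), x0, method=method, rtol=rtol, atol=atol,
        t_eval=t_eval,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed for {vf.method} system of "
            f"{vf.n_species} species: {sol.message}"
        )
    return Trajectory(sol.t, sol.y.T, vf.species)


def phase_grid(m: int = 11, n_species: int = 2) -> np.ndarray:
    """Uniform m^d grid of initial conditions over [0, 1]^n_species."""
    axis = np.linspace(0.0, 1.0, m)
    return np.array(list(itertools.product(axis, repeat=n_species)))


def jacobian(vf: VectorField, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference Jacobian of the vector field at ``x``."""
    x = np.asarray(x, dtype=float)
    n = x.size
    J = np.empty((n, n))
    for j in range(n):
        lo, hi = x.copy(), x.copy()
        # stay inside [0,1] where the cubes are defined
        hi[j] = min(x[j] + eps, 1.0)
        lo[j] = max(x[j] - eps, 0.0)
        h = hi[j] - lo[j]
        J[:, j] = (vf(0.0, hi) - vf(0.0, lo)) / h
    return J


def is_linearly_stable(
    vf: VectorField, x: np.ndarray, tol: float = 1e-5
) -> bool:
    """True iff no Jacobian eigenvalue has real part above ``tol``.

    The small positive tolerance keeps marginal (zero-eigenvalue) cases,
    such as continua of equilibria, while rejecting genuine saddles.
    """
    eig = np.linalg.eigvals(jacobian(vf, x))
    return bool(np.max(eig.real) < tol)


def find_stable_states(
    vf: VectorField,
    initials,
    t_end: float = 50.0,
    cluster_tol: float = 1e-2,
    deriv_tol: float = 1e-6,
    stability_tol: float = 1e-5,
    rtol: float = 1e-6,
) -> StableStateSet:
    """Discover continuous stable states reachable from ``initials``.

    Non-convergence (vector-field L∞ norm ≥ ``deriv_tol`` at t_end) is
    reported via the label, never raised.
    """
    initials = np.atleast_2d(np.asarray(initials, dtype=float))
    if initials.size == 0:
        raise ModelError("initials must be nonempty")
    endpoints = np.empty_like(initials)
    converged = np.zeros(len(initials), dtype=bool)
    for i, x0 in enumerate(initials):
        end = integrate(vf, x0, t_end, rtol=rtol).endpoint()
        endpoints[i] = end
        converged[i] = np.max(np.abs(vf(0.0, end))) < deriv_tol

    labels = np.full(len(initials), UNCONVERGED, dtype=int)
    conv_idx = np.flatnonzero(converged)
    reps: list[np.ndarray] = []
    if conv_idx.size:
        pts = endpoints[conv_idx]
        if len(pts) == 1:
            cluster_ids = np.array([1])
        else:
            cluster_ids = fcluster(
                linkage(pdist(pts, metric="chebyshev"), method="single"),
                t=cluster_tol, criterion="distance",
            )
        for cid in np.unique(cluster_ids):
            members = conv_idx[cluster_ids == cid]
            rep = endpoints[members].mean(axis=0)
            if is_linearly_stable(vf, rep, tol=stability_tol):
                labels[members] = len(reps)
                reps.append(rep)
            else:
                labels[members] = UNSTABLE
    states = np.array(reps) if reps else np.empty((0, initials.shape[1]))
    return StableStateSet(
        states=states, labels=labels, initials=initials,
        cluster_tol=cluster_tol, species=vf.species,
    )


def plot_phase_plane(
    vf: VectorField,
    result: StableStateSet,
    t_end: float = 50.0,
    dims: tuple[int, int] = (0, 1),
    path: str | None = None,
):
    """Convenience: 2-species phase-plane projection of the trajectories
    behind a :class:`StableStateSet`, colored by basin.  Requires
    matplotlib; returns the figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    i, j = dims
    fig, ax = plt.subplots(figsize=(5, 5))
    cmap = plt.get_cmap("tab10")
    for x0, label in zip(result.initials, result.labels):
        traj = integrate(vf, x0, t_end)
        color = cmap(label % 10) if label >= 0 else "0.6"
        ax.plot(traj.y[:, i], traj.y[:, j], color=color, lw=0.7)
    for state in result.states:
        ax.plot(state[i], state[j], "ko", ms=6)
    ax.set_xlabel(result.species[i])
    ax.set_ylabel(result.species[j])
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
    return fig


def activity_pattern(state, threshold=0.5) -> np.ndarray:
    """Boolean on/off readout: component i is on iff x̄_i > threshold_i.

    ``threshold`` may be a scalar or per-species vector, each in (0, 1).
    """
    state = np.asarray(state, dtype=float)
    thr = np.asarray(threshold, dtype=float)
    if np.any(thr <= 0) or np.any(thr >= 1):
        raise ModelError("threshold(s) must lie in (0, 1)")
    return state > thr


def species_thresholds(model: BooleanModel, params: ParameterSet) -> np.ndarray:
    """Per-species activity thresholds: the mean incoming Hill k of each
    species (as a regulation *source*), falling back to 0.5 for species
    that regulate nothing."""
    out = np.empty(model.n_species)
    for i, name in enumerate(model.species):
        ks = [p.k for (t, s), p in params.hill.items() if s == name]
        out[i] = float(np.mean(ks)) if ks else 0.5
    return out


def pattern_is_maintained(
    model: BooleanModel,
    pattern,
    method: str = "hillcubenorm",
    params: ParameterSet | None = None,
    t_end: float = 10.0,
    threshold=0.5,
    rtol: float = 1e-6,
) -> bool:
    """Ensemble-selection predicate: does the model hold an expression
    pattern?

    The pattern (on→1, off→0) is embedded as the continuous initial state,
    the converted system is integrated to ``t_end``, and the endpoint's
    activity pattern is compared against the target everywhere.
    """
    pattern = np.asarray(pattern, dtype=bool).reshape(-1)
    if pattern.size != model.n_species:
        raise ModelError(
            f"pattern has {pattern.size} entries for {model.n_species} species"
        )
    vf = build_vector_field(model, method, params)
    end = integrate(vf, pattern.astype(float), t_end, rtol=rtol).endpoint()
    return bool(np.array_equal(activity_pattern(end, threshold), pattern))
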