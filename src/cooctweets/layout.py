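"""Force-directed spring-embedder layout, implemented from the physics up.

Each link is a spring obeying Hooke's law (restoring force proportional to
the displacement from its natural length) and each node is a like-charged
particle obeying Coulomb's law (inverse-square repulsion between *all* node
pairs, linked or not).  The drawing is the equilibrium of this system,
found by damped gradient-like relaxation: positions move along the net
force, and the step is halved whenever a move would increase the maximum
force magnitude, so the residual-force sequence is non-increasing.

The physical model alone is translation invariant and, for a disconnected
graph, unbounded (components repel each other forever); an optional weak
centering force pins the drawing.  Constants are design choices scaled so
the two-node equilibrium distance is O(1); none of them is prescribed by
the underlying physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "LayoutParams",
    "Layout",
    "LayoutDivergenceError",
    "initial_placement",
    "compute_forces",
    "relax",
    "reduce_overlap",
    "SpringLayout",
    "two_node_equilibrium_distance",
]

_EPS = 1e-9  # distance regularization for coincident points


class LayoutDivergenceError(RuntimeError):
    """Relaxation produced non-finite coordinates."""


@dataclass(frozen=True)
class LayoutParams:
    """Constants of the spring/charge system and of its relaxation.

    spring_constant
        Hooke constant k_s of every link (force per unit displacement).
    natural_length
        Rest length L of every spring; sets the target edge length.
    repulsion_constant
        Coulomb constant k_r; repulsion magnitude between two nodes at
        distance d is k_r / d**2.
    step_size
        Initial displacement per unit force; adaptively halved.
    max_iterations
        Upper bound on accepted relaxation steps.
    force_tolerance
        Convergence threshold on the maximum per-node force magnitude.
    centering_strength
        Weak spring toward the origin; ``None`` means "auto": on (0.01) for
        disconnected graphs, off for connected ones.
    seed
        Seed for the initial placement (and jitter).
    """

    spring_constant: float = 1.0
    natural_length: float = 1.0
    repulsion_constant: float = 1.0
    step_size: float = 0.05
    max_iterations: int = 10_000
    force_tolerance: float = 1e-4
    centering_strength: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("spring_constant", "natural_length", "step_size", "force_tolerance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.repulsion_constant < 0:  # zero = uncharged nodes, springs only
            raise ValueError("repulsion_constant must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.centering_strength is not None and self.centering_strength < 0:
            raise ValueError("centering_strength must be >= 0")

    def resolved_centering(self, graph: nx.Graph) -> float:
        if self.centering_strength is not None:
            return self.centering_strength
        if graph.number_of_nodes() and nx.number_connected_components(graph) > 1:
            return 0.01
        return 0.0


@dataclass
class Layout:
    """Node coordinates at (approximate) force equilibrium."""

    positions: dict[object, tuple[float, float]]
    residual: float = 0.0
    iterations_used: int = 0
    metadata: dict = field(default_factory=dict)

    def as_array(self, nodes: Sequence) -> np.ndarray:
        return np.array([self.positions[n] for n in nodes], dtype=float)


def _as_matrix(nodes: Sequence, positions: Mapping) -> np.ndarray:
    return np.array([positions[n] for n in nodes], dtype=float)


def initial_placement(nodes: Sequence, seed: int = 0) -> Layout:
    """Uniform placement in the unit square; coincident points re-jittered."""
    nodes = list(nodes)
    if not nodes:
        raise ValueError("initial_placement requires at least one node")
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0.0, 1.0, size=(len(nodes), 2))
    # collisions have probability 0 but would break the force law; re-jitter
    for _ in range(100):
        _, index = np.unique(pts.round(12), axis=0, return_index=True)
        if len(index) == len(nodes):
            break
        dup = np.setdiff1d(np.arange(len(nodes)), index)
        pts[dup] += rng.uniform(-1e-6, 1e-6, size=(len(dup), 2))
    return Layout({n: (float(x), float(y)) for n, (x, y) in zip(nodes, pts)})


def _forces_matrix(
    pts: np.ndarray,
    edge_index: np.ndarray,
    params: LayoutParams,
    centering: float,
) -> np.ndarray:
    n = len(pts)
    forces = np.zeros_like(pts)
    if n > 1:
        diff = pts[:, None, :] - pts[None, :, :]          # x_i - x_j
        dist = np.linalg.norm(diff, axis=-1)
        np.fill_diagonal(dist, 1.0)
        dist = np.maximum(dist, _EPS)
        unit = diff / dist[..., None]
        # Coulomb: push i away from every j
        rep = params.repulsion_constant / dist**2
        np.fill_diagonal(rep, 0.0)
        forces += (rep[..., None] * unit).sum(axis=1)
        # Hooke: springs along edges only
        if len(edge_index):
            i, j = edge_index[:, 0], edge_index[:, 1]
            d = dist[i, j]
            # positive magnitude pulls i toward j (d > L), negative pushes away
            mag = params.spring_constant * (d - params.natural_length)
            f = -mag[:, None] * unit[i, j]
            np.add.at(forces, i, f)
            np.add.at(forces, j, -f)
    if centering > 0:
        forces -= centering * pts
    return forces


def compute_forces(
    graph: nx.Graph,
    layout: Layout,
    params: LayoutParams = LayoutParams(),
) -> dict[object, np.ndarray]:
    """Net force on every node at the given positions.

    Spring terms act along links, Coulomb terms between all node pairs, and
    the optional centering term toward the origin; Newton's third law holds
    pairwise for the spring and Coulomb terms.
    """
    nodes = list(graph.nodes)
    pts = _as_matrix(nodes, layout.positions)
    idx = {n: i for i, n in enumerate(nodes)}
    edge_index = np.array(
        [(idx[u], idx[v]) for u, v in graph.edges], dtype=int
    ).reshape(-1, 2)
    centering = params.resolved_centering(graph)
    forces = _forces_matrix(pts, edge_index, params, centering)
    return {n: forces[i] for i, n in enumerate(nodes)}


def relax(graph: nx.Graph, params: LayoutParams = LayoutParams()) -> Layout:
    """Relax the spring/charge system to (approximate) equilibrium.

    Damped updates ``position += step * force`` with backtracking: a step
    that would increase the maximum force magnitude is retried at half the
    step size, so the residual sequence is non-increasing.  Terminates when
    the residual drops below ``force_tolerance`` or after
    ``max_iterations`` accepted steps.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot lay out an empty graph")
    nodes = list(graph.nodes)
    start = initial_placement(nodes, params.seed)
    pts = start.as_array(nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    edge_index = np.array(
        [(idx[u], idx[v]) for u, v in graph.edges], dtype=int
    ).reshape(-1, 2)
    centering = params.resolved_centering(graph)

    step = params.step_size
    forces = _forces_matrix(pts, edge_index, params, centering)
    residual = float(np.linalg.norm(forces, axis=1).max())
    iterations = 0
    while residual >= params.force_tolerance and iterations < params.max_iterations:
        accepted = False
        for _ in range(60):  # backtracking budget per iteration
            candidate = pts + step * forces
            if not np.isfinite(candidate).all():
                step *= 0.5
                continue
            new_forces = _forces_matrix(candidate, edge_index, params, centering)
            new_residual = float(np.linalg.norm(new_forces, axis=1).max())
            if np.isfinite(new_residual) and new_residual <= residual:
                pts, forces, residual = candidate, new_forces, new_residual
                accepted = True
                # cautiously regrow the step so one bad region does not
                # freeze progress for the rest of the run
                step = min(step * 1.1, params.step_size)
                break
            step *= 0.5
        iterations += 1
        if not accepted:
            break  # stuck at numerical precision; report current residual
    if not np.isfinite(pts).all():
        raise LayoutDivergenceError(
            f"non-finite coordinates after {iterations} iterations "
            f"(residual {residual!r}); try a smaller step_size"
        )
    return Layout(
        positions={n: (float(x), float(y)) for n, (x, y) in zip(nodes, pts)},
        residual=residual,
        iterations_used=iterations,
        metadata={
            "centering_strength": centering,
            "final_step": step,
            "converged": residual < params.force_tolerance,
            "seed": params.seed,
        },
    )


def reduce_overlap(
    layout: Layout,
    graph: nx.Graph,
    min_separation: float = 0.05,
    max_passes: int = 100,
    seed: int = 0,
) -> Layout:
    """Greedy push-apart until all node pairs are at least ``min_separation``.

    A best-effort stand-in for the manual de-overlapping pass a human does
    on a finished drawing: coincident or too-close nodes are moved apart
    symmetrically along their axis; the relative arrangement is preserved
    best-effort and no guarantee is made about link crossings.
    """
    nodes = list(graph.nodes)
    pts = layout.as_array(nodes)
    rng = np.random.default_rng(seed)
    moved = False
    for _ in range(max_passes):
        any_close = False
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                delta = pts[i] - pts[j]
                d = float(np.linalg.norm(delta))
                # small margin so independent distance computations cannot
                # land an ulp below the threshold
                if d >= min_separation * (1 + 1e-6):
                    continue
                any_close = True
                moved = True
                if d < _EPS:
                    direction = rng.standard_normal(2)
                    direction /= np.linalg.norm(direction)
                else:
                    direction = delta / d
                # overshoot the threshold slightly so settled pairs sit
                # strictly above it under any distance computation
                push = (min_separation * 1.001 - d) / 2
                pts[i] += push * direction
                pts[j] -= push * direction
        if not any_close:
            break
    if not moved:
        return layout
    meta = dict(layout.metadata)
    meta["overlap_reduced"] = True
    meta["min_separation"] = min_separation
    return Layout(
        positions={n: (float(x), float(y)) for n, (x, y) in zip(nodes, pts)},
        residual=layout.residual,
        iterations_used=layout.iterations_used,
        metadata=meta,
    )


def two_node_equilibrium_distance(params: LayoutParams, *, tol: float = 1e-12) -> float:
    """Equilibrium separation of one spring-linked pair, by bisection.

    Solves k_s*(d - L) = k_r / d**2, i.e. the positive root of
    k_s*d**3 - k_s*L*d**2 - k_r = 0, which always lies beyond the natural
    length.  Used for scale checks; tests verify :func:`relax` against an
    independent root finder.
    """
    ks, L, kr = params.spring_constant, params.natural_length, params.repulsion_constant

    def f(d: float) -> float:
        return ks * d**3 - ks * L * d**2 - kr

    lo, hi = L, L + 1.0
    while f(hi) < 0:
        hi *= 2.0
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


class SpringLayout(BaseEstimator):
    """Estimator interface over the spring-embedder relaxation.

    ``fit(G)`` relaxes graph ``G`` and exposes ``positions_`` (node ->
    (x, y)), ``embedding_`` (array in ``G.nodes`` order), ``residual_`` and
    ``n_iter_``; ``fit_transform`` returns the embedding array.  With
    ``min_separation`` set, a greedy de-overlap pass follows relaxation.
    """

    def __init__(
        self,
        spring_constant: float = 1.0,
        natural_length: float = 1.0,
        repulsion_constant: float = 1.0,
        step_size: float = 0.05,
        max_iterations: int = 10_000,
        force_tolerance: float = 1e-4,
        centering_strength: float | None = None,
        min_separation: float | None = None,
        random_state: int = 0,
    ):
        self.spring_constant = spring_constant
        self.natural_length = natural_length
        self.repulsion_constant = repulsion_constant
        self.step_size = step_size
        self.max_iterations = max_iterations
        self.force_tolerance = force_tolerance
        self.centering_strength = centering_strength
        self.min_separation = min_separation
        self.random_state = random_state

    def _params(self) -> LayoutParams:
        return LayoutParams(
            spring_constant=self.spring_constant,
            natural_length=self.natural_length,
            repulsion_constant=self.repulsion_constant,
            step_size=self.step_size,
            max_iterations=self.max_iterations,
            force_tolerance=self.force_tolerance,
            centering_strength=self.centering_strength,
            seed=self.random_state,
        )

    def fit(self, X: nx.Graph, y=None) -> "SpringLayout":
        layout = relax(X, self._params())
        if self.min_separation is not None:
            layout = reduce_overlap(
                layout, X, min_separation=self.min_separation, seed=self.random_state
            )
        self.layout_ = layout
        self.positions_ = layout.positions
        self.embedding_ = layout.as_array(list(X.nodes))
        self.residual_ = layout.residual
        self.n_iter_ = layout.iterations_used
        return self

    def fit_transform(self, X: nx.Graph, y=None) -> np.ndarray:
        return self.fit(X).embedding_
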