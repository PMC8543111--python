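"""Activity-biased network propagation over a PPI network.

Gene expression at one age is mapped onto the nodes of the entire network
as strictly positive activity values.  A random walk with restart then
diffuses the activity: from node *i* the walker steps to a neighbour *j*
with probability proportional to *j*'s activity, and at every step it
restarts with probability ``r`` to a node drawn proportionally to
activity.  The stationary visit probabilities ``p`` turn into *edge flux*:
the probability mass flowing through each interaction per step, which
serves as the age-specific importance weight of that interaction.

With restart probability ``r`` the non-restart mass is ``1 - r``, so the
undirected edge fluxes always sum to ``1 - r`` — a useful internal
consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .network import DataError, ExpressionSeries, Snapshot

__all__ = [
    "ActivityAssignment",
    "WalkParams",
    "EdgeFluxResult",
    "ConvergenceError",
    "assign_activities",
    "transition_matrix",
    "stationary_distribution",
    "edge_flux",
    "netwalk_weight_snapshot",
    "default_epsilon",
]


class ConvergenceError(RuntimeError):
    """Power iteration failed to reach tolerance within max_iterations."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class WalkParams:
    """Random-walk-with-restart parameters.

    restart_probability
        Probability of jumping back to the activity-weighted restart
        distribution at each step; strictly inside (0, 1).
    """

    restart_probability: float = 0.15
    tolerance: float = 1e-10
    max_iterations: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 < self.restart_probability < 1.0:
            raise ValueError("restart_probability must lie strictly inside (0, 1)")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass(frozen=True)
class ActivityAssignment:
    """Strictly positive per-node activity values for one age.

    ``option1`` gives measured expression to active genes only and the dummy
    value ``epsilon`` to everything else; ``option2`` gives measured
    expression to every measured gene (active or not) and ``epsilon`` only
    to unmeasured network nodes.
    """

    values: dict
    option: str
    epsilon: float

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.values.values()):
            raise DataError("activity values must all be strictly positive")


def default_epsilon(expr_at_age: "np.ndarray | list[float]") -> float:
    """Dummy activity: 1% of the smallest positive measured expression."""
    arr = np.asarray(expr_at_age, dtype=float)
    pos = arr[np.isfinite(arr) & (arr > 0)]
    if pos.size == 0:
        return 1e-4
    return 0.01 * float(pos.min())


def assign_activities(
    expr: ExpressionSeries,
    age: str,
    net: nx.Graph,
    option: str = "option2",
    epsilon: float | None = None,
) -> ActivityAssignment:
    """Map expression at *age* onto the nodes of *net* as positive activities.

    If the raw values would leave any node below ``epsilon`` (e.g. negative
    log-ratios), all values are shifted up so the minimum equals ``epsilon``.
    """
    if age not in expr.values.columns:
        raise KeyError(f"age {age!r} not in expression series")
    if option not in ("option1", "option2"):
        raise ValueError(f"option must be 'option1' or 'option2', got {option!r}")
    col = expr.expression_at(age)
    if epsilon is None:
        epsilon = default_epsilon(col.to_numpy())
    if epsilon <= 0:
        raise ValueError("epsilon must be strictly positive")

    if option == "option1":
        informative = expr.active_genes(age)
    else:
        informative = set(col.index[col.notna()])

    values = {}
    for node in net.nodes:
        if node in informative and not np.isnan(col.get(node, np.nan)):
            values[node] = float(col[node])
        else:
            values[node] = epsilon
    lo = min(values.values())
    if lo < epsilon:
        shift = epsilon - lo
        values = {g: v + shift for g, v in values.items()}
    return ActivityAssignment(values=values, option=option, epsilon=epsilon)


def transition_matrix(net: nx.Graph, act: ActivityAssignment):
    """Row-stochastic transition matrix of the activity-biased walk.

    ``T[i, j] = value(j) / sum of values over neighbours of i`` for each
    neighbour *j* of *i*, 0 elsewhere.  The network must be connected (no
    isolated nodes), so every row has at least one neighbour and sums to 1.

    Returns ``(nodes, T)`` where *nodes* fixes the row/column order.
    """
    if net.number_of_nodes() == 0:
        raise DataError("empty network")
    if not nx.is_connected(net):
        raise DataError("network must be connected for propagation")
    nodes = sorted(net.nodes, key=str)
    index = {n: i for i, n in enumerate(nodes)}
    vals = np.array([act.values[n] for n in nodes], dtype=float)
    rows, cols, data = [], [], []
    for u in nodes:
        i = index[u]
        nbrs = [index[v] for v in net[u]]
        denom = vals[nbrs].sum()
        for j in nbrs:
            rows.append(i)
            cols.append(j)
            data.append(vals[j] / denom)
    T = sp.csr_matrix((data, (rows, cols)), shape=(len(nodes), len(nodes)))
    return nodes, T


def stationary_distribution(
    T: sp.spmatrix, act_values: np.ndarray, params: WalkParams
) -> np.ndarray:
    """Stationary visit probabilities of the walk with restart.

    Solves the fixed point ``p = (1 - r) T' p + r q`` by power iteration,
    where ``q`` is the activity-proportional restart distribution.  Raises
    :class:`ConvergenceError` if the L1 residual does not drop below
    ``params.tolerance`` within ``params.max_iterations``.
    """
    vals = np.asarray(act_values, dtype=float)
    q = vals / vals.sum()
    r = params.restart_probability
    Tt = T.T.tocsr()
    p = q.copy()
    residual = np.inf
    for _ in range(params.max_iterations):
        p_new = (1.0 - r) * (Tt @ p) + r * q
        residual = float(np.abs(p_new - p).sum())
        p = p_new
        if residual <= params.tolerance:
            p /= p.sum()
            return p
    raise ConvergenceError(
        f"power iteration did not converge (residual {residual:.3e} after "
        f"{params.max_iterations} iterations)",
        residual,
    )


@dataclass(frozen=True)
class EdgeFluxResult:
    """Weighted snapshot of per-edge flux plus the stationary distribution."""

    snapshot: Snapshot
    stationary: dict
    residual: float


def edge_flux(
    net: nx.Graph,
    nodes: list,
    T: sp.spmatrix,
    p: np.ndarray,
    params: WalkParams,
    age_label: str = "flux",
) -> EdgeFluxResult:
    """Per-edge flux: ``f(i->j) + f(j->i)`` with ``f(i->j) = p_i (1-r) T_ij``.

    Summed over undirected edges the fluxes equal ``1 - r`` (the walker's
    non-restart probability mass), up to the iteration tolerance.
    """
    index = {n: i for i, n in enumerate(nodes)}
    r = params.restart_probability
    Tc = T.tocsr()
    out = nx.Graph()
    out.add_nodes_from(net.nodes)
    for u, v in net.edges:
        i, j = index[u], index[v]
        f = p[i] * (1.0 - r) * Tc[i, j] + p[j] * (1.0 - r) * Tc[j, i]
        out.add_edge(u, v, weight=float(f))
    residual = abs(sum(d["weight"] for _, _, d in out.edges(data=True)) - (1.0 - r))
    stationary = {n: float(p[index[n]]) for n in nodes}
    return EdgeFluxResult(
        snapshot=Snapshot(age_label=age_label, graph=out),
        stationary=stationary,
        residual=residual,
    )


def netwalk_weight_snapshot(
    net: nx.Graph,
    expr: ExpressionSeries,
    age: str,
    option: str = "option2",
    params: WalkParams | None = None,
    epsilon: float | None = None,
) -> Snapshot:
    """One age-specific weighted snapshot over every edge of *net*.

    Composition of activity assignment, transition matrix construction,
    stationary solve, and edge-flux computation.
    """
    params = params or WalkParams()
    act = assign_activities(expr, age, net, option=option, epsilon=epsilon)
    nodes, T = transition_matrix(net, act)
    vals = np.array([act.values[n] for n in nodes], dtype=float)
    p = stationary_distribution(T, vals, params)
    result = edge_flux(net, nodes, T, p, params, age_label=age)
    return Snapshot(age_label=age, graph=result.snapshot.graph)
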