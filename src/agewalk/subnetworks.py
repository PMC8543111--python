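"""Construction of the eight aging-specific (sub)network variants.

From one entire context-unspecific PPI network and an age-series
expression table we derive:

* ``entire`` — the input network itself (static, unweighted);
* ``induced_dynamic`` / ``induced_static`` — per-age induced subgraphs on
  the active genes, and their node/edge union;
* ``netwalk_dynamic`` / ``netwalk_static`` — propagation-weighted snapshots
  thresholded to their top edges, and the union of those snapshots;
* ``w_netwalk_dynamic_nondiff`` — all propagation snapshots with weights
  jointly normalized to [0.01, 1] (no edge removed);
* ``w_netwalk_dynamic`` — the differential dynamic network: for each pair
  of consecutive normalized snapshots, each edge gets the symmetric
  percentage change of its weight, bounded in [-100, 100];
* ``w_netwalk_static_star`` — propagation on age-aggregated activity,
  weighted, no thresholding;
* ``netwalk_static_star`` — ``w_netwalk_static_star`` thresholded so its
  edge count matches ``netwalk_static``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .network import (
    DataError,
    DynamicNetwork,
    ExpressionSeries,
    Snapshot,
)
from .propagation import WalkParams, netwalk_weight_snapshot

logger = logging.getLogger(__name__)

__all__ = [
    "SubnetworkSuite",
    "induced_snapshot",
    "build_induced_dynamic",
    "aggregate_static",
    "threshold_snapshot",
    "normalize_weights_global",
    "differential_weight",
    "build_differential_dynamic",
    "aggregate_expression",
    "build_suite",
    "write_suite",
    "read_suite",
]


def induced_snapshot(entire: nx.Graph, active: set, age_label: str = "snapshot") -> Snapshot:
    """Vertex-induced subgraph of *entire* on the active genes.

    Active genes absent from the network are ignored (with a warning).
    """
    extra = set(active) - set(entire.nodes)
    if extra:
        logger.warning(
            "%d active gene(s) not in the network are ignored (e.g. %s)",
            len(extra),
            sorted(map(str, extra))[:3],
        )
    keep = set(active) & set(entire.nodes)
    sub = nx.Graph()
    sub.add_nodes_from(keep)
    sub.add_edges_from((u, v) for u, v in entire.edges if u in keep and v in keep)
    return Snapshot(age_label=age_label, graph=sub)


def build_induced_dynamic(entire: nx.Graph, expr: ExpressionSeries) -> DynamicNetwork:
    """One induced snapshot per age, in age order."""
    snaps = []
    for age in expr.ages:
        active = expr.active_genes(age)
        if not active:
            logger.warning("no active genes at age %s; snapshot is empty", age)
        snaps.append(induced_snapshot(entire, active, age_label=age))
    return DynamicNetwork(snapshots=snaps, weighted=False)


def aggregate_static(dyn: DynamicNetwork) -> nx.Graph:
    """Node and edge union over all snapshots; weights are discarded."""
    out = nx.Graph()
    for snap in dyn:
        out.add_nodes_from(snap.graph.nodes)
        out.add_edges_from(snap.graph.edges)
    return out


def threshold_snapshot(ws: Snapshot, rule: tuple) -> Snapshot:
    """Keep only highly weighted edges of a weighted snapshot.

    ``rule`` is ``("top_k", k)`` or ``("min_weight", w)``.  For ``top_k``,
    all edges tied with the k-th largest weight are kept, so the result is
    deterministic and order-independent.  Kept edges lose their weights;
    nodes are the endpoints of kept edges.
    """
    kind, value = rule
    edges = list(ws.graph.edges(data="weight"))
    if any(w is None for _, _, w in edges):
        raise DataError("threshold_snapshot requires a weighted snapshot")
    if kind == "top_k":
        k = int(value)
        if k >= len(edges):
            if k > len(edges):
                logger.warning(
                    "top_k=%d exceeds edge count %d; keeping all edges", k, len(edges)
                )
            kept = edges
        elif k <= 0:
            kept = []
        else:
            weights = sorted((w for _, _, w in edges), reverse=True)
            cut = weights[k - 1]
            kept = [(u, v, w) for u, v, w in edges if w >= cut]
    elif kind == "min_weight":
        kept = [(u, v, w) for u, v, w in edges if w >= float(value)]
    else:
        raise ValueError(f"unknown threshold rule {kind!r}")
    out = nx.Graph()
    out.add_edges_from((u, v) for u, v, _ in kept)
    return Snapshot(age_label=ws.age_label, graph=out)


def normalize_weights_global(dyn: DynamicNetwork) -> DynamicNetwork:
    """Linearly rescale all weights, jointly over snapshots, into [0.01, 1].

    The map is order-preserving; the global minimum maps to 0.01 and the
    global maximum to 1.0.  If all weights are equal, every weight is set
    to 1.0 (degenerate case, warned).
    """
    if not dyn.weighted or dyn.n == 0:
        raise DataError("normalize_weights_global requires a weighted dynamic network")
    all_w = [
        d["weight"] for snap in dyn for _, _, d in snap.graph.edges(data=True)
    ]
    if not all_w:
        raise DataError("no edges to normalize")
    lo, hi = min(all_w), max(all_w)
    snaps = []
    for snap in dyn:
        g = nx.Graph()
        g.add_nodes_from(snap.graph.nodes)
        for u, v, d in snap.graph.edges(data=True):
            if hi == lo:
                w = 1.0
            else:
                w = 0.01 + 0.99 * (d["weight"] - lo) / (hi - lo)
            g.add_edge(u, v, weight=w)
        snaps.append(Snapshot(age_label=snap.age_label, graph=g, age_years=snap.age_years))
    if hi == lo:
        logger.warning("all weights equal (%g); normalized weights all set to 1.0", lo)
    return DynamicNetwork(snapshots=snaps, weighted=True)


def differential_weight(w_i: float, w_i1: float) -> float:
    """Symmetric percentage change from weight ``w_i`` to weight ``w_i1``.

    ``100 * (w_i1 - w_i) / (w_i1 + w_i)`` for strictly positive inputs;
    antisymmetric under argument swap and bounded in [-100, 100].
    """
    if w_i <= 0 or w_i1 <= 0:
        raise ValueError("differential_weight requires strictly positive weights")
    return (w_i1 - w_i) * 100.0 / (w_i1 + w_i)


def build_differential_dynamic(norm: DynamicNetwork) -> DynamicNetwork:
    """Differential snapshots between each pair of consecutive snapshots.

    The input must be a normalized weighted dynamic network whose snapshots
    all share one edge set; the output has N-1 snapshots over that edge set.
    """
    if norm.n < 2:
        raise DataError("need at least 2 snapshots to build differential network")
    edge_sets = [frozenset(map(frozenset, s.graph.edges)) for s in norm]
    if len(set(edge_sets)) != 1:
        raise DataError("differential network requires identical edge sets across snapshots")
    snaps = []
    for a, b in zip(norm.snapshots, norm.snapshots[1:]):
        g = nx.Graph()
        g.add_nodes_from(a.graph.nodes)
        for u, v, d in a.graph.edges(data=True):
            w = differential_weight(d["weight"], b.graph[u][v]["weight"])
            g.add_edge(u, v, weight=w)
        snaps.append(Snapshot(age_label=f"{a.age_label}-{b.age_label}", graph=g))
    return DynamicNetwork(snapshots=snaps, weighted=True)


def aggregate_expression(expr: ExpressionSeries, combine: str = "mean") -> ExpressionSeries:
    """Collapse the series to one pseudo-age (value: mean/max; active: OR)."""
    return expr.aggregate(combine=combine)


@dataclass
class SubnetworkSuite:
    """The eight (sub)network variants plus the non-differential dynamic."""

    entire: nx.Graph
    induced_dynamic: DynamicNetwork
    induced_static: nx.Graph
    netwalk_dynamic: DynamicNetwork
    netwalk_static: nx.Graph
    netwalk_static_star: nx.Graph
    w_netwalk_dynamic: DynamicNetwork
    w_netwalk_dynamic_nondiff: DynamicNetwork
    w_netwalk_static_star: nx.Graph

    MEMBER_NAMES = (
        "entire",
        "induced_dynamic",
        "induced_static",
        "netwalk_dynamic",
        "netwalk_static",
        "netwalk_static_star",
        "w_netwalk_dynamic",
        "w_netwalk_static_star",
    )

    def members(self) -> dict:
        """The eight variants under comparison (keyed by canonical name)."""
        return {name: getattr(self, name) for name in self.MEMBER_NAMES}

    def node_sets(self) -> dict:
        out = {}
        for name, member in self.members().items():
            if isinstance(member, DynamicNetwork):
                out[name] = member.node_union()
            else:
                out[name] = set(member.nodes)
        return out

    def common_nodes(self) -> set:
        sets = list(self.node_sets().values())
        common = sets[0].copy()
        for s in sets[1:]:
            common &= s
        return common

    def sizes(self) -> dict:
        """Average node/edge counts per member (snapshot average for dynamics)."""
        out = {}
        for name, member in self.members().items():
            if isinstance(member, DynamicNetwork):
                nodes = float(np.mean([s.graph.number_of_nodes() for s in member]))
                edges = float(np.mean([s.graph.number_of_edges() for s in member]))
                out[name] = {"nodes": nodes, "edges": edges, "snapshots": member.n}
            else:
                out[name] = {
                    "nodes": member.number_of_nodes(),
                    "edges": member.number_of_edges(),
                }
        return out


def build_suite(
    entire: nx.Graph,
    expr: ExpressionSeries,
    params: WalkParams | None = None,
    threshold_rule: tuple | None = None,
    option: str = "option2",
    combine: str = "mean",
) -> SubnetworkSuite:
    """Construct every suite member from the entire network and expression.

    ``threshold_rule`` governs how the unweighted propagation-based dynamic
    is cut from the weighted snapshots; the default keeps the top 25% of
    entire-network edges per snapshot (ties at the cut weight kept).
    """
    if entire.number_of_nodes() == 0:
        raise DataError("entire network is empty")
    if not nx.is_connected(entire):
        raise DataError("entire network must be connected")
    if len(expr.ages) < 2:
        raise DataError("need at least 2 ages to build a dynamic suite")
    params = params or WalkParams()
    if threshold_rule is None:
        threshold_rule = ("top_k", max(1, round(0.25 * entire.number_of_edges())))

    induced_dynamic = build_induced_dynamic(entire, expr)
    induced_static = aggregate_static(induced_dynamic)

    flux_snaps = [
        netwalk_weight_snapshot(entire, expr, age, option=option, params=params)
        for age in expr.ages
    ]
    flux_dynamic = DynamicNetwork(snapshots=flux_snaps, weighted=True)

    netwalk_dynamic = DynamicNetwork(
        snapshots=[threshold_snapshot(s, threshold_rule) for s in flux_dynamic],
        weighted=False,
    )
    netwalk_static = aggregate_static(netwalk_dynamic)

    nondiff = normalize_weights_global(flux_dynamic)
    w_netwalk_dynamic = build_differential_dynamic(nondiff)

    agg_expr = aggregate_expression(expr, combine=combine)
    star_flux = netwalk_weight_snapshot(
        entire, agg_expr, agg_expr.ages[0], option=option, params=params
    )
    star_norm = normalize_weights_global(
        DynamicNetwork(snapshots=[star_flux], weighted=True)
    )
    w_netwalk_static_star = star_norm[0].graph

    target = netwalk_static.number_of_edges()
    star_cut = threshold_snapshot(star_norm[0], ("top_k", target))
    got = star_cut.graph.number_of_edges()
    if got != target:
        logger.info(
            "netwalk_static_star edge count %d exceeds target %d due to weight ties",
            got,
            target,
        )
    netwalk_static_star = star_cut.graph

    return SubnetworkSuite(
        entire=entire,
        induced_dynamic=induced_dynamic,
        induced_static=induced_static,
        netwalk_dynamic=netwalk_dynamic,
        netwalk_static=netwalk_static,
        netwalk_static_star=netwalk_static_star,
        w_netwalk_dynamic=w_netwalk_dynamic,
        w_netwalk_dynamic_nondiff=nondiff,
        w_netwalk_static_star=w_netwalk_static_star,
    )


# ---------------------------------------------------------------------------
# suite serialization


def _write_dynamic(dyn: DynamicNetwork, outdir: Path, weighted: bool) -> list:
    from .network import write_edge_list

    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for i, snap in enumerate(dyn):
        path = outdir / f"{i:03d}_{snap.age_label}.tsv"
        write_edge_list(snap.graph, path, weighted=weighted)
        files.append(path.name)
    return files


def _read_dynamic(indir: Path, files: list, weighted: bool) -> DynamicNetwork:
    from .network import read_edge_list

    snaps = []
    for fname in files:
        age = fname.split("_", 1)[1].removesuffix(".tsv")
        g = read_edge_list(indir / fname, weighted=weighted)
        snaps.append(Snapshot(age_label=age, graph=g))
    return DynamicNetwork(snapshots=snaps, weighted=weighted)


def write_suite(suite: SubnetworkSuite, outdir, params: dict | None = None) -> dict:
    """Serialize every suite member as edge-list TSVs plus a JSON manifest.

    Dynamic members get one file per snapshot.  The manifest records file
    layout, per-member node/edge bookkeeping and the construction
    parameters, so any member can be reloaded or audited.
    """
    from .network import write_edge_list

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    weighted_members = {"w_netwalk_dynamic", "w_netwalk_dynamic_nondiff", "w_netwalk_static_star"}
    layout: dict = {}
    all_members = dict(suite.members())
    all_members["w_netwalk_dynamic_nondiff"] = suite.w_netwalk_dynamic_nondiff
    for name, member in all_members.items():
        weighted = name in weighted_members
        if isinstance(member, DynamicNetwork):
            files = _write_dynamic(member, outdir / name, weighted)
            layout[name] = {"kind": "dynamic", "weighted": weighted, "files": files}
        else:
            path = outdir / f"{name}.tsv"
            write_edge_list(member, path, weighted=weighted)
            layout[name] = {"kind": "static", "weighted": weighted, "files": [path.name]}
    manifest = {
        "layout": layout,
        "sizes": suite.sizes(),
        "params": params or {},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def read_suite(indir) -> SubnetworkSuite:
    """Reload a suite previously written by :func:`write_suite`."""
    from .network import read_edge_list

    indir = Path(indir)
    with open(indir / "manifest.json") as fh:
        manifest = json.load(fh)
    members: dict = {}
    for name, spec in manifest["layout"].items():
        if spec["kind"] == "dynamic":
            members[name] = _read_dynamic(indir / name, spec["files"], spec["weighted"])
        else:
            members[name] = read_edge_list(indir / spec["files"][0], weighted=spec["weighted"])
    return SubnetworkSuite(**members)
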