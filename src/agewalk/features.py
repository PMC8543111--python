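"""Weighted node features of dynamic and static networks.

A node's network position in a weighted dynamic network is characterized
through the *distribution of edge weights* in four neighbourhood types
around the node:

* T1 — edges from the node to its one-hop neighbours;
* T2 — edges among its one-hop neighbours;
* T3 — edges between one-hop and two-hop neighbours (two-hop = shortest
  path distance exactly 2);
* T4 — edges among two-hop neighbours;

plus ``ALL``, the concatenation of the four.  The weight distribution is
encoded either over the vocabulary of raw distinct weights (``nobin``,
after rounding) or over 200 unit-width bins spanning [-100, 100]
(``bin``).  Three approaches turn per-snapshot weight counts into a
feature vector:

1. concatenated per-snapshot count vectors (length ``W x N``);
2. the upper triangle of the Pearson correlation matrix of count vectors
   across snapshot pairs (length ``N(N-1)/2``);
3. per-snapshot Cramér--von Mises distance between the neighbourhood
   weight distribution and the pooled weight distribution of the whole
   dynamic network (length ``N``).

Crossing {approach} x {T1..T4, ALL} x {nobin, bin} yields the 30 dynamic
feature vectors, named ``Diff-nobin-2``, ``Diff-bin-cvm-all``, ... .
Static counterparts treat a weighted static network as a single-snapshot
dynamic.  Five conventional weighted dynamic centralities (strength,
clustering, closeness, betweenness, eigenvector) serve as comparators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .network import DataError, DynamicNetwork, Snapshot

logger = logging.getLogger(__name__)

__all__ = [
    "NEIGHBORHOOD_TYPES",
    "WeightVocabulary",
    "FeatureMatrix",
    "neighborhood_edges",
    "neighborhood_weights",
    "build_vocabulary",
    "bin_index",
    "weight_count_vector",
    "cramer_von_mises",
    "approach1_features",
    "approach2_features",
    "approach3_features",
    "all_proposed_features",
    "static_counterpart_features",
    "weighted_centrality_features",
]

NEIGHBORHOOD_TYPES = ("t1", "t2", "t3", "t4")
N_BINS = 200


# ---------------------------------------------------------------------------
# vocabulary and counting


def round_half_away(x, decimals: int):
    """Round half away from zero (symmetric), unlike numpy's banker's rounding."""
    arr = np.asarray(x, dtype=float)
    scale = 10.0 ** decimals
    return np.copysign(np.floor(np.abs(arr) * scale + 0.5) / scale, arr)


@dataclass(frozen=True)
class WeightVocabulary:
    """Ordered set of distinct (or binned) edge weights of a dynamic network."""

    encoding: str  # "raw" or "binned"
    values: tuple
    rounding_decimals: int | None = None

    @property
    def W(self) -> int:
        return len(self.values)


def build_vocabulary(
    dyn: DynamicNetwork, encoding: str = "raw", rounding_decimals: int = 2
) -> WeightVocabulary:
    """Vocabulary over all snapshots jointly.

    ``raw``: sorted distinct weights after rounding (half away from zero) to
    ``rounding_decimals``.  ``binned``: the fixed 200 unit bins on
    [-100, 100], identified by their left edges.
    """
    if not dyn.weighted:
        raise DataError("vocabulary requires a weighted dynamic network")
    if encoding == "binned":
        return WeightVocabulary(
            encoding="binned", values=tuple(float(b) for b in range(-100, 100))
        )
    if encoding != "raw":
        raise ValueError(f"unknown encoding {encoding!r}")
    weights = set()
    for snap in dyn:
        for _, _, d in snap.graph.edges(data=True):
            weights.add(float(round_half_away(d["weight"], rounding_decimals)))
    return WeightVocabulary(
        encoding="raw",
        values=tuple(sorted(weights)),
        rounding_decimals=rounding_decimals,
    )


def bin_index(w: float) -> int:
    """Index of the unit-width bin of *w* on [-100, 100].

    Bins are half-open ``[a, a+1)`` starting at -100; the last bin is
    closed so that ``w = 100`` lands in bin 199.
    """
    if w < -100.0 or w > 100.0:
        raise ValueError(f"weight {w} outside [-100, 100]")
    if w == 100.0:
        return N_BINS - 1
    return int(np.floor(w + 100.0))


def weight_count_vector(weights, vocab: WeightVocabulary) -> np.ndarray:
    """Counts of each vocabulary entry among *weights* (length W, sums to n)."""
    arr = np.asarray(list(weights), dtype=float)
    counts = np.zeros(vocab.W, dtype=float)
    if arr.size == 0:
        return counts
    if vocab.encoding == "raw":
        rounded = round_half_away(arr, vocab.rounding_decimals)
        vals = np.asarray(vocab.values)
        idx = np.searchsorted(vals, rounded)
        idx = np.clip(idx, 0, vocab.W - 1)
        ok = np.isclose(vals[idx], rounded)
        if not ok.all():
            raise DataError("weight not present in raw vocabulary")
        np.add.at(counts, idx, 1.0)
    else:
        for w in arr:
            counts[bin_index(float(w))] += 1.0
    return counts


# ---------------------------------------------------------------------------
# neighbourhoods


def neighborhood_edges(snap: Snapshot, v, t: str) -> set:
    """Edge set of neighbourhood type *t* around node *v* (frozenset pairs)."""
    g = snap.graph
    if v not in g:
        raise KeyError(f"node {v!r} not in snapshot {snap.age_label!r}")
    n1 = set(g[v])
    n2 = set()
    for u in n1:
        n2 |= set(g[u])
    n2 -= n1
    n2.discard(v)
    if t == "t1":
        return {frozenset((v, u)) for u in n1}
    if t == "t2":
        return {
            frozenset((a, b))
            for a in n1
            for b in g[a]
            if b in n1 and a != b
        }
    if t == "t3":
        return {
            frozenset((a, b))
            for a in n1
            for b in g[a]
            if b in n2
        }
    if t == "t4":
        return {
            frozenset((a, b))
            for a in n2
            for b in g[a]
            if b in n2 and a != b
        }
    raise ValueError(f"unknown neighbourhood type {t!r}")


def neighborhood_weights(snap: Snapshot, v, t: str) -> np.ndarray:
    """Weights of the neighbourhood-type edge set around *v*."""
    g = snap.graph
    out = []
    for e in neighborhood_edges(snap, v, t):
        a, b = tuple(e)
        out.append(g[a][b]["weight"])
    return np.asarray(out, dtype=float)


# ---------------------------------------------------------------------------
# feature matrices


@dataclass
class FeatureMatrix:
    """Gene-by-feature numeric matrix with provenance metadata."""

    name: str
    genes: list
    X: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.genes):
            raise DataError(
                f"feature matrix {self.name!r}: shape {self.X.shape} does not match "
                f"{len(self.genes)} genes"
            )
        declared = self.meta.get("length")
        if declared is not None and declared != self.X.shape[1]:
            raise DataError(
                f"feature matrix {self.name!r}: declared length {declared} != "
                f"actual {self.X.shape[1]}"
            )

    @property
    def length(self) -> int:
        return self.X.shape[1]

    def vector(self, gene) -> np.ndarray:
        return self.X[self.genes.index(gene)]

    def subset(self, genes) -> "FeatureMatrix":
        index = {g: i for i, g in enumerate(self.genes)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise DataError(f"genes missing from {self.name!r}: {sorted(missing)[:5]}")
        rows = [index[g] for g in genes]
        return FeatureMatrix(
            name=self.name, genes=list(genes), X=self.X[rows], meta=dict(self.meta)
        )


def _gene_universe(dyn: DynamicNetwork) -> list:
    return sorted(dyn.node_union(), key=str)


def _count_blocks(dyn, genes, types, vocab):
    """counts[g][t] = N x W count array for gene g, type t."""
    N = dyn.n
    blocks = {g: {t: np.zeros((N, vocab.W)) for t in types} for g in genes}
    for si, snap in enumerate(dyn):
        for g in genes:
            if g not in snap.graph:
                continue
            for t in types:
                w = neighborhood_weights(snap, g, t)
                blocks[g][t][si] = weight_count_vector(w, vocab)
    return blocks


def _types_for(t: str):
    return list(NEIGHBORHOOD_TYPES) if t == "all" else [t]


def approach1_features(
    dyn: DynamicNetwork, t: str, vocab: WeightVocabulary, name: str | None = None
) -> FeatureMatrix:
    """Concatenated per-snapshot weight-count vectors.

    Per-type length ``W x N``; for ``all``, the four type blocks are
    concatenated within each snapshot, giving ``W x 4 x N``.  A node absent
    from a snapshot contributes a zero block.
    """
    types = _types_for(t)
    genes = _gene_universe(dyn)
    N, W = dyn.n, vocab.W
    blocks = _count_blocks(dyn, genes, types, vocab)
    X = np.zeros((len(genes), W * len(types) * N))
    for gi, g in enumerate(genes):
        per_snap = [
            np.concatenate([blocks[g][ty][si] for ty in types]) for si in range(N)
        ]
        X[gi] = np.concatenate(per_snap)
    meta = {
        "approach": 1,
        "neighborhood": t,
        "encoding": vocab.encoding,
        "N": N,
        "W": W,
        "length": W * len(types) * N,
    }
    return FeatureMatrix(name=name or f"approach1-{t}", genes=genes, X=X, meta=meta)


def _pearson_upper(counts: np.ndarray) -> np.ndarray:
    """Upper triangle (excl. diagonal) of the N x N Pearson matrix of rows.

    Pairs involving a zero-variance row get correlation 0 (a constant count
    vector carries no co-variation signal).
    """
    N = counts.shape[0]
    sd = counts.std(axis=1)
    centered = counts - counts.mean(axis=1, keepdims=True)
    out = []
    for i in range(N):
        for j in range(i + 1, N):
            if sd[i] == 0.0 or sd[j] == 0.0:
                out.append(0.0)
            else:
                out.append(
                    float(
                        (centered[i] @ centered[j])
                        / (counts.shape[1] * sd[i] * sd[j])
                    )
                )
    return np.asarray(out)


def approach2_features(
    dyn: DynamicNetwork, t: str, vocab: WeightVocabulary, name: str | None = None
) -> FeatureMatrix:
    """Pearson correlations of weight counts between snapshot pairs.

    Per-type length ``N(N-1)/2``; ``all`` concatenates the four types.
    """
    if dyn.n < 2:
        raise DataError("approach 2 requires at least 2 snapshots")
    types = _types_for(t)
    genes = _gene_universe(dyn)
    N = dyn.n
    blocks = _count_blocks(dyn, genes, types, vocab)
    L = len(types) * N * (N - 1) // 2
    X = np.zeros((len(genes), L))
    for gi, g in enumerate(genes):
        X[gi] = np.concatenate([_pearson_upper(blocks[g][ty]) for ty in types])
    meta = {
        "approach": 2,
        "neighborhood": t,
        "encoding": vocab.encoding,
        "N": N,
        "W": vocab.W,
        "length": L,
    }
    return FeatureMatrix(name=name or f"approach2-{t}", genes=genes, X=X, meta=meta)


def cramer_von_mises(sample_a, sample_b) -> float:
    """Two-sample Cramér--von Mises statistic.

    ``T = n m / (n + m)^2 * sum over pooled points of (F_a - F_b)^2`` with
    empirical CDFs evaluated at the sample points.  Symmetric in its
    arguments; 0 for identical samples.
    """
    a = np.sort(np.asarray(list(sample_a), dtype=float))
    b = np.sort(np.asarray(list(sample_b), dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("cramer_von_mises requires non-empty samples")
    return _cvm_presorted(a, b)


def _cvm_presorted(a_sorted: np.ndarray, b_sorted: np.ndarray) -> float:
    n, m = a_sorted.size, b_sorted.size
    pooled = np.concatenate([a_sorted, b_sorted])
    Fa = np.searchsorted(a_sorted, pooled, side="right") / n
    Fb = np.searchsorted(b_sorted, pooled, side="right") / m
    return float(n * m / (n + m) ** 2 * np.sum((Fa - Fb) ** 2))


def _encode_sample(weights: np.ndarray, encoding: str) -> np.ndarray:
    if encoding == "binned":
        return np.asarray([bin_index(float(w)) for w in weights], dtype=float)
    return weights


def approach3_features(
    dyn: DynamicNetwork,
    t: str,
    encoding: str = "raw",
    name: str | None = None,
    reference: str = "pooled",
) -> FeatureMatrix:
    """Cramér--von Mises distance to the network-wide weight distribution.

    For each snapshot, the node's neighbourhood weights are compared to the
    pooled weights of all edges over all snapshots (``reference="pooled"``,
    the default) or of that snapshot only (``reference="per_snapshot"``).
    Per-type length ``N``; ``all`` concatenates the four types.  An empty
    neighbourhood contributes a distance of 0 (no evidence of deviation).
    """
    types = _types_for(t)
    genes = _gene_universe(dyn)
    N = dyn.n
    snap_weights = [
        np.asarray(
            [d["weight"] for _, _, d in snap.graph.edges(data=True)], dtype=float
        )
        for snap in dyn
    ]
    if reference == "pooled":
        ref = np.concatenate(snap_weights) if snap_weights else np.array([])
        refs = [np.sort(_encode_sample(ref, encoding))] * N
    elif reference == "per_snapshot":
        refs = [np.sort(_encode_sample(w, encoding)) for w in snap_weights]
    else:
        raise ValueError(f"unknown reference {reference!r}")
    X = np.zeros((len(genes), len(types) * N))
    for gi, g in enumerate(genes):
        col = 0
        for ty in types:
            for si, snap in enumerate(dyn):
                if g in snap.graph and refs[si].size:
                    w = neighborhood_weights(snap, g, ty)
                    if w.size:
                        X[gi, col] = _cvm_presorted(
                            np.sort(_encode_sample(w, encoding)), refs[si]
                        )
                col += 1
    meta = {
        "approach": 3,
        "neighborhood": t,
        "encoding": encoding,
        "N": N,
        "length": len(types) * N,
    }
    return FeatureMatrix(name=name or f"approach3-{t}", genes=genes, X=X, meta=meta)


def _feature_name(prefix: str, approach: int, encoding: str, t: str) -> str:
    enc = "nobin" if encoding == "raw" else "bin"
    infix = {1: "", 2: "-cor", 3: "-cvm"}[approach]
    suffix = t if t == "all" else t.lstrip("t")
    return f"{prefix}-{enc}{infix}-{suffix}"


def all_proposed_features(
    dyn: DynamicNetwork, rounding_decimals: int = 2, prefix: str = "Diff"
) -> dict:
    """The full set of 30 weighted dynamic feature matrices.

    {approach 1, 2, 3} x {T1..T4, ALL} x {raw, binned}, named in the
    ``Diff-{nobin|bin}[-cor|-cvm]-{1|2|3|4|all}`` convention.
    """
    out: dict = {}
    for encoding in ("raw", "binned"):
        vocab = build_vocabulary(dyn, encoding=encoding, rounding_decimals=rounding_decimals)
        for t in (*NEIGHBORHOOD_TYPES, "all"):
            for approach in (1, 2, 3):
                name = _feature_name(prefix, approach, encoding, t)
                if approach == 1:
                    fm = approach1_features(dyn, t, vocab, name=name)
                elif approach == 2:
                    fm = approach2_features(dyn, t, vocab, name=name)
                else:
                    fm = approach3_features(dyn, t, encoding=encoding, name=name)
                out[name] = fm
    return out


def static_counterpart_features(
    stat: nx.Graph,
    approach: int = 1,
    t: str = "t2",
    encoding: str = "raw",
    rounding_decimals: int = 2,
) -> FeatureMatrix:
    """Static analogue of a dynamic feature, on a weighted static network.

    The static network is treated as a single-snapshot dynamic (N = 1).
    Approach 2 is undefined for one snapshot, so such requests fall back to
    the approach-1 counterpart (logged); e.g. the static counterpart of a
    correlation feature on T2 is ``Static-nobin-2``.
    """
    dyn = DynamicNetwork(
        snapshots=[Snapshot(age_label="static", graph=stat)], weighted=True
    )
    eff_approach = approach
    if approach == 2:
        logger.info("approach-2 static counterpart falls back to approach 1")
        eff_approach = 1
    name = _feature_name("Static", eff_approach, encoding, t)
    if eff_approach == 1:
        vocab = build_vocabulary(dyn, encoding=encoding, rounding_decimals=rounding_decimals)
        return approach1_features(dyn, t, vocab, name=name)
    return approach3_features(dyn, t, encoding=encoding, name=name)


CENTRALITY_NAMES = ("DegC-wt", "ClusC-wt", "CloseC-wt", "BetwC-wt", "EigenC-wt")


def weighted_centrality_features(dyn: DynamicNetwork) -> dict:
    """Five conventional weighted dynamic centralities, one value per snapshot.

    Strength (weighted degree), weighted clustering (geometric-mean
    variant), harmonic closeness and betweenness with edge length
    1/weight, and eigenvector centrality of the weighted adjacency.  Meant
    for the non-differential normalized dynamic network, whose weights are
    strictly positive.
    """
    if not dyn.weighted:
        raise DataError("weighted centralities require a weighted dynamic network")
    genes = _gene_universe(dyn)
    N = dyn.n
    mats = {name: np.zeros((len(genes), N)) for name in CENTRALITY_NAMES}
    gidx = {g: i for i, g in enumerate(genes)}
    for si, snap in enumerate(dyn):
        g = snap.graph.copy()
        for u, v, d in g.edges(data=True):
            if d["weight"] <= 0:
                raise DataError("centralities require strictly positive weights")
            d["length"] = 1.0 / d["weight"]
        if not nx.is_connected(g) and g.number_of_nodes() > 0:
            logger.info(
                "snapshot %s is disconnected; closeness is per reachable set",
                snap.age_label,
            )
        strength = dict(g.degree(weight="weight"))
        clust = nx.clustering(g, weight="weight")
        n_nodes = g.number_of_nodes()
        harm = nx.harmonic_centrality(g, distance="length")
        close = {
            u: (harm[u] / (n_nodes - 1) if n_nodes > 1 else 0.0) for u in g.nodes
        }
        betw = nx.betweenness_centrality(g, weight="length", normalized=False)
        try:
            eig = nx.eigenvector_centrality_numpy(g, weight="weight")
        except (nx.NetworkXException, TypeError):
            eig = {u: 0.0 for u in g.nodes}
        for u in g.nodes:
            i = gidx[u]
            mats["DegC-wt"][i, si] = strength[u]
            mats["ClusC-wt"][i, si] = clust[u]
            mats["CloseC-wt"][i, si] = close[u]
            mats["BetwC-wt"][i, si] = betw[u]
            mats["EigenC-wt"][i, si] = eig[u]
    out = {}
    for name in CENTRALITY_NAMES:
        out[name] = FeatureMatrix(
            name=name,
            genes=genes,
            X=mats[name],
            meta={"approach": "centrality", "N": N, "length": N},
        )
    return out
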