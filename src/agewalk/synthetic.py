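"""Synthetic benchmark data with a plantable aging signal.

The generator emulates the study inputs: a heavy-tailed entire PPI
network (preferential attachment), a gene x age expression table, and
gene label lists.  A seeded subset of "aging" genes receives a monotone
age trend in log-expression of magnitude ``effect_size``; everything else
is stationary noise.  Because the trend acts on expression — not on any
downstream feature — their per-age activity and propagated edge weights
drift with age, so recovering the planted genes exercises the whole
inference pipeline, not just the classifier.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .network import (
    DataError,
    ExpressionSeries,
    LabelSet,
    write_edge_list,
    write_expression_table,
    write_gene_list,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_entire_network",
    "pick_planted_genes",
    "generate_expression",
    "generate_labels",
    "generate_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters of the synthetic benchmark.

    Defaults mirror the shape of the real inputs at desk scale: a
    heavy-tailed network of 300 genes, a 10-age expression series, 30
    aging-related genes and a ~1:5 positive:negative label imbalance.
    ``effect_size`` is the total monotone drift in log-expression over the
    age range, in units of ``noise_sd``-comparable log-expression.
    """

    n_genes: int = 300
    n_edges_target: int | None = None
    n_ages: int = 10
    n_aging_genes: int = 30
    n_negatives_per_positive: int = 5
    effect_size: float = 2.0
    noise_sd: float = 0.5
    baseline_log_mean: float = 1.0
    baseline_log_sd: float = 1.0
    cancer_rate_positives: float = 0.25
    cancer_rate_negatives: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if self.n_aging_genes >= self.n_genes:
            raise ValueError("n_aging_genes must be < n_genes")
        if self.n_ages < 2:
            raise ValueError("n_ages must be >= 2")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def _gene_names(n: int) -> list:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def generate_entire_network(cfg: SyntheticConfig) -> nx.Graph:
    """Seeded preferential-attachment network (largest connected component).

    The attachment parameter is derived from ``n_edges_target`` when given
    (edges ~ m * n), otherwise 2.  Preferential attachment yields the
    heavy-tailed degree distribution typical of PPI networks.
    """
    if cfg.n_edges_target is None:
        m = 2
    else:
        m = int(round(cfg.n_edges_target / cfg.n_genes))
        if m < 1 or m >= cfg.n_genes:
            raise DataError(
                f"edge target {cfg.n_edges_target} infeasible for {cfg.n_genes} genes"
            )
    g = nx.barabasi_albert_graph(cfg.n_genes, m, seed=cfg.seed)
    names = _gene_names(cfg.n_genes)
    g = nx.relabel_nodes(g, dict(enumerate(names)))
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    return g.subgraph(comps[0]).copy()


def pick_planted_genes(net: nx.Graph, cfg: SyntheticConfig) -> frozenset:
    """Seeded uniform sample of the aging genes to plant the signal into."""
    rng = np.random.default_rng(cfg.seed + 1)
    genes = sorted(net.nodes)
    chosen = rng.choice(len(genes), size=cfg.n_aging_genes, replace=False)
    return frozenset(genes[i] for i in sorted(chosen))


def generate_expression(
    net: nx.Graph, cfg: SyntheticConfig, planted: frozenset | None = None
) -> ExpressionSeries:
    """Lognormal baseline expression with a planted monotone age trend.

    log expr(g, t) = base_g + effect_size * x_t * [g planted] + N(0, noise_sd)
    with x_t running linearly from 0 to 1 over the ages.  Activity flags use
    the per-age mean rule.
    """
    if planted is None:
        planted = pick_planted_genes(net, cfg)
    rng = np.random.default_rng(cfg.seed + 2)
    genes = sorted(net.nodes)
    ages = [f"age{int(a):02d}" for a in np.linspace(20, 99, cfg.n_ages)]
    base = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=len(genes))
    x = np.linspace(0.0, 1.0, cfg.n_ages)
    is_planted = np.array([g in planted for g in genes], dtype=float)
    log_expr = (
        base[:, None]
        + cfg.effect_size * is_planted[:, None] * x[None, :]
        + rng.normal(0.0, cfg.noise_sd, size=(len(genes), cfg.n_ages))
    )
    values = pd.DataFrame(np.exp(log_expr), index=genes, columns=ages)
    return ExpressionSeries.from_values(values, activity_rule="mean")


def generate_labels(
    cfg: SyntheticConfig, planted: frozenset, gene_universe
) -> tuple:
    """Label set (positives = planted genes) plus a synthetic cancer list.

    Negatives are a seeded sample of non-planted genes
    (``n_negatives_per_positive`` per positive).  The cancer list includes
    each positive with probability ``cancer_rate_positives`` and each
    negative with probability ``cancer_rate_negatives``, mimicking the
    partial overlap between cancer driver lists and aging labels.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    pool = sorted(set(gene_universe) - set(planted))
    n_neg = min(len(pool), cfg.n_negatives_per_positive * len(planted))
    neg_idx = rng.choice(len(pool), size=n_neg, replace=False)
    negatives = frozenset(pool[i] for i in sorted(neg_idx))
    labels = LabelSet(positives=frozenset(planted), negatives=negatives)
    cancer = set()
    for g in sorted(labels.positives):
        if rng.random() < cfg.cancer_rate_positives:
            cancer.add(g)
    for g in sorted(labels.negatives):
        if rng.random() < cfg.cancer_rate_negatives:
            cancer.add(g)
    return labels, frozenset(cancer)


@dataclass
class SyntheticDataset:
    """A complete synthetic study: network, expression, labels, cancer list."""

    config: SyntheticConfig
    network: nx.Graph
    expression: ExpressionSeries
    planted: frozenset
    labels: LabelSet
    cancer: frozenset


def generate_dataset(cfg: SyntheticConfig | None = None, **overrides) -> SyntheticDataset:
    """End-to-end seeded generation of a synthetic study."""
    if cfg is None:
        cfg = SyntheticConfig(**overrides)
    elif overrides:
        raise ValueError("pass either a config or keyword overrides, not both")
    net = generate_entire_network(cfg)
    planted = pick_planted_genes(net, cfg)
    expr = generate_expression(net, cfg, planted)
    labels, cancer = generate_labels(cfg, planted, net.nodes)
    return SyntheticDataset(
        config=cfg,
        network=net,
        expression=expr,
        planted=planted,
        labels=labels,
        cancer=cancer,
    )


def write_dataset(ds: SyntheticDataset, outdir) -> dict:
    """Write the dataset in the plain-text formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": outdir / "network.tsv",
        "expression": outdir / "expression.tsv",
        "positives": outdir / "aging_genes.txt",
        "negatives": outdir / "non_aging_genes.txt",
        "cancer": outdir / "cancer_genes.txt",
        "manifest": outdir / "ground_truth.json",
    }
    write_edge_list(ds.network, paths["network"])
    write_expression_table(ds.expression, paths["expression"])
    write_gene_list(ds.labels.positives, paths["positives"])
    write_gene_list(ds.labels.negatives, paths["negatives"])
    write_gene_list(ds.cancer, paths["cancer"])
    manifest = {
        "config": asdict(ds.config),
        "planted": sorted(ds.planted),
        "n_nodes": ds.network.number_of_nodes(),
        "n_edges": ds.network.number_of_edges(),
        "ages": ds.expression.ages,
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
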