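"""Core data types for aging-specific network analysis.

The package works with an entire context-unspecific protein--protein
interaction (PPI) network (an undirected graph), a gene expression series
measured at an ordered set of ages, and plain gene lists used as
classification labels.  Graphs are :class:`networkx.Graph` objects
throughout; edge weights, when present, live in the ``"weight"`` edge
attribute.  A dynamic network is an age-ordered sequence of snapshots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DataError",
    "Snapshot",
    "DynamicNetwork",
    "ExpressionSeries",
    "LabelSet",
    "read_edge_list",
    "write_edge_list",
    "largest_connected_component",
    "read_expression_table",
    "read_gene_list",
    "write_gene_list",
    "is_weighted",
]


class DataError(ValueError):
    """Raised when an input file or data structure violates its contract."""


def is_weighted(graph: nx.Graph) -> bool:
    """True if every edge of *graph* carries a finite ``weight`` attribute."""
    if graph.number_of_edges() == 0:
        return False
    for _, _, d in graph.edges(data=True):
        w = d.get("weight")
        if w is None or not np.isfinite(w):
            return False
    return True


@dataclass(frozen=True)
class Snapshot:
    """The state of a network at one age."""

    age_label: str
    graph: nx.Graph
    age_years: float | None = None

    @property
    def weighted(self) -> bool:
        return is_weighted(self.graph)


@dataclass
class DynamicNetwork:
    """An age-ordered sequence of network snapshots.

    All snapshots must agree on whether they are weighted, and age labels
    must be unique.  Snapshot order is taken as the age order.
    """

    snapshots: list[Snapshot]
    weighted: bool = field(default=False)

    def __post_init__(self) -> None:
        labels = [s.age_label for s in self.snapshots]
        if len(set(labels)) != len(labels):
            raise DataError("duplicate age labels in dynamic network: %r" % labels)
        for s in self.snapshots:
            if s.graph.number_of_edges() and s.weighted != self.weighted:
                raise DataError(
                    f"snapshot {s.age_label!r} weighted={s.weighted} is inconsistent "
                    f"with dynamic network weighted={self.weighted}"
                )

    @property
    def n(self) -> int:
        return len(self.snapshots)

    @property
    def ages(self) -> list[str]:
        return [s.age_label for s in self.snapshots]

    def node_union(self) -> set:
        out: set = set()
        for s in self.snapshots:
            out |= set(s.graph.nodes)
        return out

    def __len__(self) -> int:
        return len(self.snapshots)

    def __iter__(self):
        return iter(self.snapshots)

    def __getitem__(self, i: int) -> Snapshot:
        return self.snapshots[i]


class ExpressionSeries:
    """Gene-by-age expression values with per-age activity calls.

    Parameters
    ----------
    values
        DataFrame indexed by gene, one column per age (age order is column
        order).  ``NaN`` marks a missing measurement.
    active
        Boolean DataFrame of identical shape; a gene may only be active at
        an age where a measurement is present.
    """

    def __init__(self, values: pd.DataFrame, active: pd.DataFrame):
        if not values.index.equals(active.index) or not values.columns.equals(active.columns):
            raise DataError("expression values and activity flags must share gene/age axes")
        if bool((active & values.isna()).any().any()):
            raise DataError("a gene cannot be active at an age with no measurement")
        self.values = values.astype(float)
        self.active = active.astype(bool)

    @property
    def ages(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def active_genes(self, age: str) -> set:
        if age not in self.values.columns:
            raise KeyError(f"age {age!r} not in expression series")
        col = self.active[age]
        return set(col.index[col])

    def expression_at(self, age: str) -> pd.Series:
        if age not in self.values.columns:
            raise KeyError(f"age {age!r} not in expression series")
        return self.values[age]

    @classmethod
    def from_values(cls, values: pd.DataFrame, activity_rule="mean") -> "ExpressionSeries":
        """Build a series from raw values, computing activity flags.

        ``activity_rule`` is either ``"mean"`` (active where a measurement is
        present and >= the per-age mean over genes), ``("zscore", t)``
        (active where the within-age z-score >= t), or a callable mapping the
        values DataFrame to a boolean DataFrame.
        """
        active = _apply_activity_rule(values, activity_rule)
        return cls(values, active)

    def aggregate(self, combine: str = "mean") -> "ExpressionSeries":
        """Collapse all ages into one pseudo-age.

        The aggregated value is the per-gene ``mean`` or ``max`` over
        measured ages; a gene is active in the aggregate if it is active at
        one or more ages.
        """
        if combine == "mean":
            vals = self.values.mean(axis=1, skipna=True)
        elif combine == "max":
            vals = self.values.max(axis=1, skipna=True)
        else:
            raise ValueError(f"unknown combine rule {combine!r}")
        values = vals.to_frame(name="aggregate")
        active = self.active.any(axis=1).to_frame(name="aggregate")
        return ExpressionSeries(values, active)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ExpressionSeries):
            return NotImplemented
        return self.values.equals(other.values) and self.active.equals(other.active)


def _apply_activity_rule(values: pd.DataFrame, rule) -> pd.DataFrame:
    if callable(rule):
        active = rule(values)
    elif rule == "mean":
        active = values.ge(values.mean(axis=0, skipna=True), axis=1)
    elif isinstance(rule, tuple) and len(rule) == 2 and rule[0] == "zscore":
        thresh = float(rule[1])
        mu = values.mean(axis=0, skipna=True)
        sd = values.std(axis=0, skipna=True, ddof=0)
        z = values.sub(mu, axis=1).div(sd.replace(0.0, np.nan), axis=1)
        active = z.ge(thresh)
    else:
        raise ValueError(f"unknown activity rule {rule!r}")
    return (active & values.notna()).astype(bool)


@dataclass(frozen=True)
class LabelSet:
    """Aging-related (positive) and non-aging-related (negative) genes."""

    positives: frozenset
    negatives: frozenset

    def __post_init__(self) -> None:
        if self.positives & self.negatives:
            raise DataError(
                "label sets overlap: %r" % sorted(self.positives & self.negatives)[:5]
            )

    @property
    def genes(self) -> set:
        return set(self.positives) | set(self.negatives)


# ---------------------------------------------------------------------------
# readers / writers


def read_edge_list(path, weighted: bool = False) -> nx.Graph:
    """Read an undirected edge list from a 2- (or 3-, weighted) column TSV.

    Lines starting with ``#`` and blank lines are skipped.  Duplicate
    unweighted edges are collapsed; duplicate weighted edges are an error.
    Self-loops are dropped (a count is logged).
    """
    graph = nx.Graph()
    self_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            expected = 3 if weighted else 2
            if len(parts) != expected:
                raise DataError(
                    f"{path}:{lineno}: expected {expected} columns, got {len(parts)}"
                )
            u, v = parts[0], parts[1]
            if u == v:
                self_loops += 1
                continue
            if weighted:
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise DataError(
                        f"{path}:{lineno}: non-numeric weight {parts[2]!r}"
                    ) from exc
                if graph.has_edge(u, v):
                    raise DataError(f"{path}:{lineno}: duplicate weighted edge ({u}, {v})")
                graph.add_edge(u, v, weight=w)
            else:
                graph.add_edge(u, v)
    if self_loops:
        logger.info("dropped %d self-loop(s) while reading %s", self_loops, path)
    return graph


def write_edge_list(graph: nx.Graph, path, weighted: bool | None = None) -> None:
    """Write *graph* as a TSV edge list (3 columns when weighted)."""
    if weighted is None:
        weighted = is_weighted(graph)
    with open(path, "w") as fh:
        for u, v, d in sorted(graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
            if weighted:
                fh.write(f"{u}\t{v}\t{d['weight']:.10g}\n")
            else:
                fh.write(f"{u}\t{v}\n")


def largest_connected_component(graph: nx.Graph) -> nx.Graph:
    """The vertex-induced subgraph on the largest connected component.

    Ties on component size are broken by the lexicographically smallest
    member node, so the result is deterministic.
    """
    if graph.number_of_nodes() == 0:
        raise DataError("cannot take largest connected component of an empty network")
    comps = sorted(
        nx.connected_components(graph),
        key=lambda c: (-len(c), min(str(n) for n in c)),
    )
    return graph.subgraph(comps[0]).copy()


def read_expression_table(path, activity_rule="mean") -> ExpressionSeries:
    """Read a genes x ages TSV (header row = age labels, first column = gene).

    Empty cells (or the literal ``NA``/``NaN``) mark missing measurements.
    Ragged rows and duplicate gene rows are errors.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise DataError(f"{path}: empty expression table")
    header = lines[0].split("\t")
    ages = header[1:]
    n_cols = len(header)
    genes: list[str] = []
    rows: list[list[float]] = []
    seen: set = set()
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != n_cols:
            raise DataError(
                f"{path}:{lineno}: ragged row ({len(parts)} columns, header has {n_cols})"
            )
        gene = parts[0]
        if gene in seen:
            raise DataError(f"{path}:{lineno}: duplicate gene row {gene!r}")
        seen.add(gene)
        vals = []
        for cell in parts[1:]:
            cell = cell.strip()
            if cell == "" or cell.upper() in {"NA", "NAN"}:
                vals.append(np.nan)
            else:
                try:
                    vals.append(float(cell))
                except ValueError as exc:
                    raise DataError(f"{path}:{lineno}: non-numeric value {cell!r}") from exc
        genes.append(gene)
        rows.append(vals)
    values = pd.DataFrame(rows, index=genes, columns=ages, dtype=float)
    return ExpressionSeries.from_values(values, activity_rule)


def write_expression_table(expr: ExpressionSeries, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene", na_rep="NA")


def read_gene_list(path) -> set:
    """Read a plain one-symbol-per-line gene list into a set."""
    genes: set = set()
    with open(path) as fh:
        for line in fh:
            sym = line.strip()
            if sym and not sym.startswith("#"):
                genes.add(sym)
    if not genes:
        logger.warning("gene list %s is empty", path)
    return genes


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")
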