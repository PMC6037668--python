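"""Redundancy-reducing marker-trait selection on a correlation network.

Microbiota traits are heavily intercorrelated, so scanning all of them
would inflate the multiple-testing burden with little information gain.
The selection heuristic builds an undirected graph whose edges connect
trait pairs with Spearman correlation above a threshold (0.8 by default,
on absolute values), then greedily picks the highest-degree node as a
marker, removes it together with its neighbours, and repeats on the
surviving subgraph.  The result is an independent dominating set: markers
are pairwise below-threshold, and every discarded trait is correlated
with at least one marker.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "spearman_matrix",
    "threshold_graph",
    "greedy_select_markers",
    "verify_coverage",
    "MarkerSelection",
    "CoverageReport",
]


def spearman_matrix(traits: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlations between trait columns.

    Constant traits yield NaN rows/columns (flagged with a warning); NaN
    trait values are handled pairwise-complete by pandas.
    """
    if traits.shape[1] < 2:
        raise ValueError("need at least two traits")
    if traits.shape[0] < 3:
        raise ValueError("need at least three samples")
    corr = traits.corr(method="spearman")
    off_diag_na = corr.isna().sum(axis=1) >= len(corr) - 1
    np.fill_diagonal(corr.values, 1.0)
    constant = off_diag_na & (traits.nunique(dropna=True) <= 1)
    if constant.any():
        warnings.warn(f"constant traits with undefined correlations: {list(corr.index[constant])}")
    return corr


def threshold_graph(
    corr: pd.DataFrame, threshold: float = 0.8, absolute: bool = True
) -> nx.Graph:
    """Graph with an edge wherever correlation strictly exceeds the threshold.

    With ``absolute=True`` (default) the comparison is on ``|rho|``: a
    strongly anti-correlated trait is just as redundant as a correlated
    one.  Missing correlations contribute no edge.
    """
    if corr.shape[0] != corr.shape[1] or not corr.index.equals(corr.columns):
        raise ValueError("correlation matrix must be square with matching labels")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    values = corr.to_numpy(dtype=float)
    if not np.allclose(values, values.T, equal_nan=True):
        raise ValueError("correlation matrix must be symmetric")
    graph = nx.Graph()
    graph.add_nodes_from(corr.index)
    compare = np.abs(values) if absolute else values
    n_missing = 0
    nodes = list(corr.index)
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            v = compare[i, j]
            if np.isnan(v):
                n_missing += 1
                continue
            if v > threshold:
                graph.add_edge(nodes[i], nodes[j], weight=float(values[i, j]))
    if n_missing:
        warnings.warn(f"{n_missing} missing correlations treated as no edge")
    graph.graph["threshold"] = threshold
    graph.graph["absolute"] = absolute
    return graph


@dataclass
class MarkerSelection:
    """Greedy selection outcome: markers, coverage map and per-iteration log."""

    markers: list[str]
    covered_by: dict[str, list[str]]
    seed: int
    selection_log: list[dict] = field(default_factory=list)


def greedy_select_markers(graph: nx.Graph, seed: int = 0) -> MarkerSelection:
    """Iterative max-degree selection with seeded uniform tie-breaking.

    Degrees are recomputed on the surviving subgraph at each iteration;
    the chosen marker and all of its surviving neighbours are removed.
    """
    rng = np.random.default_rng(seed)
    surviving = graph.copy()
    markers: list[str] = []
    log: list[dict] = []
    iteration = 0
    while surviving.number_of_nodes() > 0:
        iteration += 1
        degrees = dict(surviving.degree())
        max_degree = max(degrees.values())
        candidates = sorted(n for n, d in degrees.items() if d == max_degree)
        chosen = candidates[int(rng.integers(len(candidates)))]
        removed = sorted(surviving.neighbors(chosen))
        markers.append(chosen)
        log.append(
            {
                "iteration": iteration,
                "marker": chosen,
                "degree": max_degree,
                "n_tied": len(candidates),
                "removed": removed,
            }
        )
        surviving.remove_nodes_from([chosen] + removed)
    marker_set = set(markers)
    covered_by = {
        node: sorted(m for m in graph.neighbors(node) if m in marker_set)
        for node in graph.nodes
        if node not in marker_set
    }
    return MarkerSelection(markers=markers, covered_by=covered_by, seed=seed, selection_log=log)


@dataclass
class CoverageReport:
    violations: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations


def verify_coverage(selection: MarkerSelection, graph: nx.Graph) -> CoverageReport:
    """Assert the independent-dominating-set property of a selection."""
    violations: list[str] = []
    marker_set = set(selection.markers)
    unknown = marker_set - set(graph.nodes)
    if unknown:
        violations.append(f"markers not in graph: {sorted(unknown)}")
    discarded = set(graph.nodes) - marker_set
    if set(selection.covered_by) != discarded:
        violations.append("covered_by keys do not partition the non-marker nodes")
    for a in selection.markers:
        for b in graph.neighbors(a):
            if b in marker_set and a < b:
                violations.append(f"markers adjacent (not independent): {a} -- {b}")
    for node in discarded:
        if not any(m in marker_set for m in graph.neighbors(node)):
            violations.append(f"discarded trait not covered by any marker: {node}")
    return CoverageReport(violations=violations)
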