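"""Multiparametric Pearson similarity analysis.

Within a classified cell population (e.g. the predicted-mitotic cells),
pairwise Pearson correlations between measured parameters — raw marker
means and size parameters, not Z-scores — summarize which parameters co-vary.
Parameters are ordered by agglomerative clustering with distance 1 - r and
complete linkage; strong positive correlations (r above a strict cutoff,
0.3 by default) are exported as an undirected parameter graph for
edge-bundle style rendering.

Cross-condition comparison correlates condition-qualified parameter vectors
built from matched rank quantiles: cells are unpaired across conditions, so
each parameter is summarized by its within-condition quantile vector on a
common grid (equal resampled n per condition), and the full block matrix of
correlations is clustered as one.  Duplicating a condition therefore yields
cross-blocks exactly equal to the within-blocks.  Note that Pearson
correlation of quantile vectors is invariant to per-parameter scaling, so
this comparison registers distribution-shape changes (e.g. class-mixture
shifts), not pure fold-changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree
from scipy.spatial.distance import squareform

from .stats import resolve_column


@dataclass
class SimilarityMatrix:
    """Symmetric Pearson-r matrix over named parameters.

    Undefined correlations (constant columns) are carried as NaN, never
    silently coerced to 0; the diagonal is exactly 1.
    """

    parameters: list[str]
    values: np.ndarray
    n_cells: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.parameters), len(self.parameters)):
            raise ValueError("matrix shape does not match parameter list")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.parameters,
                            columns=self.parameters)

    def r(self, p: str, q: str) -> float:
        return float(self.values[self.parameters.index(p),
                                 self.parameters.index(q)])


def _apply_population_filter(table: pd.DataFrame, population_filter):
    if population_filter is None:
        return table
    if callable(population_filter):
        return table[population_filter(table)]
    # a string selects a predicted class (true class as fallback)
    col = "pred_class" if "pred_class" in table.columns else "true_class"
    if col not in table.columns:
        raise KeyError("no pred_class/true_class column to filter on")
    return table[table[col] == population_filter]


def _corrcoef_nan_safe(m: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = np.atleast_2d(np.corrcoef(m, rowvar=False))
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0, out=r) if np.isfinite(r).all() else r


def pearson_matrix(
    table: pd.DataFrame,
    parameters: list[str],
    population_filter=None,
) -> SimilarityMatrix:
    """Pairwise Pearson r between raw parameter columns over cells.

    ``population_filter`` may be a class name (matches ``pred_class``, or
    ``true_class`` when predictions are absent) or a callable returning a
    boolean row mask.  At least 3 cells must survive the filter.
    """
    sub = _apply_population_filter(table, population_filter)
    if len(sub) < 3:
        raise ValueError(
            f"population has {len(sub)} cells; need >= 3 for correlation"
        )
    cols = [resolve_column(sub, p) for p in parameters]
    m = sub.loc[:, cols].to_numpy(dtype=float)
    r = _corrcoef_nan_safe(m)
    return SimilarityMatrix(list(parameters), r, len(sub))


def hierarchical_order(sim: SimilarityMatrix):
    """Complete-linkage clustering of parameters with distance 1 - r.

    Returns ``(ordered_parameters, linkage_matrix)``; the leaf order is the
    deterministic scipy dendrogram order.  Missing correlations raise,
    listing the offending pairs.
    """
    r = sim.values
    bad = np.argwhere(~np.isfinite(np.triu(r, 1)) & (np.triu(np.ones_like(r), 1) > 0))
    if bad.size:
        pairs = [(sim.parameters[i], sim.parameters[j]) for i, j in bad[:10]]
        raise ValueError(f"missing correlations for pairs: {pairs}")
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry for squareform
    np.clip(d, 0.0, None, out=d)
    Z = linkage(squareform(d, checks=False), method="complete")
    order = [sim.parameters[i] for i in leaves_list(Z)]
    return order, Z


def linkage_to_newick(Z: np.ndarray, names: list[str]) -> str:
    """Serialize a scipy merge tree as a Newick string with branch lengths."""
    root = to_tree(Z)

    def walk(node, parent_height) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{names[node.id]}:{length:g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return walk(root, root.dist) + ";"


def quantile_vector(values: np.ndarray, n: int) -> np.ndarray:
    """Rank-quantile summary: the (i + 0.5)/n quantiles of ``values``."""
    q = (np.arange(n) + 0.5) / n
    return np.quantile(np.asarray(values, dtype=float), q)


def cross_condition_similarity(
    tables: dict[str, pd.DataFrame],
    parameters: list[str],
    population_filter=None,
    min_cells: int = 3,
) -> SimilarityMatrix:
    """Block correlation matrix over (condition, parameter) pairs.

    Each condition's cells are reduced to matched rank-quantile vectors of
    equal length (the smallest per-condition cell count), one per parameter;
    the Pearson matrix over all condition-qualified vectors is returned with
    parameters labeled ``condition|parameter``.
    """
    filtered: dict[str, pd.DataFrame] = {}
    for cond, tab in tables.items():
        sub = _apply_population_filter(tab, population_filter)
        if len(sub) < min_cells:
            raise ValueError(
                f"condition {cond!r} has {len(sub)} cells after filtering; "
                f"need >= {min_cells}"
            )
        missing = []
        for p in parameters:
            try:
                resolve_column(sub, p)
            except KeyError:
                missing.append(p)
        if missing:
            raise KeyError(
                f"condition {cond!r} lacks parameter column(s) {missing}"
            )
        filtered[cond] = sub

    n = min(len(sub) for sub in filtered.values())
    labels: list[str] = []
    columns: list[np.ndarray] = []
    for cond, sub in filtered.items():
        for p in parameters:
            col = resolve_column(sub, p)
            labels.append(f"{cond}|{p}")
            columns.append(quantile_vector(sub[col].to_numpy(), n))
    m = np.column_stack(columns)
    r = _corrcoef_nan_safe(m)
    return SimilarityMatrix(labels, r, n)


def mean_block_r(sim: SimilarityMatrix, cond_a: str, cond_b: str) -> float:
    """Mean correlation of the (cond_a, cond_b) cross block."""
    ia = [i for i, p in enumerate(sim.parameters) if p.startswith(cond_a + "|")]
    ib = [i for i, p in enumerate(sim.parameters) if p.startswith(cond_b + "|")]
    if not ia or not ib:
        raise KeyError(f"no parameters for {cond_a!r} or {cond_b!r}")
    return float(np.nanmean(sim.values[np.ix_(ia, ib)]))


def edge_bundle_graph(sim: SimilarityMatrix, cutoff: float = 0.3) -> nx.Graph:
    """Undirected graph of positive correlations strictly above ``cutoff``.

    Nodes are all parameters (condition-qualified when applicable); edge
    weights are the correlations; self-edges are excluded and r equal to the
    cutoff does not qualify.
    """
    g = nx.Graph()
    g.add_nodes_from(sim.parameters)
    k = len(sim.parameters)
    for i in range(k):
        for j in range(i + 1, k):
            r = sim.values[i, j]
            if np.isfinite(r) and r > cutoff:
                g.add_edge(sim.parameters[i], sim.parameters[j], weight=float(r))
    return g


def write_graph(g: nx.Graph, json_path=None, graphml_path=None) -> None:
    """Export a parameter graph as node-link JSON and/or GraphML."""
    import json as _json

    if json_path is not None:
        data = nx.node_link_data(g, edges="links")
        Path(json_path).write_text(_json.dumps(data, indent=1))
    if graphml_path is not None:
        nx.write_graphml(g, graphml_path)
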