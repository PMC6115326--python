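"""Coexpression refinement of a protein–protein interaction network.

Each PPI edge is annotated with the Pearson correlation (PCC) of its two
endpoints' expression profiles across tissue columns; only edges with
PCC strictly above a threshold (default 0.5) are retained.  Nodes of the
refined network are flagged as *seed* (member of the preferential gene set)
or *interactor*, and can carry functional-class labels from a user-supplied
mapping table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .data_io import EdgeList, ExpressionMatrix
from .selection import collapse_replicates

logger = logging.getLogger(__name__)


def pearson_cc(x: Iterable[float], y: Iterable[float]) -> float:
    """Pearson product-moment correlation; nan when either vector has zero
    variance (an edge with nan PCC never passes the threshold)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors of length ≥ 3")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = math.sqrt(float(xd @ xd) * float(yd @ yd))
    if denom == 0.0:
        return math.nan
    return float(np.clip((xd @ yd) / denom, -1.0, 1.0))


@dataclass
class RefinedNetwork:
    """Threshold-refined network plus bookkeeping counts."""

    graph: nx.Graph                 # nodes: is_seed, functional_class; edges: pcc, source
    pcc_threshold: float
    n_edges_retained: int
    n_seed_nodes: int
    n_interactor_nodes: int
    n_edges_dropped_low_pcc: int
    n_edges_dropped_missing_expression: int

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()


def refine_network(
    ppi: EdgeList,
    matrix: ExpressionMatrix,
    seed_genes: set[str],
    threshold: float = 0.5,
    class_map: Mapping[str, str] | None = None,
) -> RefinedNetwork:
    """Keep PPI edges whose endpoints are coexpressed (PCC > threshold).

    PCC is computed across collapsed tissue columns (one value per tissue);
    a matrix with replicate columns is collapsed first.  Edges with an
    endpoint absent from the matrix are dropped and counted, not errored.
    """
    if not matrix.is_collapsed:
        matrix = collapse_replicates(matrix)
    values = matrix.values
    class_map = class_map or {}

    g = nx.Graph()
    n_low = n_missing = 0
    for a, b, source in ppi:
        if a not in values.index or b not in values.index:
            n_missing += 1
            continue
        pcc = pearson_cc(values.loc[a], values.loc[b])
        if math.isnan(pcc) or pcc <= threshold:
            n_low += 1
            continue
        g.add_edge(a, b, pcc=pcc, source=source)
    if n_missing:
        logger.info("dropped %d edges with endpoints missing from the "
                    "expression matrix", n_missing)

    for node in g.nodes:
        g.nodes[node]["is_seed"] = node in seed_genes
        g.nodes[node]["functional_class"] = class_map.get(node, "")

    n_seed = sum(1 for n in g.nodes if g.nodes[n]["is_seed"])
    return RefinedNetwork(
        graph=g,
        pcc_threshold=threshold,
        n_edges_retained=g.number_of_edges(),
        n_seed_nodes=n_seed,
        n_interactor_nodes=g.number_of_nodes() - n_seed,
        n_edges_dropped_low_pcc=n_low,
        n_edges_dropped_missing_expression=n_missing,
    )


def write_refined_network(network: RefinedNetwork, edge_path: str | Path,
                          node_path: str | Path,
                          graphml_path: str | Path | None = None) -> None:
    """Write edge and node tables (tab-separated); optionally GraphML."""
    g = network.graph
    with open(edge_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("node_a\tnode_b\tpcc\tsource\n")
        for a, b, data in sorted(g.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['pcc']:.4f}\t{data['source']}\n")
    with open(node_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("node\tis_seed\tfunctional_class\n")
        for n in sorted(g.nodes):
            fh.write(f"{n}\t{int(g.nodes[n]['is_seed'])}\t"
                     f"{g.nodes[n]['functional_class']}\n")
    if graphml_path is not None:
        nx.write_graphml(g, graphml_path)
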