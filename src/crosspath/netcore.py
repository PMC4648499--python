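"""Graph primitives shared by all stages.

Column-stochastic normalization for the random walk, induced subgraphs,
and average clustering coefficients.  Nodes with degree < 2 contribute a
local clustering coefficient of 0 (the dominant convention), so the
graph-level average is defined on every non-empty graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp

from crosspath.iocore import GeneNetwork

logger = logging.getLogger(__name__)


@dataclass
class StochasticMatrix:
    """Column-normalized adjacency matrix W with its node ordering.

    Entry (i, j) is 1/degree(j) when {i, j} is an edge, else 0; columns of
    isolated nodes are all-zero and listed in ``zero_columns``.
    """

    ordering: list[str]
    matrix: sp.csc_array
    zero_columns: list[str] = field(default_factory=list)

    def index_of(self, gene: str) -> int:
        return self.ordering.index(gene)


def column_normalize(net: GeneNetwork) -> StochasticMatrix:
    """Build the column-stochastic transition matrix of an undirected graph."""
    if net.number_of_nodes() == 0:
        raise ValueError("cannot normalize an empty network")
    ordering = sorted(net.nodes)
    adj = nx.to_scipy_sparse_array(net, nodelist=ordering, dtype=float)
    deg = np.asarray(adj.sum(axis=0)).ravel()
    inv = np.zeros_like(deg)
    nonzero = deg > 0
    inv[nonzero] = 1.0 / deg[nonzero]
    w = (adj.tocsc() @ sp.diags_array(inv)).tocsc()
    zero_columns = [g for g, nz in zip(ordering, nonzero) if not nz]
    if zero_columns:
        logger.info("%d isolated node(s) have all-zero columns", len(zero_columns))
    return StochasticMatrix(ordering=ordering, matrix=w, zero_columns=zero_columns)


def induced_subgraph(net: GeneNetwork, keep: set[str]) -> GeneNetwork:
    """Subgraph on ``keep`` ∩ nodes with every edge internal to it."""
    return nx.Graph(net.subgraph(keep))


def avg_clustering_coefficient(net: GeneNetwork) -> float:
    """Mean local clustering coefficient over all nodes of a non-empty graph."""
    if net.number_of_nodes() == 0:
        raise ValueError("average clustering coefficient of an empty graph")
    return nx.average_clustering(net)
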