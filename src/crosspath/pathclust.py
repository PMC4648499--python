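"""Pathway clustering by shared associated genes; common-module extraction.

Associated genes are the genes belonging to both the CFNN and at least
one significantly enriched pathway.  A binary gene x pathway matrix over
them feeds a cosine-distance (1 - cosine similarity) hierarchical
clustering; cutting the tree partitions the pathways into clusters.  For
each cluster the member pathways' associated-gene sets are intersected;
the intersection's induced subnetwork inside the CFNN is the cluster's
common module, summarized by its average clustering coefficient.

With average or complete linkage on 1 - cosine, merge heights stay in
[0, 1], so the published cut height of 1.1 is only reachable with a
linkage that grows heights (e.g. Ward); the default here is average
linkage with cut 0.7 (cosine similarity ≳ 0.3 within a cluster — on the
[0, 1] scale a cut near 0.9 would merge pathways sharing almost no
genes), and both knobs are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from crosspath.iocore import GeneNetwork, PathwayAnnotation
from crosspath.enrich import EnrichmentRecord
from crosspath.netcore import avg_clustering_coefficient, induced_subgraph

logger = logging.getLogger(__name__)


@dataclass
class AssociationMatrix:
    """Binary associated-gene x pathway membership table (rows genes)."""

    table: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    @property
    def pathways(self) -> list[str]:
        return list(self.table.columns)

    def associated_genes_of(self, pathway_id: str) -> frozenset[str]:
        col = self.table[pathway_id]
        return frozenset(col.index[col > 0])


@dataclass(frozen=True)
class ClusterConfig:
    """Tree-cut distance and linkage.  cut_distance=1.1 with linkage='ward'
    reproduces the published setting; the average-linkage default cuts at
    0.7 on the [0, 1] cosine-distance scale (within-cluster similarity
    ≳ 0.3)."""

    cut_distance: float = 0.7
    linkage: str = "average"

    def __post_init__(self) -> None:
        if self.cut_distance <= 0:
            raise ValueError("cut_distance must be positive")
        if self.linkage not in ("average", "complete", "ward"):
            raise ValueError(f"unsupported linkage {self.linkage!r}")


@dataclass
class CommonModule:
    cluster_id: int
    member_pathways: frozenset[str]
    common_genes: frozenset[str]
    subnetwork: GeneNetwork
    avg_cc: float | None


def build_association_matrix(
    cfnn: GeneNetwork,
    records: list[EnrichmentRecord],
    db: list[PathwayAnnotation],
) -> AssociationMatrix:
    """Binary matrix of CFNN genes vs. significant pathways.

    Entry (g, P) = 1 iff g is a CFNN node and a member of P.  Pathways
    without any CFNN gene are dropped (logged); genes outside every
    significant pathway never enter the matrix.
    """
    sig = [r for r in records if r.significant]
    if not sig:
        raise ValueError("no significant pathway to build the matrix from")
    members = {p.pathway_id: p.genes for p in db}
    cfnn_nodes = set(cfnn.nodes)
    columns: dict[str, frozenset[str]] = {}
    for rec in sig:
        overlap = frozenset(members[rec.pathway_id] & cfnn_nodes)
        if overlap:
            columns[rec.pathway_id] = overlap
        else:
            logger.info(
                "significant pathway %s shares no gene with the CFNN; dropped",
                rec.pathway_id,
            )
    if not columns:
        raise ValueError("no associated genes: CFNN is disjoint from all "
                         "significant pathways")
    genes = sorted(frozenset().union(*columns.values()))
    pathways = sorted(columns)
    table = pd.DataFrame(0, index=genes, columns=pathways, dtype=np.int8)
    for pid, overlap in columns.items():
        table.loc[sorted(overlap), pid] = 1
    return AssociationMatrix(table=table)


def pathway_cosine_distance(matrix: AssociationMatrix) -> pd.DataFrame:
    """1 - cosine similarity between pathway columns (symmetric, zero diag)."""
    if len(matrix.pathways) < 2:
        raise ValueError("need at least 2 pathways for pairwise distances")
    x = matrix.table.to_numpy(dtype=float).T
    if (x.sum(axis=1) == 0).any():
        raise ValueError("all-zero pathway column reached the distance step")
    dist = squareform(np.clip(pdist(x, metric="cosine"), 0.0, None))
    return pd.DataFrame(dist, index=matrix.pathways, columns=matrix.pathways)


def cluster_pathways(distances: pd.DataFrame, cfg: ClusterConfig | None = None
                     ) -> list[frozenset[str]]:
    """Agglomerative clustering cut at cfg.cut_distance.

    Returns a partition of the pathway ids; clusters are numbered (by list
    position) in order of their lexicographically smallest member so the
    output is independent of input order.
    """
    cfg = cfg or ClusterConfig()
    ids = list(distances.index)
    if len(ids) < 2:
        raise ValueError("need at least 2 pathways to cluster")
    condensed = squareform(distances.to_numpy(), checks=False)
    z = linkage(condensed, method=cfg.linkage)
    labels = fcluster(z, t=cfg.cut_distance, criterion="distance")
    groups: dict[int, set[str]] = {}
    for pid, lab in zip(ids, labels):
        groups.setdefault(int(lab), set()).add(pid)
    return [frozenset(g) for g in sorted(groups.values(), key=min)]


def extract_common_module(
    cluster: frozenset[str],
    matrix: AssociationMatrix,
    cfnn: GeneNetwork,
    cluster_id: int = 0,
) -> CommonModule:
    """Intersect the cluster's associated-gene sets and induce on the CFNN.

    A cluster whose member pathways share no associated gene yields a
    module with an empty gene set and avg_cc = None.
    """
    if not cluster:
        raise ValueError("empty pathway cluster")
    assoc = [matrix.associated_genes_of(pid) for pid in sorted(cluster)]
    common = frozenset.intersection(*assoc)
    subnet = induced_subgraph(cfnn, set(common))
    avg_cc = avg_clustering_coefficient(subnet) if common else None
    return CommonModule(
        cluster_id=cluster_id,
        member_pathways=cluster,
        common_genes=common,
        subnetwork=subnet,
        avg_cc=avg_cc,
    )
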