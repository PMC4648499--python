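"""Pathway enrichment: two-sided hypergeometric tests with BH correction.

For a query gene list (the CFNN nodes) and a pathway database, each
pathway is tested under Hypergeometric(N, m, n) where N is the universe
size, m the pathway size within the universe and n the query size within
the universe.  The two-sided p doubles the smaller of the two tails and
caps at 1; pathways with zero overlap are still tested since they can be
significantly depleted.  BH adjustment runs across all tested pathways
and significance is called at adjusted p < alpha (default 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from crosspath.iocore import GeneNetwork, GenePanel, PathwayAnnotation


@dataclass(frozen=True)
class EnrichmentRecord:
    pathway_id: str
    k: int          # query ∩ pathway within universe
    m: int          # pathway size within universe
    n: int          # query size within universe
    N: int          # universe size
    p_raw: float
    p_adj: float
    direction: str  # "enriched" | "depleted"
    significant: bool


@dataclass(frozen=True)
class EnrichmentConfig:
    """alpha is the adjusted-p call threshold; the universe is either all
    genes annotated to ≥ 1 pathway (default), all network genes, or a
    custom list."""

    alpha: float = 0.05
    universe_policy: str = "annotated_genes"
    custom_universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.universe_policy not in ("annotated_genes", "network_genes", "custom"):
            raise ValueError(f"unknown universe policy {self.universe_policy!r}")
        if self.universe_policy == "custom" and not self.custom_universe:
            raise ValueError("custom universe policy without a custom list")


def hypergeom_two_sided(k: int, m: int, n: int, N: int) -> tuple[float, str]:
    """Two-sided hypergeometric p-value and its direction.

    p = min(1, 2·min(P(X ≥ k), P(X ≤ k))); direction is 'enriched' when
    k is at or above the expectation n·m/N, else 'depleted'.
    """
    if min(k, m, n, N) < 0 or k > min(m, n) or m > N or n > N:
        raise ValueError(f"inconsistent counts k={k} m={m} n={n} N={N}")
    upper = float(stats.hypergeom.sf(k - 1, N, m, n))
    lower = float(stats.hypergeom.cdf(k, N, m, n))
    p_raw = min(1.0, 2.0 * min(upper, lower))
    direction = "enriched" if N == 0 or k * N >= n * m else "depleted"
    return p_raw, direction


def bh_adjust(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return [float(q) for q in multipletests(p, method="fdr_bh")[1]]


def resolve_universe(
    query: GenePanel,
    db: list[PathwayAnnotation],
    cfg: EnrichmentConfig,
    network: GeneNetwork | None = None,
) -> frozenset[str]:
    if cfg.universe_policy == "annotated_genes":
        return frozenset().union(*(p.genes for p in db))
    if cfg.universe_policy == "network_genes":
        if network is None:
            raise ValueError("network_genes universe requires the network")
        return frozenset(network.nodes)
    assert cfg.custom_universe is not None
    return cfg.custom_universe


def enrich_pathways(
    query: GenePanel,
    db: list[PathwayAnnotation],
    cfg: EnrichmentConfig | None = None,
    network: GeneNetwork | None = None,
) -> list[EnrichmentRecord]:
    """Test every pathway with ≥ 1 gene in the universe against the query.

    Records are sorted by adjusted p then pathway id.
    """
    cfg = cfg or EnrichmentConfig()
    if not query.genes:
        raise ValueError("query panel is empty")
    if not db:
        raise ValueError("pathway database is empty")
    universe = resolve_universe(query, db, cfg, network)
    query_u = query.genes & universe
    if not query_u:
        raise ValueError("query has no genes inside the universe")
    N, n = len(universe), len(query_u)

    tested: list[tuple[str, int, int, float, str]] = []
    for pw in db:
        members_u = pw.genes & universe
        if not members_u:
            continue
        m = len(members_u)
        k = len(members_u & query_u)
        p_raw, direction = hypergeom_two_sided(k, m, n, N)
        tested.append((pw.pathway_id, k, m, p_raw, direction))
    if not tested:
        raise ValueError("no pathway intersects the universe")

    adj = bh_adjust([t[3] for t in tested])
    records = [
        EnrichmentRecord(
            pathway_id=pid, k=k, m=m, n=n, N=N,
            p_raw=p_raw, p_adj=p_adj, direction=direction,
            significant=p_adj < cfg.alpha,
        )
        for (pid, k, m, p_raw, direction), p_adj in zip(tested, adj)
    ]
    records.sort(key=lambda r: (r.p_adj, r.pathway_id))
    return records
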