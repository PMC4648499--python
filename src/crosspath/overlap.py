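"""Common susceptibility genes, their permutation significance, and the CFNN.

The intersection of two or more disease panels gives the common
susceptibility genes.  Significance is assessed by redrawing panels of
the same sizes uniformly from the interaction network's gene universe
and recording the null intersection sizes; the empirical p-value uses
the add-one rule (n_at_least + 1) / (n_replicates + 1).  Because a raw
empirical estimate is floored at 1/(R+1), a parametric companion p-value
is also reported from a Poisson fit to the null counts (rare-overlap
counts are closely Poisson); the family choice is ours and both values
are always given.

The CFNN (common-gene first-neighbor network) is the induced subgraph of
the interaction network on the common genes plus all their direct
neighbors; neighbor-neighbor edges are therefore included.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from crosspath.iocore import GeneNetwork, GenePanel
from crosspath.netcore import induced_subgraph

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PermutationTestResult:
    observed: int
    n_replicates: int
    n_at_least: int
    p_empirical: float
    p_parametric: float | None
    seed: int
    null_mean: float

    def __post_init__(self) -> None:
        if not 0 <= self.n_at_least <= self.n_replicates:
            raise ValueError("n_at_least outside [0, n_replicates]")


def intersect_panels(panels: list[GenePanel]) -> GenePanel:
    """Set intersection of ≥ 2 panels, named 'common'."""
    if len(panels) < 2:
        raise ValueError("need at least 2 panels to intersect")
    common = frozenset.intersection(*(p.genes for p in panels))
    if not common:
        logger.warning("panel intersection is empty")
    return GenePanel(name="common", genes=common)


def overlap_permutation_test(
    universe: set[str],
    sizes: list[int],
    observed: int,
    n_replicates: int = 10_000,
    seed: int = 0,
) -> PermutationTestResult:
    """Null distribution of the k-way intersection size of random panels.

    Each replicate draws len(sizes) gene sets uniformly without
    replacement (independently of one another) from the universe and
    records their intersection size.
    """
    n_univ = len(universe)
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    for s in sizes:
        if s > n_univ:
            raise ValueError(f"panel size {s} exceeds universe size {n_univ}")
    rng = np.random.default_rng(seed)
    k = len(sizes)
    counts = np.empty(n_replicates, dtype=np.int64)
    hits = np.zeros(n_univ, dtype=np.int8)
    for r in range(n_replicates):
        hits[:] = 0
        for s in sizes:
            hits[rng.choice(n_univ, size=s, replace=False)] += 1
        counts[r] = int((hits == k).sum())
    n_at_least = int((counts >= observed).sum())
    lam = float(counts.mean())
    p_parametric = float(stats.poisson.sf(observed - 1, lam)) if lam > 0 else (
        1.0 if observed <= 0 else 0.0
    )
    return PermutationTestResult(
        observed=observed,
        n_replicates=n_replicates,
        n_at_least=n_at_least,
        p_empirical=(n_at_least + 1) / (n_replicates + 1),
        p_parametric=p_parametric,
        seed=seed,
        null_mean=lam,
    )


def build_cfnn(net: GeneNetwork, common: GenePanel) -> GeneNetwork:
    """Induced subgraph on the common genes and all their first neighbors."""
    present = set(common.genes) & set(net.nodes)
    if not present:
        raise ValueError("no common gene is present in the network")
    isolated = {g for g in present if net.degree(g) == 0}
    if isolated:
        logger.warning(
            "excluding %d isolated common gene(s): %s",
            len(isolated), sorted(isolated),
        )
    anchors = present - isolated
    keep = set(anchors)
    for g in anchors:
        keep.update(net.neighbors(g))
    return induced_subgraph(net, keep)
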