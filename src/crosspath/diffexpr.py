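"""Two-group differential expression and the multi-protein-component test.

Per-gene Welch t-tests on log-scale values with BH adjustment stand in
for the usual moderated-t machinery: the contract is simply "a per-gene
two-group test + BH", with the engine documented and swappable.  Genes
with zero variance in both groups are untestable and excluded from the
BH denominator.

A pathway-diagram component (one or more interchangeable proteins) is
called differentially expressed when any member gene is significant.
The component count for a pathway is compared against redraws of equally
many genes from a gene universe, with add-one empirical p-values and a
Poisson-fit parametric companion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from crosspath.enrich import bh_adjust
from crosspath.iocore import ComponentDefinition, ExpressionMatrix, GenePanel
from crosspath.overlap import PermutationTestResult

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComponentTestResult:
    pathway_id: str
    n_components: int
    observed_hits: int
    permutation: PermutationTestResult

    def __post_init__(self) -> None:
        if not 0 <= self.observed_hits <= self.n_components:
            raise ValueError("observed_hits outside [0, n_components]")


def de_test(expr: ExpressionMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Welch two-sample t-test per gene with BH over the testable genes.

    Returns a DataFrame indexed by gene with columns effect (case mean -
    control mean), statistic, p_raw, p_adj, testable, significant.
    """
    case = expr.values[expr.case_samples].to_numpy(dtype=float)
    ctrl = expr.values[expr.control_samples].to_numpy(dtype=float)
    effect = case.mean(axis=1) - ctrl.mean(axis=1)
    testable = ~((case.var(axis=1) == 0.0) & (ctrl.var(axis=1) == 0.0))

    stat = np.full(len(effect), np.nan)
    p_raw = np.full(len(effect), np.nan)
    if testable.any():
        t, p = stats.ttest_ind(case[testable], ctrl[testable],
                               axis=1, equal_var=False)
        stat[testable] = t
        p_raw[testable] = p
    p_adj = np.full(len(effect), np.nan)
    if testable.any():
        p_adj[testable] = bh_adjust(list(p_raw[testable]))

    out = pd.DataFrame(
        {
            "effect": effect,
            "statistic": stat,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "testable": testable,
            "significant": testable & (p_adj < alpha),
        },
        index=expr.values.index.rename("gene"),
    )
    n_untestable = int((~testable).sum())
    if n_untestable:
        logger.info("%d zero-variance gene(s) excluded from testing",
                    n_untestable)
    return out


def union_deg(results: list[pd.DataFrame], name: str = "deg_union") -> GenePanel:
    """Union of significant genes across datasets."""
    if not results:
        raise ValueError("no DE result tables given")
    genes: set[str] = set()
    for tab in results:
        genes.update(tab.index[tab["significant"]])
    if not genes:
        logger.warning("no significant gene in any dataset")
    return GenePanel.from_iterable(name, genes)


def _pathway_components(components: list[ComponentDefinition],
                        pathway_id: str) -> list[ComponentDefinition]:
    comps = [c for c in components if c.pathway_id == pathway_id]
    if not comps:
        raise KeyError(f"no components defined for pathway {pathway_id!r}")
    return comps


def count_de_components(deg: GenePanel,
                        components: list[ComponentDefinition],
                        pathway_id: str) -> int:
    """Number of the pathway's components with ≥ 1 member in the DEG set."""
    comps = _pathway_components(components, pathway_id)
    return sum(1 for c in comps if c.member_genes & deg.genes)


def component_permutation_test(
    deg_size: int,
    universe: set[str],
    components: list[ComponentDefinition],
    pathway_id: str,
    observed_hits: int,
    n_replicates: int = 10_000,
    seed: int = 0,
) -> ComponentTestResult:
    """Null distribution of the hit-component count under random DEG draws.

    Each replicate draws deg_size genes uniformly without replacement
    from the universe; a component is hit when any member is drawn.
    Members outside the universe can never be hit by a draw.
    """
    comps = _pathway_components(components, pathway_id)
    ids = sorted(universe)
    n_univ = len(ids)
    if deg_size > n_univ:
        raise ValueError(f"deg_size {deg_size} exceeds universe size {n_univ}")
    index = {g: i for i, g in enumerate(ids)}
    member_idx = [
        np.array(sorted(index[g] for g in c.member_genes if g in index),
                 dtype=np.intp)
        for c in comps
    ]

    rng = np.random.default_rng(seed)
    counts = np.empty(n_replicates, dtype=np.int64)
    mask = np.zeros(n_univ, dtype=bool)
    for r in range(n_replicates):
        mask[:] = False
        mask[rng.choice(n_univ, size=deg_size, replace=False)] = True
        counts[r] = sum(1 for idx in member_idx
                        if idx.size and mask[idx].any())
    n_at_least = int((counts >= observed_hits).sum())
    lam = float(counts.mean())
    p_parametric = float(stats.poisson.sf(observed_hits - 1, lam)) if lam > 0 else (
        1.0 if observed_hits <= 0 else 0.0
    )
    perm = PermutationTestResult(
        observed=observed_hits,
        n_replicates=n_replicates,
        n_at_least=n_at_least,
        p_empirical=(n_at_least + 1) / (n_replicates + 1),
        p_parametric=p_parametric,
        seed=seed,
        null_mean=lam,
    )
    return ComponentTestResult(
        pathway_id=pathway_id,
        n_components=len(comps),
        observed_hits=observed_hits,
        permutation=perm,
    )
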