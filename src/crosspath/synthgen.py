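"""Synthetic inputs with the statistical structure the analysis assumes.

The generator emulates, at roughly one-tenth scale, the shape of the
real inputs: a scale-free interaction network (preferential attachment),
three disease panels sharing a small planted intersection, a pathway
database of mixed sizes where a handful of pathways are enriched around
the planted genes' network neighborhood and all carry a planted
fully-connected module, pathway components a fraction of which are
multi-protein, and two-group log-scale expression with planted
differential genes.  Every draw flows from the config seed through
integer-indexed choices, so output is bit-identical across runs and
platforms.

Planting details that matter downstream:

* the module genes are wired into a clique, and one planted common gene
  is placed inside the module, so the whole module lies in the CFNN;
* the three panels are redrawn until their three-way intersection equals
  the planted common set exactly, making overlap recovery a sharp test;
* enriched pathways contain every module gene and draw the bulk of their
  remaining members from the planted common genes' neighborhood, split
  between the first- and second-neighbor shells: the 1-hop half puts
  enrichment signal inside the CFNN while the 2-hop half keeps any single
  neighbor gene unlikely to appear in every enriched pathway.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from crosspath.iocore import (
    ComponentDefinition,
    ExpressionMatrix,
    GeneNetwork,
    GenePanel,
    PathwayAnnotation,
    write_components,
    write_edge_list,
    write_expression,
    write_gmt,
    write_pathways_gmt,
)

import pandas as pd


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic benchmark (≈ 10x scaled down)."""

    n_genes: int = 1500
    attachment_edges: int = 3
    panel_sizes: tuple[int, int, int] = (100, 60, 90)
    n_planted_common: int = 10
    n_pathways: int = 120
    pathway_size_range: tuple[int, int] = (15, 80)
    n_enriched_pathways: int = 8
    module_size: int = 6
    multi_protein_fraction: float = 0.3
    n_samples_per_group: int = 10
    n_de_genes: int = 50
    de_effect: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= self.attachment_edges:
            raise ValueError("n_genes must exceed attachment_edges")
        if self.n_planted_common > min(self.panel_sizes):
            raise ValueError("n_planted_common exceeds a panel size")
        if self.module_size and self.module_size < 3:
            raise ValueError("module_size must be ≥ 3 (or 0 to disable)")
        if not 0.0 <= self.multi_protein_fraction <= 1.0:
            raise ValueError("multi_protein_fraction must be in [0, 1]")
        for val in (self.n_pathways, self.n_samples_per_group):
            if val < 1:
                raise ValueError("counts must be positive")


@dataclass(frozen=True)
class SyntheticTruth:
    planted_common_genes: frozenset[str]
    planted_enriched_pathway_ids: frozenset[str]
    planted_module_genes: frozenset[str]
    planted_de_genes: frozenset[str]


@dataclass
class SyntheticDataset:
    network: GeneNetwork
    panels: list[GenePanel]
    pathways: list[PathwayAnnotation]
    components: list[ComponentDefinition]
    expression: ExpressionMatrix
    truth: SyntheticTruth
    config: SynthConfig


def _rng(cfg: SynthConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stage])


def generate_network(cfg: SynthConfig) -> tuple[GeneNetwork, frozenset[str]]:
    """Preferential-attachment graph with the module genes wired as a clique.

    Returns the network and the planted module genes (a truth part).
    """
    rng = _rng(cfg, 0)
    ba_seed = int(rng.integers(2**31))
    raw = nx.barabasi_albert_graph(cfg.n_genes, cfg.attachment_edges,
                                   seed=ba_seed)
    width = len(str(cfg.n_genes - 1))
    mapping = {i: f"G{i:0{width}d}" for i in raw.nodes}
    net: GeneNetwork = nx.relabel_nodes(raw, mapping)
    nodes = sorted(net.nodes)
    module = []
    if cfg.module_size:
        module = [nodes[i] for i in rng.choice(len(nodes), size=cfg.module_size,
                                               replace=False)]
        for i, u in enumerate(module):
            for v in module[i + 1:]:
                net.add_edge(u, v)
    return net, frozenset(module)


def generate_panels(
    net: GeneNetwork,
    cfg: SynthConfig,
    module_genes: frozenset[str] = frozenset(),
) -> tuple[list[GenePanel], frozenset[str]]:
    """Three panels whose three-way intersection is exactly the planted set.

    One planted common gene sits inside the planted module (when both are
    requested) so the module is reachable from the common genes; panel
    fillers are redrawn until no accidental extra three-way overlap
    remains.
    """
    rng = _rng(cfg, 1)
    nodes = sorted(net.nodes)
    planted: list[str] = []
    if cfg.n_planted_common:
        if module_genes:
            planted.append(sorted(module_genes)[
                int(rng.integers(len(module_genes)))])
        rest_pool = sorted(set(nodes) - set(planted) - set(module_genes))
        need = cfg.n_planted_common - len(planted)
        planted.extend(rest_pool[i] for i in rng.choice(len(rest_pool),
                                                        size=need,
                                                        replace=False))
    planted_set = frozenset(planted)
    filler_pool = sorted(set(nodes) - planted_set)

    names = ("panelA", "panelB", "panelC")
    for _ in range(1000):
        fillers = []
        for size in cfg.panel_sizes:
            need = size - len(planted_set)
            idx = rng.choice(len(filler_pool), size=need, replace=False)
            fillers.append(frozenset(filler_pool[i] for i in idx))
        if not frozenset.intersection(*fillers):
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not avoid accidental three-way overlap")
    panels = [
        GenePanel(name=name, genes=planted_set | filler)
        for name, filler in zip(names, fillers)
    ]
    return panels, planted_set


def _neighborhood_shells(net: GeneNetwork, common: frozenset[str]
                         ) -> tuple[list[str], list[str]]:
    """First- and second-neighbor shells around the common genes."""
    seed = set(common) & set(net.nodes)
    shell1 = {v for u in seed for v in net.neighbors(u)} - seed
    shell2 = {v for u in shell1 for v in net.neighbors(u)} - shell1 - seed
    return sorted(shell1), sorted(shell2)


def generate_pathways(
    net: GeneNetwork,
    common: frozenset[str],
    module_genes: frozenset[str],
    cfg: SynthConfig,
) -> tuple[list[PathwayAnnotation], list[ComponentDefinition], frozenset[str]]:
    """Pathway database with planted enriched pathways, plus components.

    Enriched pathways contain all module genes and draw ~60 % of their
    members from the module ∪ the planted common genes' neighborhood
    (split evenly between the first- and second-neighbor shells); null
    pathways draw uniformly.  Every pathway is partitioned into
    components, with a configurable fraction being multi-protein
    (2-3 members).
    """
    rng = _rng(cfg, 2)
    nodes = sorted(net.nodes)
    shell1, shell2 = _neighborhood_shells(net, common)
    pool1 = sorted((set(shell1) | module_genes) - common - module_genes)
    pool2 = sorted(set(shell2) - common - module_genes - set(pool1))
    lo, hi = cfg.pathway_size_range
    lo = max(lo, cfg.module_size + 1)

    width = len(str(max(cfg.n_pathways - 1, 1)))
    categories = ("disease", "functional")
    pathways: list[PathwayAnnotation] = []
    enriched_ids: list[str] = []
    for i in range(cfg.n_pathways):
        pid = f"PW{i:0{width}d}"
        size = int(rng.integers(lo, hi + 1))
        category = categories[int(rng.integers(2))]
        if i < cfg.n_enriched_pathways:
            members = set(module_genes)
            n_signal = max(len(members), math.ceil(0.6 * size))
            need = n_signal - len(members)
            # split neighborhood draws between the 1- and 2-hop shells so
            # enrichment stays concentrated near the CFNN while no single
            # neighbor gene is likely to land in every enriched pathway
            n_near = min(need - need // 2, len(pool1))
            n_far = min(need - n_near, len(pool2))
            if n_near > 0:
                idx = rng.choice(len(pool1), size=n_near, replace=False)
                members.update(pool1[j] for j in idx)
            if n_far > 0:
                idx = rng.choice(len(pool2), size=n_far, replace=False)
                members.update(pool2[j] for j in idx)
            rest = [g for g in nodes if g not in members]
            n_rest = size - len(members)
            if n_rest > 0:
                idx = rng.choice(len(rest), size=n_rest, replace=False)
                members.update(rest[j] for j in idx)
            enriched_ids.append(pid)
        else:
            idx = rng.choice(len(nodes), size=size, replace=False)
            members = {nodes[j] for j in idx}
        pathways.append(PathwayAnnotation(
            pathway_id=pid, display_name=pid, category=category,
            genes=frozenset(members),
        ))

    components: list[ComponentDefinition] = []
    for pw in pathways:
        members = sorted(pw.genes)
        order = rng.permutation(len(members))
        shuffled = [members[i] for i in order]
        j, cnum = 0, 0
        while j < len(shuffled):
            remaining = len(shuffled) - j
            if remaining >= 2 and rng.random() < cfg.multi_protein_fraction:
                csize = int(rng.integers(2, min(3, remaining) + 1))
            else:
                csize = 1
            components.append(ComponentDefinition(
                component_id=f"{pw.pathway_id}.c{cnum:03d}",
                pathway_id=pw.pathway_id,
                member_genes=frozenset(shuffled[j:j + csize]),
            ))
            j += csize
            cnum += 1
    return pathways, components, frozenset(enriched_ids)


def generate_expression(
    net: GeneNetwork,
    cfg: SynthConfig,
    bias_pool: frozenset[str] = frozenset(),
) -> tuple[ExpressionMatrix, frozenset[str]]:
    """Two-group log-scale matrix with planted differential genes.

    Baseline values are N(0, noise_sd); planted genes gain +de_effect in
    the case group.  When a bias pool (the enriched pathways' gene union)
    is given, ~70 % of the planted genes are drawn from it.
    """
    rng = _rng(cfg, 3)
    genes = sorted(net.nodes)
    n = cfg.n_samples_per_group
    samples = [f"case{i + 1:02d}" for i in range(n)] + \
              [f"ctrl{i + 1:02d}" for i in range(n)]
    values = rng.normal(0.0, cfg.noise_sd, size=(len(genes), 2 * n))

    planted: set[str] = set()
    if cfg.n_de_genes:
        biased = sorted(bias_pool & set(genes))
        n_bias = min(round(0.7 * cfg.n_de_genes), len(biased))
        if n_bias:
            idx = rng.choice(len(biased), size=n_bias, replace=False)
            planted.update(biased[i] for i in idx)
        rest = [g for g in genes if g not in planted]
        need = cfg.n_de_genes - len(planted)
        idx = rng.choice(len(rest), size=need, replace=False)
        planted.update(rest[i] for i in idx)
        gene_pos = {g: i for i, g in enumerate(genes)}
        rows = sorted(gene_pos[g] for g in planted)
        values[rows, :n] += cfg.de_effect

    frame = pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                         columns=samples)
    groups = pd.Series(["case"] * n + ["control"] * n, index=samples,
                       name="group")
    return ExpressionMatrix(values=frame, groups=groups), frozenset(planted)


def synthesize(cfg: SynthConfig | None = None) -> SyntheticDataset:
    """Generate every input the pipeline consumes, plus the ground truth."""
    cfg = cfg or SynthConfig()
    net, module = generate_network(cfg)
    panels, common = generate_panels(net, cfg, module)
    pathways, components, enriched = generate_pathways(net, common, module, cfg)
    bias_pool = frozenset().union(
        *(p.genes for p in pathways if p.pathway_id in enriched)
    ) if enriched else frozenset()
    expression, de_genes = generate_expression(net, cfg, bias_pool)
    truth = SyntheticTruth(
        planted_common_genes=common,
        planted_enriched_pathway_ids=enriched,
        planted_module_genes=module,
        planted_de_genes=de_genes,
    )
    return SyntheticDataset(
        network=net, panels=panels, pathways=pathways, components=components,
        expression=expression, truth=truth, config=cfg,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every generated artifact as plain text; returns the path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": out / "network.tsv",
        "panels": out / "panels.gmt",
        "pathways": out / "pathways.gmt",
        "components": out / "components.tsv",
        "expression": out / "expression.tsv",
        "design": out / "design.tsv",
        "truth": out / "truth.json",
    }
    write_edge_list(ds.network, paths["network"])
    write_gmt(ds.panels, paths["panels"])
    write_pathways_gmt(ds.pathways, paths["pathways"])
    write_components(ds.components, paths["components"])
    write_expression(ds.expression, paths["expression"], paths["design"])
    truth = {
        "planted_common_genes": sorted(ds.truth.planted_common_genes),
        "planted_enriched_pathway_ids":
            sorted(ds.truth.planted_enriched_pathway_ids),
        "planted_module_genes": sorted(ds.truth.planted_module_genes),
        "planted_de_genes": sorted(ds.truth.planted_de_genes),
    }
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return paths
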