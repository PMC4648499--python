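"""Config-driven orchestration of the full workflow.

Stages run in order — optional RWR panel expansion, panel intersection
with its permutation test, CFNN construction, pathway enrichment,
pathway clustering with common-module extraction, and (when expression
inputs are given) differential expression with component permutation
tests.  Every stage reads its inputs from files and writes plain-text
outputs into the run directory, so any stage can be re-run in isolation
and a run is fully described by its JSON manifest (no timestamps; all
randomness flows from config seeds).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from crosspath import iocore
from crosspath.enrich import EnrichmentConfig, enrich_pathways
from crosspath.iocore import GenePanel
from crosspath.netcore import avg_clustering_coefficient
from crosspath.overlap import build_cfnn, intersect_panels, overlap_permutation_test
from crosspath.pathclust import (
    ClusterConfig,
    build_association_matrix,
    cluster_pathways,
    extract_common_module,
    pathway_cosine_distance,
)
from crosspath.diffexpr import (
    component_permutation_test,
    count_de_components,
    de_test,
    union_deg,
)
from crosspath.rwr import RWRConfig, expand_panel

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and its input."""


@dataclass
class PipelineConfig:
    network: str
    panels: str
    pathways: str
    outdir: str
    components: str | None = None
    expression: list[dict[str, str]] = field(default_factory=list)
    expand_panel: str | None = None
    rwr: RWRConfig = field(default_factory=RWRConfig)
    overlap_replicates: int = 10_000
    seed: int = 0
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    clustering: ClusterConfig = field(default_factory=ClusterConfig)
    de_alpha: float = 0.05
    component_pathways: list[str] = field(default_factory=list)
    component_replicates: int = 10_000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "rwr" in raw:
            raw["rwr"] = RWRConfig(**raw["rwr"])
        if "enrichment" in raw:
            enr = dict(raw["enrichment"])
            if enr.get("custom_universe"):
                enr["custom_universe"] = frozenset(enr["custom_universe"])
            raw["enrichment"] = EnrichmentConfig(**enr)
        if "clustering" in raw:
            raw["clustering"] = ClusterConfig(**raw["clustering"])
        return cls(**raw)


def _json_default(o):
    if hasattr(o, "item"):  # numpy scalars
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n"
    )


def _perm_as_dict(perm) -> dict:
    return {
        "observed": perm.observed,
        "n_replicates": perm.n_replicates,
        "n_at_least": perm.n_at_least,
        "p_empirical": perm.p_empirical,
        "p_parametric": perm.p_parametric,
        "p_parametric_family": "poisson",
        "seed": perm.seed,
        "null_mean": perm.null_mean,
    }


def stage_expand(cfg: PipelineConfig, outdir: Path) -> dict:
    """Copy panels through, RWR-expanding the designated one if any."""
    net = iocore.read_edge_list(cfg.network)
    panels = iocore.read_gmt(cfg.panels)
    info: dict = {"expanded_panel": cfg.expand_panel}
    if cfg.expand_panel is not None:
        names = [p.name for p in panels]
        if cfg.expand_panel not in names:
            raise PipelineError(
                f"expand: panel {cfg.expand_panel!r} not in {names}"
            )
        out_panels = []
        for p in panels:
            if p.name == cfg.expand_panel:
                expanded, ranking = expand_panel(net, p, cfg.rwr)
                ranking.rename("score").to_frame().to_csv(
                    outdir / "rwr_ranking.tsv", sep="\t",
                    index_label="gene", float_format="%.10g",
                )
                info["seed_genes"] = len(p.genes)
                info["expanded_to"] = len(expanded.genes)
                p = expanded
            out_panels.append(p)
        panels = out_panels
    iocore.write_gmt(panels, outdir / "panels_final.gmt")
    info["panel_sizes"] = {p.name: len(p.genes) for p in panels}
    return info


def stage_overlap(cfg: PipelineConfig, outdir: Path) -> dict:
    """Intersect the final panels, test the overlap, and build the CFNN."""
    net = iocore.read_edge_list(cfg.network)
    panels = iocore.read_gmt(outdir / "panels_final.gmt")
    common = intersect_panels(panels)
    (outdir / "common_genes.txt").write_text(
        "".join(f"{g}\n" for g in sorted(common.genes))
    )
    if not common.genes:
        raise PipelineError(
            "overlap: the panel intersection is empty — no common "
            "susceptibility genes; downstream stages cannot run"
        )
    result = overlap_permutation_test(
        universe=set(net.nodes),
        sizes=[len(p.genes) for p in panels],
        observed=len(common.genes),
        n_replicates=cfg.overlap_replicates,
        seed=cfg.seed,
    )
    _write_json(_perm_as_dict(result), outdir / "overlap_test.json")
    cfnn = build_cfnn(net, common)
    iocore.write_edge_list(cfnn, outdir / "cfnn_edges.tsv")
    return {
        "n_common_genes": len(common.genes),
        "p_empirical": result.p_empirical,
        "p_parametric": result.p_parametric,
        "cfnn_nodes": cfnn.number_of_nodes(),
        "cfnn_edges": cfnn.number_of_edges(),
        "cfnn_avg_cc": avg_clustering_coefficient(cfnn),
    }


def stage_enrich(cfg: PipelineConfig, outdir: Path) -> dict:
    """Hypergeometric enrichment of the CFNN genes over the pathway db."""
    net = iocore.read_edge_list(cfg.network)
    cfnn = iocore.read_edge_list(outdir / "cfnn_edges.tsv")
    db = iocore.read_pathways_gmt(cfg.pathways)
    query = GenePanel.from_iterable("cfnn", cfnn.nodes)
    records = enrich_pathways(query, db, cfg.enrichment, network=net)
    pd.DataFrame([asdict(r) for r in records]).to_csv(
        outdir / "enrichment.tsv", sep="\t", index=False,
        float_format="%.10g",
    )
    return {
        "n_pathways_tested": len(records),
        "n_significant": sum(r.significant for r in records),
        "alpha": cfg.enrichment.alpha,
        "universe_policy": cfg.enrichment.universe_policy,
    }


def stage_cluster(cfg: PipelineConfig, outdir: Path) -> dict:
    """Cluster significant pathways and extract each cluster's module."""
    cfnn = iocore.read_edge_list(outdir / "cfnn_edges.tsv")
    db = iocore.read_pathways_gmt(cfg.pathways)
    enr = pd.read_csv(outdir / "enrichment.tsv", sep="\t")
    from crosspath.enrich import EnrichmentRecord
    records = [
        EnrichmentRecord(
            pathway_id=str(row.pathway_id), k=int(row.k), m=int(row.m),
            n=int(row.n), N=int(row.N), p_raw=float(row.p_raw),
            p_adj=float(row.p_adj), direction=str(row.direction),
            significant=bool(row.significant),
        )
        for row in enr.itertuples()
    ]
    matrix = build_association_matrix(cfnn, records, db)
    if len(matrix.pathways) < 2:
        clusters = [frozenset(matrix.pathways)]
    else:
        distances = pathway_cosine_distance(matrix)
        clusters = cluster_pathways(distances, cfg.clustering)
    modules = [
        extract_common_module(cluster, matrix, cfnn, cluster_id=i + 1)
        for i, cluster in enumerate(clusters)
    ]

    rows = []
    for mod in modules:
        for pid in sorted(mod.member_pathways):
            rows.append({"cluster_id": mod.cluster_id, "pathway_id": pid})
    pd.DataFrame(rows).to_csv(outdir / "clusters.tsv", sep="\t", index=False)

    summary = []
    for mod in modules:
        iocore.write_edge_list(
            mod.subnetwork, outdir / f"module_{mod.cluster_id:02d}_edges.tsv"
        )
        summary.append({
            "cluster_id": mod.cluster_id,
            "n_pathways": len(mod.member_pathways),
            "n_common_genes": len(mod.common_genes),
            "common_genes": ",".join(sorted(mod.common_genes)),
            "avg_cc": "" if mod.avg_cc is None else f"{mod.avg_cc:.10g}",
        })
    pd.DataFrame(summary).to_csv(outdir / "modules.tsv", sep="\t", index=False)
    return {
        "n_associated_genes": len(matrix.genes),
        "n_clusters": len(clusters),
        "n_modules_nonempty": sum(1 for m in modules if m.common_genes),
        "linkage": cfg.clustering.linkage,
        "cut_distance": cfg.clustering.cut_distance,
    }


def stage_de(cfg: PipelineConfig, outdir: Path) -> dict:
    """Per-dataset differential expression and the DEG union."""
    tables = []
    for i, item in enumerate(cfg.expression, start=1):
        expr = iocore.read_expression(item["matrix"], item["design"])
        tab = de_test(expr, alpha=cfg.de_alpha)
        tab.to_csv(outdir / f"de_{i:02d}.tsv", sep="\t",
                   float_format="%.10g")
        tables.append(tab)
    deg = union_deg(tables)
    (outdir / "deg_union.txt").write_text(
        "".join(f"{g}\n" for g in sorted(deg.genes))
    )
    return {
        "n_datasets": len(tables),
        "n_deg_union": len(deg.genes),
        "alpha": cfg.de_alpha,
    }


def stage_components(cfg: PipelineConfig, outdir: Path) -> dict:
    """Component permutation tests for the designated pathways."""
    assert cfg.components is not None
    components = iocore.read_components(cfg.components)
    deg_genes = frozenset(
        (outdir / "deg_union.txt").read_text().split()
    )
    deg = GenePanel(name="deg_union", genes=deg_genes)
    # universe: all genes in the expression matrices (the tested genes)
    universe: set[str] = set()
    for i in range(1, len(cfg.expression) + 1):
        tab = pd.read_csv(outdir / f"de_{i:02d}.tsv", sep="\t", index_col=0)
        universe.update(str(g) for g in tab.index)
    results = {}
    for pid in cfg.component_pathways:
        observed = count_de_components(deg, components, pid)
        res = component_permutation_test(
            deg_size=len(deg.genes),
            universe=universe,
            components=components,
            pathway_id=pid,
            observed_hits=observed,
            n_replicates=cfg.component_replicates,
            seed=cfg.seed,
        )
        results[pid] = {
            "n_components": res.n_components,
            "observed_hits": res.observed_hits,
            **{f"perm_{k}": v
               for k, v in _perm_as_dict(res.permutation).items()},
        }
    _write_json(results, outdir / "component_tests.json")
    return {"pathways_tested": sorted(results),
            "universe_size": len(universe)}


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every applicable stage; returns the run directory."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = [("expand", stage_expand), ("overlap", stage_overlap),
              ("enrich", stage_enrich), ("cluster", stage_cluster)]
    if cfg.expression:
        stages.append(("de", stage_de))
        if cfg.components and cfg.component_pathways:
            stages.append(("components", stage_components))

    manifest: dict = {
        "config": {
            "network": str(cfg.network),
            "panels": str(cfg.panels),
            "pathways": str(cfg.pathways),
            "components": str(cfg.components) if cfg.components else None,
            "expression": cfg.expression,
            "expand_panel": cfg.expand_panel,
            "rwr": asdict(cfg.rwr),
            "overlap_replicates": cfg.overlap_replicates,
            "seed": cfg.seed,
            "enrichment": {
                "alpha": cfg.enrichment.alpha,
                "universe_policy": cfg.enrichment.universe_policy,
            },
            "clustering": asdict(cfg.clustering),
            "de_alpha": cfg.de_alpha,
            "component_pathways": cfg.component_pathways,
            "component_replicates": cfg.component_replicates,
        },
        "stages": {},
    }
    for name, fn in stages:
        logger.info("stage %s ...", name)
        try:
            manifest["stages"][name] = fn(cfg, outdir)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    _write_json(manifest, outdir / "manifest.json")
    summarize_run(outdir)
    return outdir


def summarize_run(run_dir: str | Path) -> Path:
    """One-page markdown summary recomputed from the stored artifacts."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest in {run_dir}")
    manifest = json.loads(manifest_path.read_text())
    st = manifest["stages"]
    lines = ["# Run summary", ""]

    ov = st.get("overlap")
    if ov:
        lines += [
            f"- common genes: {ov['n_common_genes']} "
            f"(empirical p = {ov['p_empirical']:.3g}, "
            f"Poisson-fit p = {ov['p_parametric']:.3g})",
            f"- CFNN: {ov['cfnn_nodes']} genes, {ov['cfnn_edges']} "
            f"interactions, avg clustering coefficient "
            f"{ov['cfnn_avg_cc']:.3f}",
        ]
    else:
        lines.append("- overlap stage: MISSING")

    en = st.get("enrich")
    if en:
        lines.append(
            f"- pathways: {en['n_significant']} significant of "
            f"{en['n_pathways_tested']} tested (adjusted p < {en['alpha']})"
        )
        enr_path = run_dir / "enrichment.tsv"
        if enr_path.exists():
            enr = pd.read_csv(enr_path, sep="\t")
            sig = enr[enr["significant"]]
            lines.append(
                "- significant pathways by direction: "
                + ", ".join(
                    f"{d}={int(c)}"
                    for d, c in sig["direction"].value_counts().items()
                )
            )
    else:
        lines.append("- enrichment stage: MISSING")

    cl = st.get("cluster")
    if cl:
        lines.append(
            f"- clusters: {cl['n_clusters']} "
            f"({cl['n_modules_nonempty']} with a non-empty common module); "
            f"{cl['n_associated_genes']} associated genes"
        )
        mod_path = run_dir / "modules.tsv"
        if mod_path.exists():
            mods = pd.read_csv(mod_path, sep="\t")
            for row in mods.itertuples():
                cc = "None" if pd.isna(row.avg_cc) else f"{row.avg_cc:.3f}"
                lines.append(
                    f"  - module {row.cluster_id}: {row.n_pathways} pathways, "
                    f"{row.n_common_genes} common genes, avg_cc {cc}"
                )
    else:
        lines.append("- clustering stage: MISSING")

    if "de" in st:
        de = st["de"]
        lines.append(
            f"- differential expression: {de['n_deg_union']} genes in the "
            f"DEG union across {de['n_datasets']} dataset(s)"
        )
        comp_path = run_dir / "component_tests.json"
        if comp_path.exists():
            comp = json.loads(comp_path.read_text())
            for pid, res in sorted(comp.items()):
                lines.append(
                    f"  - {pid}: {res['observed_hits']}/{res['n_components']} "
                    f"components hit (empirical p = "
                    f"{res['perm_p_empirical']:.3g})"
                )
    else:
        lines.append("- differential expression: not run")

    out = run_dir / "summary.md"
    out.write_text("\n".join(lines) + "\n")
    return out
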