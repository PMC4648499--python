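"""Shared locations and pipeline configuration for the analysis scripts.

All scripts operate on the synthetic benchmark written by 01_simulate.py
under results/synthetic/ and accumulate stage outputs in results/run/.
"""

from pathlib import Path

from crosspath.pipeline import PipelineConfig

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "synthetic"
RUN = ROOT / "results" / "run"

SEED = 1


def pipeline_config(component_pathways: list[str] | None = None
                    ) -> PipelineConfig:
    RUN.mkdir(parents=True, exist_ok=True)
    return PipelineConfig(
        network=str(DATA / "network.tsv"),
        panels=str(DATA / "panels.gmt"),
        pathways=str(DATA / "pathways.gmt"),
        components=str(DATA / "components.tsv"),
        expression=[{"matrix": str(DATA / "expression.tsv"),
                     "design": str(DATA / "design.tsv")}],
        outdir=str(RUN),
        seed=SEED,
        component_pathways=component_pathways or [],
    )
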