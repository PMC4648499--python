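"""Shared pathways and common modules.

Runs two-sided hypergeometric enrichment of the CFNN genes over the
pathway database (BH-adjusted p < 0.05), clusters the significant
pathways by cosine similarity of their associated-gene vectors, and
extracts each cluster's common module with its clustering coefficient.
Compares the findings against the generator's planted truth.
"""

import json

import pandas as pd

from common_config import DATA, RUN, pipeline_config

from crosspath.pipeline import stage_cluster, stage_enrich


def main() -> None:
    cfg = pipeline_config()
    en = stage_enrich(cfg, RUN)
    cl = stage_cluster(cfg, RUN)
    truth = json.loads((DATA / "truth.json").read_text())
    planted = set(truth["planted_enriched_pathway_ids"])
    module_truth = set(truth["planted_module_genes"])

    enr = pd.read_csv(RUN / "enrichment.tsv", sep="\t")
    sig = set(enr.loc[enr["significant"], "pathway_id"])
    print(f"{en['n_significant']} of {en['n_pathways_tested']} pathways "
          f"significant; {len(sig & planted)}/{len(planted)} planted "
          f"recovered, {len(sig - planted)} false positive(s)")
    print(f"{cl['n_associated_genes']} associated genes; "
          f"{cl['n_clusters']} cluster(s) at cut {cl['cut_distance']} "
          f"({cl['linkage']} linkage)")

    modules = pd.read_csv(RUN / "modules.tsv", sep="\t")
    for row in modules.itertuples():
        genes = set() if pd.isna(row.common_genes) \
            else set(str(row.common_genes).split(","))
        jac = (len(genes & module_truth) / len(genes | module_truth)
               if genes | module_truth else 0.0)
        cc = "None" if pd.isna(row.avg_cc) else f"{row.avg_cc:.3f}"
        print(f"  module {row.cluster_id}: {row.n_pathways} pathways, "
              f"{row.n_common_genes} common genes, avg_cc {cc}, "
              f"Jaccard vs planted clique {jac:.2f}")


if __name__ == "__main__":
    main()
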