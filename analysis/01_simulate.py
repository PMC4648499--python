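"""Generate the synthetic benchmark dataset.

Builds a 1500-gene scale-free interaction network with a planted 6-gene
clique module, three disease panels sharing exactly 10 planted common
genes, 120 pathways (8 enriched around the planted neighborhood) with
component definitions, and a two-group expression matrix with 50 planted
differential genes.  Everything is written as plain text under
results/synthetic/ together with the ground truth.
"""

from common_config import DATA, SEED

from crosspath.synthgen import SynthConfig, synthesize, write_dataset


def main() -> None:
    cfg = SynthConfig(seed=SEED)
    ds = synthesize(cfg)
    paths = write_dataset(ds, DATA)
    print(f"network: {ds.network.number_of_nodes()} genes, "
          f"{ds.network.number_of_edges()} interactions")
    print(f"panels: {', '.join(f'{p.name} ({len(p.genes)})' for p in ds.panels)}")
    print(f"pathways: {len(ds.pathways)} "
          f"({len(ds.truth.planted_enriched_pathway_ids)} planted enriched), "
          f"{len(ds.components)} components")
    print(f"expression: {ds.expression.values.shape[0]} genes x "
          f"{ds.expression.values.shape[1]} samples, "
          f"{len(ds.truth.planted_de_genes)} planted differential genes")
    print(f"wrote {len(paths)} files to {DATA}")


if __name__ == "__main__":
    main()
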