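"""Join consensus pathways, DE targets, and the drug table.

Builds the prioritization database (one row per pathway/gene/drug with the
classified effect), the per-(subtype, pathway) target counts, and the
tripartite pathway-gene-drug network of homeostasis records. Writes
results/prioritization.tsv, results/target_counts.tsv,
results/network_edges.tsv and results/network.graphml.
"""

import argparse
from pathlib import Path

import networkx as nx
import pandas as pd

from dbdr import io as dio
from dbdr.prioritize import (
    HOMEOSTASIS,
    build_multipartite_network,
    build_prioritization_table,
    count_targets_by_subtype,
)

ROOT = Path(__file__).resolve().parents[1]
SUBTYPES = ("Basal", "Her2", "LumA", "LumB")


def main():
    parser = argparse.ArgumentParser()
    parser.parse_args()

    data = ROOT / "scratch" / "data"
    out = ROOT / "results"
    consensus_df = pd.read_csv(out / "consensus.tsv", sep="\t")
    consensus = {s: list(g["pathway"]) for s, g in consensus_df.groupby("subtype")}
    de = {
        s: pd.read_csv(ROOT / "scratch" / "de" / f"de_{s}.tsv", sep="\t", index_col="gene")
        for s in SUBTYPES
        if s in consensus
    }
    drugs = dio.read_drug_table(data / "drug_gene_interactions.tsv")
    collection = dio.read_gmt(data / "pathways.gmt")

    table = build_prioritization_table(consensus, de, drugs, collection)
    table.to_csv(out / "prioritization.tsv", sep="\t", index=False)
    counts = count_targets_by_subtype(table)
    counts.to_csv(out / "target_counts.tsv", sep="\t", index=False)
    network = build_multipartite_network(table)
    nx.to_pandas_edgelist(network).to_csv(out / "network_edges.tsv", sep="\t", index=False)
    nx.write_graphml(network, out / "network.graphml")

    homeo = table[table["effect"] == HOMEOSTASIS]
    print(f"{len(table)} prioritization records; {len(homeo)} homeostasis")
    print(
        f"network: {network.number_of_nodes()} nodes, {network.number_of_edges()} edges"
    )
    for _, row in counts.iterrows():
        print(
            f"  {row['subtype']}/{row['pathway']}: {row['n_targets']} targets, "
            f"{row['n_drugs']} drugs"
        )


if __name__ == "__main__":
    main()
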