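"""Generate the study's synthetic dual-platform cohort.

Two cohorts (microarray-like log2 intensities, RNA-seq-like upper-quartile
log2 counts) measure the same 94-sample population: four tumor subtypes
(Basal 12, Her2 8, LumA 40, LumB 20) plus 14 controls, 20 pathways of 50
genes, with three pathways per subtype carrying planted 1.5-control-SD
shifts. A sparse drug-gene table (with one planted counter-regulating drug
per shifted gene) and a drug-drug conflict list complete the inputs.

Large matrices go to scratch/data (regenerate with this script); the
ground truth and a composition summary go to results/.
"""

import argparse
import json
from pathlib import Path

from dbdr import io as dio
from dbdr.simulate import (
    SimConfig,
    default_planted_map,
    generate_drug_table,
    generate_two_platform_cohorts,
)

ROOT = Path(__file__).resolve().parents[1]


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    config = SimConfig(
        planted=default_planted_map(("Basal", "Her2", "LumA", "LumB"), 3, 1.5),
        seed=args.seed,
    )
    cohort_a, cohort_b, collection, truth = generate_two_platform_cohorts(config)
    planted_genes = {
        g: ("up" if d > 0 else "down")
        for shifts in truth.gene_shifts.values()
        for g, d in shifts.items()
        if d != 0
    }
    drugs, ddi, effects = generate_drug_table(
        list(cohort_a.matrix.index), planted=planted_genes, seed=args.seed + 1
    )
    truth.drug_effects = effects

    data = ROOT / "scratch" / "data"
    data.mkdir(parents=True, exist_ok=True)
    dio.write_expression_tsv(cohort_a, data / "expression_a.tsv", data / "annotation_a.tsv")
    dio.write_expression_tsv(cohort_b, data / "expression_b.tsv", data / "annotation_b.tsv")
    dio.write_gmt(collection, data / "pathways.gmt")
    drugs.to_csv(data / "drug_gene_interactions.tsv", sep="\t", index=False)
    ddi.to_csv(data / "drug_drug_interactions.tsv", sep="\t", index=False)

    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    dio.write_ground_truth(truth, out / "ground_truth.json")
    summary = {
        "seed": args.seed,
        "genes": cohort_a.matrix.shape[0],
        "samples_per_platform": cohort_a.matrix.shape[1],
        "subtype_counts": cohort_a.annotation["subtype"].value_counts().to_dict(),
        "n_pathways": len(collection),
        "planted": truth.planted,
        "drug_gene_rows": len(drugs),
        "planted_drugs": len(effects),
    }
    (out / "cohort_summary.json").write_text(json.dumps(summary, indent=1))
    print(f"wrote cohorts to {data}")
    print(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
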