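"""Rank deregulated pathways per subtype and intersect across platforms.

PDS rows are z-scored (PDSz), summarized by the median over the subtype's
tumors, sorted, and the two platforms' top-k lists are intersected to the
consensus deregulated pathways per subtype. Also clusters the eight median
profiles to check that they group by subtype rather than platform. Writes
results/ranking.tsv, results/consensus.tsv, results/profile_clustering.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from dbdr import io as dio
from dbdr.ranking import (
    cluster_subtype_profiles,
    cross_dataset_intersection,
    median_pdsz_by_subtype,
    mutual_nearest_pairs,
    pdsz_transform,
    top_k_pathways,
)

ROOT = Path(__file__).resolve().parents[1]
SUBTYPES = ("Basal", "Her2", "LumA", "LumB")
TOP_K = 10


def main():
    parser = argparse.ArgumentParser()
    parser.parse_args()

    data = ROOT / "scratch" / "data"
    pds_dir = ROOT / "results" / "pds"
    out = ROOT / "results"
    rows, profiles, tops = [], [], {}
    for tag, ds in (("a", "microarray"), ("b", "rnaseq")):
        ann = pd.read_csv(data / f"annotation_{tag}.tsv", sep="\t", index_col="sample_id")
        for subtype in SUBTYPES:
            values = dio.read_pds_values(pds_dir / f"pds_{ds}_{subtype}.tsv")
            med = median_pdsz_by_subtype(pdsz_transform(values), ann, subtype)
            profiles.append((f"{subtype}|{ds}", med))
            top = top_k_pathways(med, TOP_K)
            tops[(subtype, ds)] = top
            for rank, pid in enumerate(top_k_pathways(med, len(med)), start=1):
                rows.append((subtype, ds, pid, med[pid], rank))
    pd.DataFrame(
        rows, columns=["subtype", "dataset", "pathway", "median_pdsz", "rank"]
    ).to_csv(out / "ranking.tsv", sep="\t", index=False)

    consensus_rows = []
    for subtype in SUBTYPES:
        consensus = cross_dataset_intersection(
            tops[(subtype, "microarray")], tops[(subtype, "rnaseq")]
        )
        consensus_rows += [(subtype, pid) for pid in consensus]
        print(f"{subtype}: consensus of top-{TOP_K} lists has {len(consensus)} pathways")
    pd.DataFrame(consensus_rows, columns=["subtype", "pathway"]).to_csv(
        out / "consensus.tsv", sep="\t", index=False
    )

    clustering = cluster_subtype_profiles(profiles)
    pairs = mutual_nearest_pairs(clustering)
    pd.DataFrame(pairs, columns=["profile_a", "profile_b"]).to_csv(
        out / "profile_clustering.tsv", sep="\t", index=False
    )
    by_subtype = sum(a.split("|")[0] == b.split("|")[0] for a, b in pairs)
    print(f"profile clustering: {by_subtype}/{len(pairs)} mutual-NN pairs match by subtype")


if __name__ == "__main__":
    main()
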