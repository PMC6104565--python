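"""Differential expression of each subtype against the controls.

Welch t on log2 values per gene, BH adjustment, status at |log2FC| > 1 and
adjusted p < 0.001; the two platforms' calls are merged with the union
rule for downstream prioritization. Full per-gene tables go to
scratch/de; a per-subtype summary goes to results/de_summary.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from dbdr import io as dio
from dbdr.diffexpr import two_group_de
from dbdr.pipeline import combine_de

ROOT = Path(__file__).resolve().parents[1]
SUBTYPES = ("Basal", "Her2", "LumA", "LumB")


def main():
    parser = argparse.ArgumentParser()
    parser.parse_args()

    data = ROOT / "scratch" / "data"
    de_dir = ROOT / "scratch" / "de"
    de_dir.mkdir(parents=True, exist_ok=True)
    cohorts = {
        tag: dio.read_expression_tsv(
            data / f"expression_{tag}.tsv", data / f"annotation_{tag}.tsv"
        )
        for tag in ("a", "b")
    }
    summary = []
    for subtype in SUBTYPES:
        de_a = two_group_de(cohorts["a"], subtype)
        de_b = two_group_de(cohorts["b"], subtype)
        merged = combine_de(de_a, de_b, "either")
        merged.to_csv(de_dir / f"de_{subtype}.tsv", sep="\t", index_label="gene")
        counts = merged["status"].value_counts()
        summary.append(
            (subtype, int(counts.get("up", 0)), int(counts.get("down", 0)))
        )
        print(
            f"{subtype}: {counts.get('up', 0)} up, {counts.get('down', 0)} down "
            f"(union of both platforms)"
        )
    pd.DataFrame(summary, columns=["subtype", "n_up", "n_down"]).to_csv(
        ROOT / "results" / "de_summary.tsv", sep="\t", index=False
    )


if __name__ == "__main__":
    main()
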