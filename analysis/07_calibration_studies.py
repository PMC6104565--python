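"""Calibration and recovery studies over fresh multi-seed simulations.

Reports: planted-pathway consensus recovery at 1.5 control-SD, the
subtype-vs-platform clustering rate, DE type-I error under a global null,
planted log2FC recovery, and the null consensus size against its
hypergeometric expectation (k*k/N = 5 for top-10 of 20). Seed counts here
are moderate so the whole driver chain stays quick; the results
reproduction script (scripts/acceptance.py) runs the full-size versions.
Writes results/calibration.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from dbdr.experiments import (
    consensus_recovery_study,
    de_null_calibration,
    de_recovery_study,
    null_consensus_study,
    subtype_pairing_study,
)

ROOT = Path(__file__).resolve().parents[1]


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    rows = []
    rec = consensus_recovery_study(n_seeds=10, base_seed=args.seed)
    rows.append(("consensus_recovery_rate", rec["recovered_all"].mean(), 10))
    pair = subtype_pairing_study(n_seeds=10, base_seed=args.seed + 1)
    rows.append(("all_subtypes_paired_rate", pair["all_paired"].mean(), 10))
    rows.append(
        ("per_subtype_pairing_rate", pair["n_paired_subtypes"].sum() / 40, 40)
    )
    null = de_null_calibration(seed=args.seed + 2)
    rows.append(("de_type1_error_at_005", null["type1_rate"], 2000))
    der = de_recovery_study(n_seeds=10, base_seed=args.seed + 3)
    rows.append(("de_planted_recovery_rate", der["fraction_recovered"].mean(), 10))
    nullc = null_consensus_study(n_seeds=50, base_seed=args.seed + 4)
    rows.append(("null_consensus_mean_size", nullc["consensus_size"].mean(), 50))

    table = pd.DataFrame(rows, columns=["quantity", "value", "n"])
    table.to_csv(ROOT / "results" / "calibration.tsv", sep="\t", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
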