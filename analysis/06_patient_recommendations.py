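"""Per-patient therapy recommendations.

Two kinds of patient are run through the recommender at the default PDS
threshold of 0.45: (i) the two bundled basal case-study profiles with
their documented drug options, and (ii) the first simulated Basal patient
of the microarray cohort against this run's own prioritization table.
Writes results/recommendations.json.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from dbdr import io as dio
from dbdr.examples import basal_prioritization_table, empty_ddi, patient_profile
from dbdr.recommend import PatientProfile, recommend_drugs

ROOT = Path(__file__).resolve().parents[1]


def _as_dict(rec):
    return {
        "selected": rec.selected,
        "excluded": rec.excluded,
        "drugs": rec.drugs,
        "dropped_conflicts": rec.dropped_conflicts,
    }


def main():
    parser = argparse.ArgumentParser()
    parser.parse_args()

    payload = {}
    case_table = basal_prioritization_table()
    for pid in ("MB.3058", "MB.5387"):
        rec = recommend_drugs(patient_profile(pid), case_table, empty_ddi())
        payload[pid] = _as_dict(rec)
        print(f"{pid}: {', '.join(rec.drugs)}")

    data = ROOT / "scratch" / "data"
    out = ROOT / "results"
    values = dio.read_pds_values(out / "pds" / "pds_microarray_Basal.tsv")
    ann = pd.read_csv(data / "annotation_a.tsv", sep="\t", index_col="sample_id")
    patient = ann.index[ann["subtype"] == "Basal"][0]
    table = pd.read_csv(out / "prioritization.tsv", sep="\t")
    table = table[table["subtype"] == "Basal"]
    ddi = dio.read_ddi_table(data / "drug_drug_interactions.tsv")
    profile = PatientProfile(patient, values[patient].to_dict(), "Basal")
    rec = recommend_drugs(profile, table, ddi)
    payload[patient] = _as_dict(rec)
    print(
        f"{patient} (simulated): {len(rec.selected)} pathways selected, "
        f"{len(rec.drugs)} conflict-free drugs"
    )

    (out / "recommendations.json").write_text(json.dumps(payload, indent=1))


if __name__ == "__main__":
    main()
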