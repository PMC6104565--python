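"""Per-patient therapy recommendation from pathway deregulation scores.

A patient's candidate pathways are filtered by a PDS threshold (default
0.45, inclusive); the homeostasis drugs of the surviving pathways are
pooled; drug pairs with a known drug–drug interaction are resolved by
dropping the drug whose best supporting pathway has the lower PDS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from dbdr.errors import ValidationError
from dbdr.prioritize import HOMEOSTASIS

DEFAULT_PDS_THRESHOLD = 0.45

REASON_BELOW = "below_threshold"
REASON_NO_TARGET = "no_druggable_target"


@dataclass
class PatientProfile:
    """One patient: per-pathway PDS values and the assigned subtype."""

    patient_id: str
    pds: Mapping[str, float]
    subtype: str

    def __post_init__(self):
        bad = {p: v for p, v in self.pds.items() if not 0.0 <= v <= 1.0}
        if bad:
            raise ValidationError("pds", f"PDS outside [0, 1]: {bad}")


@dataclass
class TherapyRecommendation:
    """Selected pathways, traceable drug entries, exclusions, conflicts."""

    patient_id: str
    selected: list[tuple[str, float]]
    entries: list[dict]  # pathway, pds, gene, drug, interaction_type
    excluded: list[tuple[str, float, str]]
    drugs: list[str]
    dropped_conflicts: list[dict]

    @property
    def drug_set(self) -> set[str]:
        return set(self.drugs)


def select_patient_pathways(
    profile: PatientProfile,
    candidates: Sequence[str],
    pds_threshold: float = DEFAULT_PDS_THRESHOLD,
) -> tuple[list[tuple[str, float]], list[tuple[str, float, str]]]:
    """Split candidate pathways into selected (PDS >= threshold, inclusive)
    and excluded-with-reason, both ordered by descending PDS."""
    if not 0.0 <= pds_threshold <= 1.0:
        raise ValidationError("pds_threshold", "must be in [0, 1]")
    scored = [(p, float(profile.pds[p])) for p in candidates if p in profile.pds]
    scored.sort(key=lambda t: (-t[1], t[0]))
    selected = [(p, v) for p, v in scored if v >= pds_threshold]
    excluded = [(p, v, REASON_BELOW) for p, v in scored if v < pds_threshold]
    return selected, excluded


def _conflict_set(ddi: pd.DataFrame) -> set[frozenset]:
    pairs = set()
    for _, row in ddi.iterrows():
        a, b = str(row["drug_a"]).strip().upper(), str(row["drug_b"]).strip().upper()
        if a != b:
            pairs.add(frozenset((a, b)))
    return pairs


def check_drug_pair_interactions(
    drugs: Mapping[str, float], ddi: pd.DataFrame
) -> tuple[list[str], list[dict]]:
    """Greedy conflict screening over all unordered drug pairs.

    ``drugs`` maps drug name -> support score (best supporting pathway's
    PDS). While any retained pair is in the interaction table, the drug with
    the lower support is dropped (ties: the lexicographically later name).
    Deterministic and idempotent; returns (retained sorted by descending
    support, report of dropped drugs with the conflicting pair).
    """
    conflicts = _conflict_set(ddi)
    retained = dict(drugs)
    dropped: list[dict] = []
    changed = True
    while changed:
        changed = False
        names = sorted(retained, key=lambda d: (-retained[d], d))
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a, b = names[i], names[j]
                if frozenset((a.upper(), b.upper())) in conflicts:
                    # names is sorted by support desc, so b is the weaker
                    dropped.append({"dropped": b, "kept": a, "pair": (a, b)})
                    del retained[b]
                    changed = True
                    break
            if changed:
                break
    order = sorted(retained, key=lambda d: (-retained[d], d))
    return order, dropped


def recommend_drugs(
    profile: PatientProfile,
    prioritization: pd.DataFrame,
    ddi: pd.DataFrame,
    pds_threshold: float = DEFAULT_PDS_THRESHOLD,
) -> TherapyRecommendation:
    """Build the patient's recommendation from a subtype-level
    prioritization table (already restricted to the patient's subtype).

    Only homeostasis records are recommendable. Selected pathways without a
    homeostasis drug are moved to the exclusions with reason
    ``no_druggable_target`` (the "NA" rows of a patient report). The pooled
    drug set is then screened for drug–drug conflicts.
    """
    candidates = list(profile.pds)
    selected, excluded = select_patient_pathways(profile, candidates, pds_threshold)
    homeo = prioritization[prioritization["effect"] == HOMEOSTASIS]
    by_pathway = {pid: grp for pid, grp in homeo.groupby("pathway")}
    entries: list[dict] = []
    support: dict[str, float] = {}
    final_selected = []
    for pid, pds_value in selected:
        grp = by_pathway.get(pid)
        if grp is None or grp.empty:
            excluded.append((pid, pds_value, REASON_NO_TARGET))
            continue
        final_selected.append((pid, pds_value))
        for _, row in grp.sort_values(["gene", "drug"]).iterrows():
            drug = str(row["drug"]).strip().upper()
            entries.append(
                {
                    "pathway": pid,
                    "pds": pds_value,
                    "gene": row["gene"],
                    "drug": drug,
                    "interaction_type": row["interaction_type"],
                }
            )
            support[drug] = max(support.get(drug, 0.0), pds_value)
    retained, dropped = check_drug_pair_interactions(support, ddi)
    retained_set = set(retained)
    entries = [e for e in entries if e["drug"] in retained_set]
    return TherapyRecommendation(
        patient_id=profile.patient_id,
        selected=final_selected,
        entries=entries,
        excluded=excluded,
        drugs=retained,
        dropped_conflicts=dropped,
    )
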