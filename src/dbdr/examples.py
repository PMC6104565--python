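"""Bundled worked example: a basal breast-tumor case study.

A small excerpt of a prioritization database (drug–target rows with their
log2 fold changes and interaction types) and two basal-subtype patients'
pathway deregulation profiles, used in documentation and as an executable
worked example of the effect classifier and the per-patient recommender.
"""

from __future__ import annotations

import pandas as pd

from dbdr.recommend import PatientProfile

#: Prioritization-database excerpt: (pathway, gene, drug, interaction type,
#: source, log2FC, expected effect).
EXAMPLE_DB_ROWS: list[dict] = [
    dict(pathway="hsa00230 Purine metabolism", gene="HPRT1", drug="AZATHIOPRINE",
         interaction_type="Inhibitor", source="DrugBank", log2FC=1.623,
         effect="Homeostasis"),
    dict(pathway="hsa00230 Purine metabolism", gene="PNP", drug="CLADRINE",
         interaction_type="Inducer", source="DrugBank", log2FC=1.628,
         effect="Anti-homeostasis"),
    dict(pathway="hsa00230 Purine metabolism", gene="PDE2A", drug="TOFISPAM",
         interaction_type="Inhibitor", source="DrugBank", log2FC=-3.962,
         effect="Anti-homeostasis"),
    dict(pathway="hsa00230 Purine metabolism", gene="PDE8B", drug="KETOTIFEN",
         interaction_type="Inhibitor", source="DrugBank", log2FC=-2.509,
         effect="Anti-homeostasis"),
    dict(pathway="hsa00310 Lysine degradation", gene="ALDH2", drug="DISULFIRAM",
         interaction_type="Inhibitor", source="DrugBank", log2FC=-2.363,
         effect="Anti-homeostasis"),
    dict(pathway="hsa00100 Steroid biosynthesis", gene="SQLE", drug="NAFTIFINE",
         interaction_type="Inhibitor", source="DrugBank", log2FC=2.703,
         effect="Homeostasis"),
    dict(pathway="hsa00100 Steroid biosynthesis", gene="SQLE", drug="TERBINAFINE",
         interaction_type="Inhibitor", source="DrugBank", log2FC=2.703,
         effect="Homeostasis"),
    dict(pathway="hsa00100 Steroid biosynthesis", gene="SQLE", drug="BUTENAFINE",
         interaction_type="Inhibitor", source="DrugBank", log2FC=2.703,
         effect="Homeostasis"),
    dict(pathway="hsa00100 Steroid biosynthesis", gene="SQLE", drug="ELLAGIC ACID",
         interaction_type="Inhibitor", source="DrugBank", log2FC=2.703,
         effect="Homeostasis"),
]

#: Homeostasis drug options per deregulated pathway for the basal case
#: study ("n/a" targets mean the pathway has no druggable DE target).
BASAL_PATHWAY_DRUGS: dict[str, list[tuple[str, str, str]]] = {
    "Steroid biosynthesis": [("SQLE", "TERBINAFINE", "inhibitor")],
    "Pyrimidine metabolism": [
        ("TYMS", "PEMETREXED", "inhibitor"),
        ("TYMS", "CAPECITABINE", "inhibitor"),
    ],
    "Sphingolipid metabolism": [("SPHK1", "SK1-I", "inhibitor")],
    "Olfactory transduction": [],
    "Apoptosis": [
        ("BIRC5", "ALVOCIDIB", "inhibitor"),
        ("BIRC5", "PACLITAXEL", "inhibitor"),
    ],
    "Oocyte meiosis": [
        ("AURKA", "ALISERTIB", "inhibitor"),
        ("CDK1", "DINACICLIB", "inhibitor"),
    ],
    "Cell cycle": [("CDK1", "DINACICLIB", "inhibitor")],
    "Neurotrophin signaling pathway": [],
    "ErbB signaling pathway": [],
    "Drug metabolism - other enzymes": [],
}

#: Per-patient pathway deregulation scores (two basal-subtype patients).
PATIENT_PDS: dict[str, dict[str, float]] = {
    "MB.3058": {
        "Steroid biosynthesis": 0.937,
        "Pyrimidine metabolism": 0.466,
        "Sphingolipid metabolism": 0.628,
        "Olfactory transduction": 0.736,
        "Apoptosis": 0.398,
        "Oocyte meiosis": 0.406,
        "Cell cycle": 0.328,
        "Neurotrophin signaling pathway": 0.765,
        "ErbB signaling pathway": 0.783,
        "Drug metabolism - other enzymes": 0.712,
    },
    "MB.5387": {
        "Steroid biosynthesis": 0.597,
        "Pyrimidine metabolism": 0.605,
        "Sphingolipid metabolism": 0.590,
        "Olfactory transduction": 0.500,
        "Apoptosis": 0.712,
        "Oocyte meiosis": 1.0,
        "Cell cycle": 0.718,
        "Neurotrophin signaling pathway": 0.839,
        "ErbB signaling pathway": 0.616,
        "Drug metabolism - other enzymes": 0.846,
    },
}


def example_database() -> pd.DataFrame:
    """The prioritization-database excerpt as a DataFrame."""
    return pd.DataFrame(EXAMPLE_DB_ROWS)


def basal_prioritization_table() -> pd.DataFrame:
    """Basal-subtype homeostasis records backing the patient case study."""
    rows = [
        dict(subtype="Basal", pathway=pathway, pathway_name=pathway, gene=gene,
             drug=drug, interaction_type=itype, source="case-study",
             log2FC=float("nan"), effect="Homeostasis")
        for pathway, options in BASAL_PATHWAY_DRUGS.items()
        for gene, drug, itype in options
    ]
    return pd.DataFrame(rows)


def patient_profile(patient_id: str) -> PatientProfile:
    return PatientProfile(patient_id, dict(PATIENT_PDS[patient_id]), "Basal")


def empty_ddi() -> pd.DataFrame:
    return pd.DataFrame(columns=["drug_a", "drug_b", "note"])
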