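"""Drug prioritization: join consensus pathways, DE targets, and drugs.

A drug is prioritized for a subtype when it interacts with a differentially
expressed gene belonging to a consensus deregulated pathway. The expected
effect of the interaction is classified by sign logic: a drug that pushes a
deregulated target back toward its control expression level (inhibiting an
overexpressed gene, activating an underexpressed one) restores homeostasis;
the opposite push is anti-homeostasis; directionless interaction types are
undetermined.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from dbdr.errors import DataError
from dbdr.diffexpr import STATUS_DOWN, STATUS_UP
from dbdr.genesets import GeneSetCollection

INHIBITORY = frozenset(
    {"inhibitor", "antagonist", "blocker", "suppressor", "negative modulator"}
)
ACTIVATING = frozenset(
    {"inducer", "activator", "agonist", "positive modulator", "stimulator"}
)

HOMEOSTASIS = "Homeostasis"
ANTI_HOMEOSTASIS = "Anti-homeostasis"
UNDETERMINED = "Undetermined"

TABLE_COLUMNS = [
    "subtype",
    "pathway",
    "pathway_name",
    "gene",
    "drug",
    "interaction_type",
    "source",
    "log2FC",
    "effect",
]


def classify_interaction_direction(interaction_type: str) -> str:
    """Map an interaction-type claim to inhibitory / activating / other.

    Case-insensitive after whitespace trimming; unknown vocabulary falls to
    'other' (never an error) so novel claim types degrade to Undetermined.
    """
    t = str(interaction_type).strip().lower()
    if t in INHIBITORY:
        return "inhibitory"
    if t in ACTIVATING:
        return "activating"
    return "other"


def classify_effect(de_status: str, direction: str) -> str:
    """Expected effect of a drug on a differentially expressed target."""
    if de_status not in (STATUS_UP, STATUS_DOWN):
        raise DataError(
            f"effect is defined only for up/down genes, got {de_status!r}"
        )
    if direction == "other":
        return UNDETERMINED
    counter_regulating = (de_status == STATUS_UP and direction == "inhibitory") or (
        de_status == STATUS_DOWN and direction == "activating"
    )
    return HOMEOSTASIS if counter_regulating else ANTI_HOMEOSTASIS


def _norm(s: str) -> str:
    return str(s).strip().upper()


def build_prioritization_table(
    consensus: Mapping[str, Sequence[str]],
    de: Mapping[str, pd.DataFrame],
    drugs: pd.DataFrame,
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """One record per (subtype, pathway, gene, drug) where the pathway is in
    the subtype's consensus set, the gene is a differentially expressed
    pathway member, and the drug targets the gene.

    ``consensus`` maps subtype -> consensus pathway ids; ``de`` maps
    subtype -> DE table (with status set). Gene/drug matching is exact,
    case-insensitive, whitespace-trimmed. Rows are ordered by
    (subtype, pathway, gene, drug).
    """
    drug_index: dict[str, list[tuple[str, str, str]]] = {}
    for _, row in drugs.iterrows():
        drug_index.setdefault(_norm(row["gene"]), []).append(
            (str(row["drug"]).strip(), str(row["interaction_type"]), str(row["source"]))
        )
    records = []
    for subtype in sorted(consensus):
        de_table = de[subtype]
        status = {_norm(g): s for g, s in de_table["status"].items()}
        lfc = {_norm(g): v for g, v in de_table["log2FC"].items()}
        for pid in sorted(consensus[subtype]):
            if pid not in collection:
                raise DataError(f"consensus pathway {pid!r} not in the collection")
            gs = collection[pid]
            for gene in gs.members:
                g = _norm(gene)
                if status.get(g) not in (STATUS_UP, STATUS_DOWN):
                    continue
                for drug, itype, source in drug_index.get(g, []):
                    direction = classify_interaction_direction(itype)
                    records.append(
                        (
                            subtype,
                            pid,
                            gs.name,
                            gene,
                            drug,
                            itype,
                            source,
                            lfc[g],
                            classify_effect(status[g], direction),
                        )
                    )
    table = pd.DataFrame(records, columns=TABLE_COLUMNS)
    return table.sort_values(
        ["subtype", "pathway", "gene", "drug"], ignore_index=True
    )


def count_targets_by_subtype(table: pd.DataFrame) -> pd.DataFrame:
    """Distinct druggable DE targets (and drugs) per (subtype, pathway)."""
    if table.empty:
        return pd.DataFrame(columns=["subtype", "pathway", "n_targets", "n_drugs"])
    grouped = table.groupby(["subtype", "pathway"]).agg(
        n_targets=("gene", "nunique"), n_drugs=("drug", "nunique")
    )
    return grouped.reset_index()


def build_multipartite_network(
    table: pd.DataFrame, effect_filter: str | None = HOMEOSTASIS
) -> nx.Graph:
    """Tripartite pathway–gene–drug graph from a prioritization table.

    Nodes carry a ``layer`` attribute (pathway/gene/drug); pathway–gene and
    gene–drug edges carry the interaction type and effect; there are no
    pathway–drug edges. ``effect_filter`` keeps only records with the
    requested effect (None keeps all).
    """
    g = nx.Graph()
    rows = table if effect_filter is None else table[table["effect"] == effect_filter]
    for _, row in rows.iterrows():
        pnode = f"pathway::{row['pathway']}"
        gnode = f"gene::{row['gene']}"
        dnode = f"drug::{row['drug']}"
        g.add_node(pnode, layer="pathway", label=row["pathway"])
        g.add_node(gnode, layer="gene", label=row["gene"])
        g.add_node(dnode, layer="drug", label=row["drug"])
        g.add_edge(pnode, gnode, kind="membership", effect=row["effect"])
        g.add_edge(
            gnode,
            dnode,
            kind="interaction",
            interaction_type=row["interaction_type"],
            effect=row["effect"],
        )
    return g
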