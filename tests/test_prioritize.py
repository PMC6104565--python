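"""Drug prioritization: interaction-direction vocabulary, effect logic,
the consensus x DE x drug join, target counting, and the tripartite
network."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from dbdr.errors import DataError
from dbdr.examples import example_database
from dbdr.experiments import homeostasis_recovery_study
from dbdr.genesets import GeneSetCollection
from dbdr.prioritize import (
    ANTI_HOMEOSTASIS,
    HOMEOSTASIS,
    UNDETERMINED,
    build_multipartite_network,
    build_prioritization_table,
    classify_effect,
    classify_interaction_direction,
    count_targets_by_subtype,
)


class TestInteractionDirection:
    @pytest.mark.parametrize(
        "itype,expected",
        [
            ("Inhibitor", "inhibitory"),
            ("  antagonist ", "inhibitory"),
            ("BLOCKER", "inhibitory"),
            ("Inducer", "activating"),
            ("agonist", "activating"),
            ("binder", "other"),
            ("n/a", "other"),
            ("some novel claim", "other"),
        ],
    )
    def test_vocabulary(self, itype, expected):
        assert classify_interaction_direction(itype) == expected


class TestEffectClassifier:
    @pytest.mark.parametrize(
        "status,direction,expected",
        [
            ("up", "inhibitory", HOMEOSTASIS),
            ("down", "activating", HOMEOSTASIS),
            ("up", "activating", ANTI_HOMEOSTASIS),
            ("down", "inhibitory", ANTI_HOMEOSTASIS),
            ("up", "other", UNDETERMINED),
            ("down", "other", UNDETERMINED),
        ],
    )
    def test_truth_table(self, status, direction, expected):
        assert classify_effect(status, direction) == expected

    def test_non_significant_status_rejected(self):
        with pytest.raises(DataError):
            classify_effect("not_significant", "inhibitory")

    def test_symmetric_under_simultaneous_flip(self):
        flip_s = {"up": "down", "down": "up"}
        flip_d = {"inhibitory": "activating", "activating": "inhibitory", "other": "other"}
        for s, d in itertools.product(("up", "down"), ("inhibitory", "activating", "other")):
            assert classify_effect(s, d) == classify_effect(flip_s[s], flip_d[d])

    def test_case_study_database_effects_reproduced(self):
        # nine rows of a published-style prioritization excerpt
        db = example_database()
        for _, row in db.iterrows():
            status = "up" if row["log2FC"] > 0 else "down"
            direction = classify_interaction_direction(row["interaction_type"])
            assert classify_effect(status, direction) == row["effect"]


def _join_inputs(seed=0, n_genes=30, n_pathways=3, n_drugs=8):
    rng = np.random.default_rng(seed)
    genes = [f"g{i:02d}" for i in range(n_genes)]
    collection = GeneSetCollection.from_dict(
        {f"p{k}": genes[k * 10 : (k + 1) * 10] for k in range(n_pathways)}
    )
    consensus = {"Basal": [f"p{k}" for k in range(n_pathways) if rng.random() < 0.8]}
    status = rng.choice(["up", "down", "not_significant"], size=n_genes, p=[0.3, 0.3, 0.4])
    de = {
        "Basal": pd.DataFrame(
            {
                "log2FC": np.where(status == "up", 2.0, np.where(status == "down", -2.0, 0.1)),
                "t": 0.0,
                "pvalue": 1e-6,
                "adj_pvalue": 1e-5,
                "status": status,
            },
            index=genes,
        )
    }
    rows = []
    for d in range(n_drugs):
        for g in rng.choice(genes, size=4, replace=False):
            rows.append((f"D{d}", g, rng.choice(["inhibitor", "inducer", "binder"]), "src"))
    drugs = pd.DataFrame(rows, columns=["drug", "gene", "interaction_type", "source"])
    return consensus, de, drugs, collection


class TestBuildTable:
    def test_no_significant_genes_gives_empty_table(self):
        consensus, de, drugs, collection = _join_inputs()
        de["Basal"]["status"] = "not_significant"
        table = build_prioritization_table(consensus, de, drugs, collection)
        assert table.empty

    def test_matches_triple_loop_join_oracle(self):
        consensus, de, drugs, collection = _join_inputs(seed=5)
        table = build_prioritization_table(consensus, de, drugs, collection)
        expected = 0
        for pid in consensus["Basal"]:
            for gene in collection.members(pid):
                if de["Basal"].loc[gene, "status"] not in ("up", "down"):
                    continue
                expected += int((drugs["gene"] == gene).sum())
        assert len(table) == expected

    def test_rows_sorted_deterministically(self):
        consensus, de, drugs, collection = _join_inputs(seed=6)
        table = build_prioritization_table(consensus, de, drugs, collection)
        key = list(zip(table["subtype"], table["pathway"], table["gene"], table["drug"]))
        assert key == sorted(key)

    def test_shrinking_consensus_never_adds_records(self):
        consensus, de, drugs, collection = _join_inputs(seed=7)
        consensus["Basal"] = ["p0", "p1", "p2"]
        full = build_prioritization_table(consensus, de, drugs, collection)
        smaller = build_prioritization_table(
            {"Basal": ["p0", "p2"]}, de, drugs, collection
        )
        assert len(smaller) <= len(full)
        full_keys = set(zip(full["pathway"], full["gene"], full["drug"]))
        small_keys = set(zip(smaller["pathway"], smaller["gene"], smaller["drug"]))
        assert small_keys <= full_keys

    def test_homeostasis_records_have_counter_regulating_sign(self):
        consensus, de, drugs, collection = _join_inputs(seed=8)
        consensus["Basal"] = ["p0", "p1", "p2"]
        table = build_prioritization_table(consensus, de, drugs, collection)
        homeo = table[table["effect"] == HOMEOSTASIS]
        for _, row in homeo.iterrows():
            direction = classify_interaction_direction(row["interaction_type"])
            assert (row["log2FC"] > 0, direction) in [
                (True, "inhibitory"),
                (False, "activating"),
            ]

    def test_gene_in_multiple_consensus_pathways_yields_one_record_each(self):
        genes = [f"g{i}" for i in range(6)]
        collection = GeneSetCollection.from_dict(
            {"pA": genes[:4], "pB": genes[2:]}
        )
        de = {
            "Basal": pd.DataFrame(
                {"log2FC": 2.0, "t": 0.0, "pvalue": 1e-9, "adj_pvalue": 1e-8,
                 "status": "up"},
                index=genes,
            )
        }
        drugs = pd.DataFrame(
            [("DX", "g2", "inhibitor", "src")],
            columns=["drug", "gene", "interaction_type", "source"],
        )
        table = build_prioritization_table({"Basal": ["pA", "pB"]}, de, drugs, collection)
        assert sorted(table["pathway"]) == ["pA", "pB"]


class TestTargetCounts:
    def test_empty(self):
        assert count_targets_by_subtype(pd.DataFrame(columns=["subtype", "pathway", "gene", "drug"])).empty

    def test_distinctness(self):
        table = pd.DataFrame(
            {
                "subtype": ["Basal"] * 3,
                "pathway": ["p0"] * 3,
                "gene": ["g1"] * 3,
                "drug": ["D1", "D2", "D3"],
                "effect": [HOMEOSTASIS] * 3,
            }
        )
        summary = count_targets_by_subtype(table)
        assert summary.loc[0, "n_targets"] == 1
        assert summary.loc[0, "n_drugs"] == 3

    def test_matches_brute_force_distinct_count(self):
        consensus, de, drugs, collection = _join_inputs(seed=9)
        table = build_prioritization_table(consensus, de, drugs, collection)
        summary = count_targets_by_subtype(table)
        for _, row in summary.iterrows():
            sub = table[(table["subtype"] == row["subtype"]) & (table["pathway"] == row["pathway"])]
            assert row["n_targets"] == len(set(sub["gene"]))
            assert row["n_drugs"] == len(set(sub["drug"]))


class TestNetwork:
    def test_empty_table_empty_graph(self):
        g = build_multipartite_network(pd.DataFrame(columns=[
            "pathway", "gene", "drug", "interaction_type", "effect"]))
        assert g.number_of_nodes() == 0

    def test_case_study_steroid_rows(self):
        db = example_database()
        steroid = db[db["pathway"].str.contains("Steroid")].copy()
        g = build_multipartite_network(steroid, effect_filter=HOMEOSTASIS)
        layers = nx.get_node_attributes(g, "layer")
        assert sum(v == "pathway" for v in layers.values()) == 1
        assert sum(v == "gene" for v in layers.values()) == 1
        assert sum(v == "drug" for v in layers.values()) == 4
        assert g.number_of_edges() == 5

    def test_no_pathway_drug_edges_and_counts_match_brute_force(self):
        consensus, de, drugs, collection = _join_inputs(seed=10)
        table = build_prioritization_table(consensus, de, drugs, collection)
        g = build_multipartite_network(table, effect_filter=None)
        layers = nx.get_node_attributes(g, "layer")
        for u, v in g.edges():
            assert {layers[u], layers[v]} in ({"pathway", "gene"}, {"gene", "drug"})
        pg = {(r["pathway"], r["gene"]) for _, r in table.iterrows()}
        gd = {(r["gene"], r["drug"]) for _, r in table.iterrows()}
        assert g.number_of_edges() == len(pg) + len(gd)


class TestEndToEndRecovery:
    def test_planted_inhibitors_reach_homeostasis_table(self):
        df = homeostasis_recovery_study(n_seeds=20, base_seed=13)
        assert int(df["recovered"].sum()) >= 18
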