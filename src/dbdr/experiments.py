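"""Multi-seed simulation studies over the pipeline.

These functions are the package's calibration and recovery experiments:
each one generates synthetic cohorts at stated study conditions, runs the
relevant pipeline stages, and measures an outcome (planted-pathway
recovery, subtype-vs-platform clustering, DE type-I error, null consensus
size). They back the analysis drivers, the test suite, and the results
reproduction script.
"""

from __future__ import annotations

import dataclasses
from typing import Any, Sequence

import numpy as np
import pandas as pd

from dbdr.diffexpr import two_group_de
from dbdr.pds import compute_pds_matrix, pathway_pds, subtype_view
from dbdr.ranking import (
    cluster_subtype_profiles,
    cross_dataset_intersection,
    median_pdsz_by_subtype,
    mutual_nearest_pairs,
    pdsz_transform,
    top_k_pathways,
)
from dbdr.simulate import (
    SimConfig,
    default_planted_map,
    generate_cohort,
    generate_two_platform_cohorts,
    pathway_id,
)


def spawn_seeds(base_seed: int, n: int) -> list[int]:
    """Derive n reproducible per-replicate seeds (< 2**31) from one seed."""
    state = np.random.SeedSequence(base_seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def single_subtype_config(
    seed: int,
    effect: float = 1.5,
    n_planted: int = 3,
    n_tumor: int = 60,
    n_control: int = 30,
    n_genes: int = 1000,
    n_pathways: int = 20,
    genes_per_pathway: int = 50,
    subtype: str = "Basal",
) -> SimConfig:
    """The recovery-study cohort: one subtype, two platforms, planted
    deregulation in the first ``n_planted`` pathways."""
    planted = (
        {subtype: [(pathway_id(i), effect) for i in range(n_planted)]}
        if n_planted
        else {}
    )
    return SimConfig(
        n_genes=n_genes,
        n_pathways=n_pathways,
        genes_per_pathway=genes_per_pathway,
        n_tumor=n_tumor,
        n_control=n_control,
        subtypes=(subtype,),
        planted=planted,
        seed=seed,
    )


def consensus_for_config(
    config: SimConfig, k: int = 10, params: dict | None = None
) -> tuple[dict[str, list[str]], Any]:
    """Two-platform consensus pathway sets per subtype for one cohort."""
    cohort_a, cohort_b, collection, truth = generate_two_platform_cohorts(config)
    consensus: dict[str, list[str]] = {}
    for subtype in config.subtypes:
        tops = []
        for cohort in (cohort_a, cohort_b):
            view = subtype_view(cohort, subtype)
            pds = compute_pds_matrix(view, collection, params)
            med = median_pdsz_by_subtype(pdsz_transform(pds), view.annotation, subtype)
            tops.append(top_k_pathways(med, k))
        consensus[subtype] = cross_dataset_intersection(tops[0], tops[1])
    return consensus, truth


def consensus_recovery_study(
    n_seeds: int = 20,
    base_seed: int = 0,
    effect: float = 1.5,
    k: int = 10,
    **config_kwargs,
) -> pd.DataFrame:
    """Planted-pathway recovery across seeds.

    Per seed: are all planted pathways inside the cross-dataset consensus
    at top-k? Returns one row per seed with the consensus size and the
    number of planted pathways recovered.
    """
    rows = []
    for seed in spawn_seeds(base_seed, n_seeds):
        config = single_subtype_config(seed, effect=effect, **config_kwargs)
        consensus, truth = consensus_for_config(config, k=k)
        subtype = config.subtypes[0]
        planted = set(truth.planted.get(subtype, []))
        got = set(consensus[subtype])
        rows.append(
            {
                "seed": seed,
                "consensus_size": len(got),
                "n_planted": len(planted),
                "n_recovered": len(planted & got),
                "recovered_all": planted <= got,
            }
        )
    return pd.DataFrame(rows)


def null_consensus_study(
    n_seeds: int = 200,
    base_seed: int = 0,
    k: int = 10,
    n_tumor: int = 30,
    n_control: int = 14,
    **config_kwargs,
) -> pd.DataFrame:
    """Consensus sizes under the global null (nothing planted).

    With independent datasets and exchangeable pathways, the size of the
    intersection of two top-k lists of N pathways is hypergeometric with
    mean k*k/N.
    """
    rows = []
    for seed in spawn_seeds(base_seed, n_seeds):
        config = single_subtype_config(
            seed, n_planted=0, n_tumor=n_tumor, n_control=n_control, **config_kwargs
        )
        consensus, _ = consensus_for_config(config, k=k)
        rows.append({"seed": seed, "consensus_size": len(consensus[config.subtypes[0]])})
    return pd.DataFrame(rows)


def subtype_profiles_two_platforms(
    config: SimConfig, params: dict | None = None
) -> list[tuple[str, pd.Series]]:
    """Median-PDSz profile per (subtype, platform), labelled
    '<subtype>|<dataset>'."""
    cohort_a, cohort_b, collection, _ = generate_two_platform_cohorts(config)
    profiles = []
    for cohort in (cohort_a, cohort_b):
        for subtype in config.subtypes:
            view = subtype_view(cohort, subtype)
            pds = compute_pds_matrix(view, collection, params)
            med = median_pdsz_by_subtype(pdsz_transform(pds), view.annotation, subtype)
            profiles.append((f"{subtype}|{cohort.dataset_id}", med))
    return profiles


def subtype_pairing_study(
    n_seeds: int = 20,
    base_seed: int = 0,
    effect: float = 1.5,
    n_per_subtype: int = 3,
    subtypes: Sequence[str] = ("Basal", "Her2", "LumA", "LumB"),
) -> pd.DataFrame:
    """Do deregulation profiles cluster by biology rather than platform?

    Per seed, a two-platform cohort with distinct planted pathways per
    subtype is generated; the 2 x len(subtypes) median-PDSz profiles are
    clustered (correlation distance, average linkage); success means every
    subtype's two platform profiles are mutual nearest neighbors.
    """
    rows = []
    for seed in spawn_seeds(base_seed, n_seeds):
        config = SimConfig(
            subtypes=tuple(subtypes),
            planted=default_planted_map(subtypes, n_per_subtype, effect),
            seed=seed,
        )
        profiles = subtype_profiles_two_platforms(config)
        clustering = cluster_subtype_profiles(profiles)
        pairs = mutual_nearest_pairs(clustering)
        by_subtype = {
            frozenset(lab.split("|")[0] for lab in pair) for pair in pairs
        }
        paired = sum(frozenset([s]) in by_subtype for s in subtypes)
        rows.append(
            {"seed": seed, "n_paired_subtypes": paired, "all_paired": paired == len(subtypes)}
        )
    return pd.DataFrame(rows)


def de_null_calibration(
    seed: int = 0, n_genes: int = 2000, n_per_group: int = 30, alpha: float = 0.05
) -> dict[str, float]:
    """Type-I error of the Welch test under a global null."""
    config = SimConfig(
        n_genes=n_genes,
        n_pathways=1,
        genes_per_pathway=1,
        n_tumor=n_per_group,
        n_control=n_per_group,
        subtypes=("Basal",),
        planted={},
        seed=seed,
    )
    cohort, _, _ = generate_cohort(config)
    de = two_group_de(cohort, "Basal")
    rate = float((de["pvalue"] < alpha).mean())
    return {"type1_rate": rate, "alpha": alpha, "n_genes": n_genes}


def de_recovery_study(
    n_seeds: int = 20,
    base_seed: int = 0,
    log2fc: float = 2.0,
    sigma: float = 0.5,
    n_per_group: int = 30,
    n_planted_genes: int = 50,
    lfc_window: float = 0.3,
    adjp_cut: float = 1e-3,
) -> pd.DataFrame:
    """Recovery of a planted log2 fold change by the Welch DE route.

    Per seed: fraction of planted genes whose estimated log2FC is within
    ``lfc_window`` of truth with BH-adjusted p below ``adjp_cut``.
    """
    rows = []
    for seed in spawn_seeds(base_seed, n_seeds):
        config = SimConfig(
            n_genes=1000,
            n_pathways=1,
            genes_per_pathway=n_planted_genes,
            n_tumor=n_per_group,
            n_control=n_per_group,
            subtypes=("Basal",),
            planted={"Basal": [(pathway_id(0), log2fc / sigma)]},
            noise_sd=sigma,
            up_fraction=1.0,
            seed=seed,
        )
        cohort, collection, truth = generate_cohort(config)
        de = two_group_de(cohort, "Basal")
        planted_genes = [g for g, d in truth.gene_shifts["Basal"].items() if d != 0]
        sub = de.loc[planted_genes]
        ok = (np.abs(sub["log2FC"] - log2fc) <= lfc_window) & (sub["adj_pvalue"] < adjp_cut)
        rows.append({"seed": seed, "fraction_recovered": float(ok.mean())})
    return pd.DataFrame(rows)


def homeostasis_recovery_study(
    n_seeds: int = 20,
    base_seed: int = 0,
    effect: float = 1.5,
    k: int = 10,
    **config_kwargs,
) -> pd.DataFrame:
    """End-to-end recovery of planted counter-regulating drugs.

    Per seed: a two-platform cohort with planted deregulation plus a drug
    table containing one dedicated inhibitor per up-shifted planted gene
    (and activator per down-shifted gene); the full consensus -> DE ->
    prioritization join is run. Success means at least one planted
    inhibitor of an up-planted gene lands in the Homeostasis table.
    """
    from dbdr.diffexpr import two_group_de
    from dbdr.pipeline import combine_de
    from dbdr.prioritize import HOMEOSTASIS, build_prioritization_table
    from dbdr.simulate import generate_drug_table

    rows = []
    for seed in spawn_seeds(base_seed, n_seeds):
        config = single_subtype_config(seed, effect=effect, **config_kwargs)
        subtype = config.subtypes[0]
        cohort_a, cohort_b, collection, truth = generate_two_platform_cohorts(config)
        tops = []
        for cohort in (cohort_a, cohort_b):
            view = subtype_view(cohort, subtype)
            pds = compute_pds_matrix(view, collection)
            med = median_pdsz_by_subtype(pdsz_transform(pds), view.annotation, subtype)
            tops.append(top_k_pathways(med, k))
        consensus = {subtype: cross_dataset_intersection(tops[0], tops[1])}
        de = {
            subtype: combine_de(
                two_group_de(cohort_a, subtype), two_group_de(cohort_b, subtype)
            )
        }
        planted_genes = {
            g: ("up" if delta > 0 else "down")
            for g, delta in truth.gene_shifts[subtype].items()
            if delta != 0
        }
        drugs, _, drug_effects = generate_drug_table(
            list(cohort_a.matrix.index), planted=planted_genes, seed=seed + 1
        )
        table = build_prioritization_table(consensus, de, drugs, collection)
        homeo = table[table["effect"] == HOMEOSTASIS]
        planted_inhibitors = {
            (d, g) for (d, g), mech in drug_effects.items() if mech == "inhibitor"
        }
        found = {
            (row["drug"], row["gene"]) for _, row in homeo.iterrows()
        } & planted_inhibitors
        rows.append(
            {
                "seed": seed,
                "n_records": len(table),
                "n_homeostasis": len(homeo),
                "n_planted_inhibitors_found": len(found),
                "recovered": len(found) > 0,
            }
        )
    return pd.DataFrame(rows)


def planted_pds_gap(
    effect: float,
    seed: int,
    n_tumor: int = 60,
    n_control: int = 30,
    params: dict | None = None,
) -> float:
    """Mean tumor PDS minus mean control PDS for one planted pathway."""
    config = single_subtype_config(seed, effect=effect, n_planted=1)
    config = dataclasses.replace(config, n_tumor=n_tumor, n_control=n_control)
    cohort, collection, truth = generate_cohort(config)
    pid = truth.planted["Basal"][0]
    pds, _ = pathway_pds(cohort, collection.members(pid), pid, params)
    is_ctrl = cohort.annotation.loc[pds.index, "subtype"] == "Control"
    return float(pds[~is_ctrl].mean() - pds[is_ctrl].mean())
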