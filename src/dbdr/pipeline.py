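"""End-to-end pipeline: simulate/ingest -> PDS -> ranking -> DE ->
prioritization -> per-patient recommendations, with a run manifest.

Each (subtype, dataset) pair is analyzed independently: the subtype's
tumors plus the controls define the principal curves, the PDSz medians, and
the differential expression contrast. Consensus pathways are the
intersection of the two datasets' top-k lists; prioritized targets must be
differentially expressed, with the cross-dataset agreement rule set by
``de_rule``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import networkx as nx
import pandas as pd

from dbdr import io as dio
from dbdr.diffexpr import (
    DEFAULT_ADJP_CUT,
    DEFAULT_LFC_CUT,
    STATUS_DOWN,
    STATUS_NS,
    STATUS_UP,
    apply_de_thresholds,
    two_group_de,
)
from dbdr.errors import DbdrError, ValidationError
from dbdr.genesets import GeneSetCollection
from dbdr.pds import DEFAULT_PARAMS, compute_pds_matrix, subtype_view
from dbdr.prioritize import (
    build_multipartite_network,
    build_prioritization_table,
    count_targets_by_subtype,
)
from dbdr.ranking import (
    cross_dataset_intersection,
    median_pdsz_by_subtype,
    pdsz_transform,
    top_k_pathways,
)
from dbdr.recommend import DEFAULT_PDS_THRESHOLD, PatientProfile, recommend_drugs
from dbdr.simulate import (
    ExpressionCohort,
    SimConfig,
    default_planted_map,
    generate_drug_table,
    generate_two_platform_cohorts,
)

logger = logging.getLogger(__name__)

_DE_RULES = ("both", "either", "first")


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs. Unknown keys are rejected."""

    # input files (all-or-none per dataset); when absent, data are simulated
    expression_a: str | None = None
    annotation_a: str | None = None
    expression_b: str | None = None
    annotation_b: str | None = None
    gmt: str | None = None
    drug_table: str | None = None
    ddi_table: str | None = None
    # simulation settings (used when no input files are given)
    sim: dict[str, Any] = field(default_factory=dict)
    planted_effect: float = 1.5
    planted_per_subtype: int = 3
    # engine parameters
    var_expl: float = DEFAULT_PARAMS["var_expl"]
    max_components: int = DEFAULT_PARAMS["max_components"]
    max_iter: int = DEFAULT_PARAMS["max_iter"]
    tol: float = DEFAULT_PARAMS["tol"]
    span: float = DEFAULT_PARAMS["span"]
    # ranking / DE / recommendation knobs
    top_k: int = 30
    lfc_cut: float = DEFAULT_LFC_CUT
    adjp_cut: float = DEFAULT_ADJP_CUT
    de_rule: str = "either"
    pds_threshold: float = DEFAULT_PDS_THRESHOLD
    patients: list[str] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.var_expl <= 1:
            raise ValidationError("var_expl", "must be in (0, 1]")
        if self.max_components < 1:
            raise ValidationError("max_components", "must be >= 1")
        if self.max_iter < 1:
            raise ValidationError("max_iter", "must be >= 1")
        if self.tol <= 0:
            raise ValidationError("tol", "must be > 0")
        if not 0 < self.span <= 1:
            raise ValidationError("span", "must be in (0, 1]")
        if self.top_k < 1:
            raise ValidationError("top_k", "must be >= 1")
        if self.lfc_cut < 0:
            raise ValidationError("lfc_cut", "must be >= 0")
        if not 0 < self.adjp_cut <= 1:
            raise ValidationError("adjp_cut", "must be in (0, 1]")
        if self.de_rule not in _DE_RULES:
            raise ValidationError("de_rule", f"must be one of {_DE_RULES}")
        if not 0 <= self.pds_threshold <= 1:
            raise ValidationError("pds_threshold", "must be in [0, 1]")

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError("config", f"unknown keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def engine_params(self) -> dict[str, Any]:
        return {
            "var_expl": self.var_expl,
            "max_components": self.max_components,
            "max_iter": self.max_iter,
            "tol": self.tol,
            "span": self.span,
        }


def combine_de(de_a: pd.DataFrame, de_b: pd.DataFrame, rule: str = "either") -> pd.DataFrame:
    """Merge two datasets' DE calls for prioritization.

    'either' (default) takes the first dataset's call, falling back to the
    second — a gene is a candidate target when any platform flags it;
    'both' keeps a call only when both datasets agree on direction (the
    conservative variant); 'first' uses dataset A alone. Reported log2FC
    always comes from dataset A where the gene was tested there.
    """
    if rule == "first":
        return de_a.copy()
    merged = de_a.copy()
    b_status = de_b["status"].reindex(de_a.index).fillna(STATUS_NS)
    if rule == "both":
        agree = merged["status"] == b_status
        merged.loc[~agree, "status"] = STATUS_NS
    elif rule == "either":
        take_b = (merged["status"] == STATUS_NS) & b_status.isin([STATUS_UP, STATUS_DOWN])
        merged.loc[take_b, "status"] = b_status[take_b]
    else:
        raise ValidationError("de_rule", f"must be one of {_DE_RULES}")
    return merged


def _load_or_simulate(config: PipelineConfig):
    paths = (config.expression_a, config.annotation_a, config.expression_b,
             config.annotation_b, config.gmt)
    if all(paths):
        cohort_a = dio.read_expression_tsv(config.expression_a, config.annotation_a)
        cohort_b = dio.read_expression_tsv(config.expression_b, config.annotation_b)
        collection = dio.read_gmt(config.gmt)
        truth = None
        drugs = dio.read_drug_table(config.drug_table) if config.drug_table else pd.DataFrame(
            columns=["drug", "gene", "interaction_type", "source"])
        ddi = dio.read_ddi_table(config.ddi_table) if config.ddi_table else pd.DataFrame(
            columns=["drug_a", "drug_b", "note"])
        return cohort_a, cohort_b, collection, truth, drugs, ddi
    if any(paths):
        raise ValidationError("config", "provide all dataset paths or none (simulate)")
    sim_kwargs = dict(config.sim)
    sim_kwargs.setdefault("seed", config.seed)
    sim = SimConfig(**sim_kwargs)
    if not sim.planted:
        sim = dataclasses.replace(
            sim,
            planted=default_planted_map(
                sim.subtypes, config.planted_per_subtype, config.planted_effect,
                sim.n_pathways,
            ),
        )
    cohort_a, cohort_b, collection, truth = generate_two_platform_cohorts(sim)
    planted_genes: dict[str, str] = {}
    for sub_shifts in truth.gene_shifts.values():
        for g, delta in sub_shifts.items():
            if delta != 0:
                planted_genes.setdefault(g, "up" if delta > 0 else "down")
    drugs, ddi, drug_effects = generate_drug_table(
        list(cohort_a.matrix.index), planted=planted_genes, seed=sim.seed + 1
    )
    truth.drug_effects = drug_effects
    return cohort_a, cohort_b, collection, truth, drugs, ddi


def analyze_dataset(
    cohort: ExpressionCohort,
    collection: GeneSetCollection,
    subtypes: list[str],
    params: dict[str, Any],
    top_k: int,
) -> tuple[dict[str, list[str]], dict[str, pd.Series], dict[str, Any]]:
    """Per-subtype PDS -> PDSz -> median ranking -> top-k for one dataset.

    Returns (subtype -> top-k ids, subtype -> median PDSz profile,
    subtype -> PDSMatrix)."""
    tops: dict[str, list[str]] = {}
    profiles: dict[str, pd.Series] = {}
    pds_matrices: dict[str, Any] = {}
    for subtype in subtypes:
        view = subtype_view(cohort, subtype)
        pds = compute_pds_matrix(view, collection, params)
        pds_matrices[subtype] = pds
        pdsz = pdsz_transform(pds)
        med = median_pdsz_by_subtype(pdsz, view.annotation, subtype)
        profiles[subtype] = med
        tops[subtype] = top_k_pathways(med, top_k)
    return tops, profiles, pds_matrices


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict[str, Any]:
    """Execute the full pipeline and write all stage outputs plus a manifest.

    Returns a result bundle with in-memory objects (consensus sets, DE
    tables, the prioritization table, recommendations) and the manifest.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "ingest"
    try:
        cohort_a, cohort_b, collection, truth, drugs, ddi = _load_or_simulate(config)
        subtypes = sorted(
            set(cohort_a.annotation["subtype"]) - {"Control"}
        )
        stage = "pds"
        params = config.engine_params()
        tops_a, profiles_a, pds_a = analyze_dataset(
            cohort_a, collection, subtypes, params, config.top_k)
        tops_b, profiles_b, _ = analyze_dataset(
            cohort_b, collection, subtypes, params, config.top_k)
        stage = "ranking"
        consensus = {
            s: cross_dataset_intersection(tops_a[s], tops_b[s]) for s in subtypes
        }
        stage = "de"
        de: dict[str, pd.DataFrame] = {}
        for s in subtypes:
            de_a = apply_de_thresholds(
                two_group_de(cohort_a, s), config.lfc_cut, config.adjp_cut)
            de_b = apply_de_thresholds(
                two_group_de(cohort_b, s), config.lfc_cut, config.adjp_cut)
            de[s] = combine_de(de_a, de_b, config.de_rule)
        stage = "prioritization"
        table = build_prioritization_table(consensus, de, drugs, collection)
        summary = count_targets_by_subtype(table)
        network = build_multipartite_network(table)
        stage = "recommendation"
        recommendations = {}
        for pid in config.patients:
            ann = cohort_a.annotation
            if pid not in ann.index:
                raise ValidationError("patients", f"unknown patient id {pid!r}")
            subtype = ann.loc[pid, "subtype"]
            profile = PatientProfile(
                patient_id=pid,
                pds=pds_a[subtype].values[pid].to_dict(),
                subtype=subtype,
            )
            sub_table = table[table["subtype"] == subtype]
            recommendations[pid] = recommend_drugs(
                profile, sub_table, ddi, config.pds_threshold)
        stage = "write"
        manifest = _write_outputs(
            out, config, cohort_a, cohort_b, collection, truth, drugs, ddi,
            profiles_a, profiles_b, tops_a, tops_b, consensus, de, table,
            summary, network, recommendations,
        )
    except DbdrError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise DbdrError(f"stage {stage!r} failed: {exc}") from exc
    return {
        "consensus": consensus,
        "de": de,
        "prioritization": table,
        "summary": summary,
        "network": network,
        "recommendations": recommendations,
        "profiles": {"a": profiles_a, "b": profiles_b},
        "truth": truth,
        "manifest": manifest,
    }


def _write_outputs(out, config, cohort_a, cohort_b, collection, truth, drugs,
                   ddi, profiles_a, profiles_b, tops_a, tops_b, consensus, de,
                   table, summary, network, recommendations) -> dict[str, Any]:
    import dbdr

    cfg_json = json.dumps(dataclasses.asdict(config), sort_keys=True)
    cfg_hash = __import__("hashlib").sha256(cfg_json.encode()).hexdigest()

    dio.write_expression_tsv(cohort_a, out / "expression_a.tsv", out / "annotation_a.tsv")
    dio.write_expression_tsv(cohort_b, out / "expression_b.tsv", out / "annotation_b.tsv")
    dio.write_gmt(collection, out / "pathways.gmt")
    drugs.to_csv(out / "drug_gene_interactions.tsv", sep="\t", index=False)
    ddi.to_csv(out / "drug_drug_interactions.tsv", sep="\t", index=False)
    if truth is not None:
        dio.write_ground_truth(truth, out / "ground_truth.json")

    ranking_rows = []
    for ds, (profiles, tops) in (("a", (profiles_a, tops_a)), ("b", (profiles_b, tops_b))):
        for s, med in profiles.items():
            ranks = {pid: r + 1 for r, pid in enumerate(top_k_pathways(med, len(med)))}
            for pid, val in med.items():
                ranking_rows.append((s, ds, pid, val, ranks[pid]))
    pd.DataFrame(
        ranking_rows, columns=["subtype", "dataset", "pathway", "median_pdsz", "rank"]
    ).to_csv(out / "ranking.tsv", sep="\t", index=False)

    pd.DataFrame(
        [(s, pid) for s, pids in consensus.items() for pid in pids],
        columns=["subtype", "pathway"],
    ).to_csv(out / "consensus.tsv", sep="\t", index=False)

    for s, de_table in de.items():
        de_table.to_csv(out / f"de_{s}.tsv", sep="\t", index_label="gene")
    table.to_csv(out / "prioritization.tsv", sep="\t", index=False)
    summary.to_csv(out / "target_counts.tsv", sep="\t", index=False)

    edges = nx.to_pandas_edgelist(network)
    edges.to_csv(out / "network_edges.tsv", sep="\t", index=False)
    nx.write_graphml(network, out / "network.graphml")

    recs = {
        pid: {
            "patient_id": rec.patient_id,
            "selected": rec.selected,
            "entries": rec.entries,
            "excluded": rec.excluded,
            "drugs": rec.drugs,
            "dropped_conflicts": rec.dropped_conflicts,
        }
        for pid, rec in recommendations.items()
    }
    (out / "recommendations.json").write_text(json.dumps(recs, indent=1), encoding="utf-8")

    outputs = sorted(p.name for p in out.iterdir() if p.is_file() and not p.name.endswith(".provenance.json") and p.name != "manifest.json")
    for name in outputs:
        dio.write_sidecar(out / name, "dbdr run-all", cfg_hash)
    manifest = {
        "package_version": dbdr.__version__,
        "seed": config.seed,
        "config": json.loads(cfg_json),
        "config_hash": cfg_hash,
        "outputs": {name: dio.sha256_of(out / name) for name in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return manifest
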