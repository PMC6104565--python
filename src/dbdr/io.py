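"""Readers and writers for the pipeline's file formats.

Tab-separated values (header row, UTF-8, '.' decimal) for matrices and
tables; GMT for gene sets; JSON for nested reports and metadata sidecars.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from dbdr.errors import GmtParseError
from dbdr.genesets import GeneSet, GeneSetCollection
from dbdr.pds import PDSMatrix
from dbdr.simulate import ExpressionCohort, GroundTruth

logger = logging.getLogger(__name__)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one gene set per line as
    ``name<TAB>description<TAB>member...``; duplicate members on a line are
    de-duplicated (order-preserving) with a warning."""
    entries = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(lineno, f"expected >= 3 tab-separated fields, got {len(fields)}")
            name, desc, *members = fields
            members = [m for m in members if m.strip()]
            unique = list(dict.fromkeys(members))
            if len(unique) != len(members):
                logger.warning("GMT line %d (%s): duplicate members removed", lineno, name)
            entries.append(GeneSet(name, desc, tuple(unique)))
    return GeneSetCollection(entries)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in collection:
            fh.write("\t".join([gs.id, gs.name, *gs.members]) + "\n")


def write_expression_tsv(cohort: ExpressionCohort, expr_path: str | Path,
                         annotation_path: str | Path) -> None:
    cohort.matrix.to_csv(expr_path, sep="\t", index_label="gene")
    cohort.annotation.to_csv(annotation_path, sep="\t", index_label="sample_id")


def read_expression_tsv(expr_path: str | Path, annotation_path: str | Path,
                        dataset_id: str | None = None) -> ExpressionCohort:
    matrix = pd.read_csv(expr_path, sep="\t", index_col="gene")
    annotation = pd.read_csv(annotation_path, sep="\t", index_col="sample_id")
    ds = dataset_id or (
        str(annotation["dataset"].iloc[0]) if "dataset" in annotation else "dataset"
    )
    return ExpressionCohort(matrix=matrix, annotation=annotation, dataset_id=ds)


def write_pds_matrix(pds: PDSMatrix, tsv_path: str | Path, meta_path: str | Path) -> None:
    """PDS matrix as pathways-x-samples TSV plus a JSON metadata sidecar."""
    pds.values.to_csv(tsv_path, sep="\t", index_label="pathway")
    meta = {pid: asdict(m) for pid, m in pds.meta.items()}
    Path(meta_path).write_text(json.dumps(meta, indent=1), encoding="utf-8")


def read_pds_values(tsv_path: str | Path) -> pd.DataFrame:
    return pd.read_csv(tsv_path, sep="\t", index_col="pathway")


def read_drug_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"drug", "gene", "interaction_type", "source"}
    missing = required - set(table.columns)
    if missing:
        raise GmtParseError(1, f"drug table missing columns {sorted(missing)}")
    return table


def read_ddi_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "planted": truth.planted,
        "effect_sizes": truth.effect_sizes,
        "gene_shifts": truth.gene_shifts,
        "drug_effects": {f"{d}|{g}": m for (d, g), m in truth.drug_effects.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_sidecar(path: str | Path, command: str, config_hash: str) -> None:
    """Provenance sidecar: which command and configuration produced a file."""
    side = Path(str(path) + ".provenance.json")
    side.write_text(
        json.dumps({"file": Path(path).name, "command": command,
                    "config_hash": config_hash, "sha256": sha256_of(path)}, indent=1),
        encoding="utf-8",
    )
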