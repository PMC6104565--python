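"""Synthetic dual-platform expression cohorts with planted ground truth.

The generators emulate the statistical structure the downstream analysis
assumes: two platforms (microarray-like log2 intensities and RNA-seq-like
counts) measuring the same cohort-level signal; control vs tumor sample
groups labelled with molecular subtypes; a minority of pathways whose member
genes carry coordinated expression shifts in specific subtypes; and a sparse
drug–gene interaction table in which only a fraction of genes is druggable.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
spawning, so sub-streams (baselines, each platform's samples, drug tables)
are reproducible independently of one another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from dbdr.errors import ValidationError
from dbdr.genesets import GeneSet, GeneSetCollection

INTERACTION_TYPES = (
    "inhibitor",
    "antagonist",
    "blocker",
    "inducer",
    "activator",
    "agonist",
    "binder",
    "other",
)

_SOURCES = ("DrugBank", "TTD", "ChEMBL", "PharmGKB")

#: Subtype sizes follow the real cohorts' composition scaled to a
#: 94-sample cohort (Basal 12, Her2 8, LumA 40, LumB 20, Control 14).
DEFAULT_SUBTYPE_SIZES = {"Basal": 12, "Her2": 8, "LumA": 40, "LumB": 20}
DEFAULT_N_CONTROL = 14

CONTROL_LABEL = "Control"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic cohort.

    ``planted`` maps subtype label -> list of (pathway id, effect size)
    where the effect size is expressed in units of the control standard
    deviation on the log2 scale, so it means the same thing on both
    platforms. ``n_tumor`` is either one count applied to every subtype or
    a per-subtype mapping.
    """

    n_genes: int = 1000
    n_pathways: int = 20
    genes_per_pathway: int = 50
    n_tumor: int | Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_SIZES)
    )
    n_control: int = DEFAULT_N_CONTROL
    subtypes: tuple[str, ...] = ("Basal", "Her2", "LumA", "LumB")
    planted: Mapping[str, Sequence[tuple[str, float]]] = field(default_factory=dict)
    platform: str = "microarray"
    noise_sd: float = 1.0
    up_fraction: float = 0.5
    overlap_fraction: float = 0.0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    nb_dispersion: float = 0.1
    upper_quartile: float = 1000.0
    seed: int = 0

    def tumor_counts(self) -> dict[str, int]:
        if isinstance(self.n_tumor, Mapping):
            return {s: int(self.n_tumor[s]) for s in self.subtypes}
        return {s: int(self.n_tumor) for s in self.subtypes}

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes", "must be >= 1")
        if self.n_pathways < 1:
            raise ValidationError("n_pathways", "must be >= 1")
        if self.genes_per_pathway * self.n_pathways > self.n_genes:
            raise ValidationError(
                "genes_per_pathway",
                f"genes_per_pathway*n_pathways = "
                f"{self.genes_per_pathway * self.n_pathways} exceeds n_genes "
                f"= {self.n_genes}",
            )
        if self.n_control < 0:
            raise ValidationError("n_control", "must be >= 0")
        counts = self.tumor_counts()
        for s, n in counts.items():
            if n < 0:
                raise ValidationError("n_tumor", f"subtype {s!r} count must be >= 0")
        if isinstance(self.n_tumor, Mapping):
            missing = set(self.subtypes) - set(self.n_tumor)
            if missing:
                raise ValidationError(
                    "n_tumor", f"missing counts for subtypes {sorted(missing)}"
                )
        if self.platform not in ("microarray", "counts"):
            raise ValidationError("platform", "must be 'microarray' or 'counts'")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd", "must be > 0")
        if not 0.0 <= self.up_fraction <= 1.0:
            raise ValidationError("up_fraction", "must be in [0, 1]")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValidationError("overlap_fraction", "must be in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion", "must be > 0")
        if self.upper_quartile <= 0:
            raise ValidationError("upper_quartile", "must be > 0")
        pathway_ids = {pathway_id(i) for i in range(self.n_pathways)}
        for s, entries in self.planted.items():
            if s not in self.subtypes:
                raise ValidationError("planted", f"unknown subtype {s!r}")
            for pid, eff in entries:
                if pid not in pathway_ids:
                    raise ValidationError(
                        "planted", f"pathway {pid!r} not in the collection"
                    )
                if eff < 0:
                    raise ValidationError("planted", "effect sizes must be >= 0")


@dataclass
class ExpressionCohort:
    """A gene-by-sample expression matrix plus per-sample annotations.

    ``matrix`` is on the log2 scale after platform-specific normalization.
    ``annotation`` is indexed by sample id with columns ``subtype`` (one of
    the tumor subtypes or ``Control``) and ``dataset``.
    """

    matrix: pd.DataFrame
    annotation: pd.DataFrame
    dataset_id: str

    def __post_init__(self):
        if self.matrix.isna().any().any():
            raise ValidationError("matrix", "missing values present")
        if self.matrix.columns.duplicated().any():
            raise ValidationError("matrix", "duplicate sample ids")
        missing = set(self.annotation.index) - set(self.matrix.columns)
        if missing:
            raise ValidationError(
                "annotation", f"annotated samples absent from matrix: {sorted(missing)[:5]}"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.index)

    def sample_ids(self, subtype: str) -> list[str]:
        return list(self.annotation.index[self.annotation["subtype"] == subtype])

    @property
    def control_ids(self) -> list[str]:
        return self.sample_ids(CONTROL_LABEL)


@dataclass
class GroundTruth:
    """What was planted: the answer key for recovery experiments.

    ``gene_shifts`` maps subtype -> gene -> signed shift in control-SD
    units; ``drug_effects`` maps (drug, gene) -> 'inhibitor'/'activator'
    for deliberately planted counter-regulating drugs.
    """

    planted: dict[str, list[str]]
    effect_sizes: dict[str, dict[str, float]]
    gene_shifts: dict[str, dict[str, float]]
    drug_effects: dict[tuple[str, str], str] = field(default_factory=dict)


def pathway_id(i: int) -> str:
    return f"PW{i + 1:03d}"


def gene_id(i: int) -> str:
    return f"G{i + 1:05d}"


def _build_collection(config: SimConfig, rng: np.random.Generator) -> GeneSetCollection:
    """Disjoint consecutive gene blocks; optionally swap in members from
    other pathways to emulate the heavy overlap of real pathway databases."""
    genes = [gene_id(i) for i in range(config.n_genes)]
    m = config.genes_per_pathway
    entries = []
    for p in range(config.n_pathways):
        members = list(genes[p * m : (p + 1) * m])
        if config.overlap_fraction > 0:
            n_swap = int(round(config.overlap_fraction * m))
            if n_swap:
                pool = [g for g in genes[: config.n_pathways * m] if g not in members]
                swapped = rng.choice(pool, size=n_swap, replace=False)
                members[:n_swap] = list(swapped)
        entries.append(GeneSet(pathway_id(p), f"Synthetic pathway {p + 1}", tuple(members)))
    return GeneSetCollection(entries)


def _planted_shifts(
    config: SimConfig, collection: GeneSetCollection
) -> dict[str, dict[str, float]]:
    """Signed per-gene shifts (control-SD units) per subtype.

    Within a planted pathway the first ``up_fraction`` of members shift up
    and the remainder down — deterministic so both platforms share signs.
    """
    shifts: dict[str, dict[str, float]] = {s: {} for s in config.subtypes}
    for subtype, entries in config.planted.items():
        for pid, eff in entries:
            members = collection.members(pid)
            n_up = int(round(config.up_fraction * len(members)))
            for j, g in enumerate(members):
                sign = 1.0 if j < n_up else -1.0
                shifts[subtype][g] = shifts[subtype].get(g, 0.0) + sign * eff
    return shifts


def _sample_layout(config: SimConfig, dataset_id: str) -> pd.DataFrame:
    rows = []
    for subtype, n in config.tumor_counts().items():
        for i in range(n):
            rows.append((f"{dataset_id}_{subtype}_{i + 1:03d}", subtype))
    for i in range(config.n_control):
        rows.append((f"{dataset_id}_{CONTROL_LABEL}_{i + 1:03d}", CONTROL_LABEL))
    ann = pd.DataFrame(rows, columns=["sample_id", "subtype"]).set_index("sample_id")
    ann["dataset"] = dataset_id
    return ann


def _shift_matrix(
    config: SimConfig,
    annotation: pd.DataFrame,
    gene_shifts: Mapping[str, Mapping[str, float]],
) -> np.ndarray:
    """Gene-by-sample matrix of planted shifts in control-SD units."""
    genes = [gene_id(i) for i in range(config.n_genes)]
    gindex = {g: i for i, g in enumerate(genes)}
    out = np.zeros((config.n_genes, len(annotation)))
    for j, (sid, row) in enumerate(annotation.iterrows()):
        sub = row["subtype"]
        if sub == CONTROL_LABEL:
            continue
        for g, delta in gene_shifts.get(sub, {}).items():
            out[gindex[g], j] = delta
    return out


def _microarray_matrix(
    config: SimConfig,
    annotation: pd.DataFrame,
    baselines: np.ndarray,
    shifts_sd: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n_samples = len(annotation)
    noise = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))
    values = baselines[:, None] + shifts_sd * config.noise_sd + noise
    genes = [gene_id(i) for i in range(config.n_genes)]
    return pd.DataFrame(values, index=genes, columns=annotation.index)


def _counts_matrix(
    config: SimConfig,
    annotation: pd.DataFrame,
    baselines: np.ndarray,
    shifts_sd: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Negative-binomial counts, upper-quartile scaled, then log2(x+1).

    Gene means are 2**baseline; a planted shift of ``e`` control SDs moves
    the log2 mean by ``e`` times the gene's delta-method log2-scale SD
    (sqrt(1/mu + alpha)/ln 2), so effect sizes remain comparable to the
    microarray platform's control-SD units.
    """
    mu = np.power(2.0, baselines)
    alpha = config.nb_dispersion
    sd_log2 = np.sqrt(1.0 / mu + alpha) / math.log(2.0)
    log2_mu = baselines[:, None] + shifts_sd * sd_log2[:, None]
    mu_mat = np.power(2.0, log2_mu)
    # NB with mean mu, variance mu + alpha*mu^2: size r = 1/alpha, p = r/(r+mu)
    r = 1.0 / alpha
    p = r / (r + mu_mat)
    counts = rng.negative_binomial(r, p).astype(float)
    uq = np.percentile(counts, 75, axis=0)
    uq[uq == 0] = 1.0
    scaled = counts * (config.upper_quartile / uq)
    genes = [gene_id(i) for i in range(config.n_genes)]
    return pd.DataFrame(np.log2(scaled + 1.0), index=genes, columns=annotation.index)


def _generate_platform(
    config: SimConfig,
    platform: str,
    dataset_id: str,
    baselines: np.ndarray,
    gene_shifts: dict[str, dict[str, float]],
    rng: np.random.Generator,
) -> ExpressionCohort:
    annotation = _sample_layout(config, dataset_id)
    shifts_sd = _shift_matrix(config, annotation, gene_shifts)
    if platform == "microarray":
        matrix = _microarray_matrix(config, annotation, baselines, shifts_sd, rng)
    else:
        matrix = _counts_matrix(config, annotation, baselines, shifts_sd, rng)
    matrix.index.name = "gene"
    matrix.columns = pd.Index(list(annotation.index), name=None)
    return ExpressionCohort(matrix=matrix, annotation=annotation, dataset_id=dataset_id)


def generate_cohort(
    config: SimConfig, dataset_id: str | None = None
) -> tuple[ExpressionCohort, GeneSetCollection, GroundTruth]:
    """Generate one single-platform cohort with planted deregulation.

    Control samples are drawn around per-gene baselines; tumor samples of
    each subtype have the planted pathways' member genes shifted by the
    configured effect size (a mix of up- and down-shifted genes). Returns
    the cohort, the pathway collection, and the planted ground truth.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_base, rng_a, _rng_b, _rng_drug = [
        np.random.default_rng(s) for s in ss.spawn(5)
    ]
    collection = _build_collection(config, rng_struct)
    gene_shifts = _planted_shifts(config, collection)
    baselines = rng_base.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    if config.platform == "counts":
        # keep count means in a realistic window (~8..1e5 counts)
        baselines = np.clip(baselines, 3.0, None)
    ds = dataset_id or config.platform
    cohort = _generate_platform(
        config, config.platform, ds, baselines, gene_shifts, rng_a
    )
    truth = GroundTruth(
        planted={s: [pid for pid, _ in v] for s, v in config.planted.items()},
        effect_sizes={s: {pid: e for pid, e in v} for s, v in config.planted.items()},
        gene_shifts=gene_shifts,
    )
    return cohort, collection, truth


def generate_two_platform_cohorts(
    config: SimConfig,
) -> tuple[ExpressionCohort, ExpressionCohort, GeneSetCollection, GroundTruth]:
    """Two cohorts (microarray-like and counts-like) sharing one ground truth.

    The cohorts share the gene universe, pathway collection, and planted
    shifts, but their samples are independent draws with platform-specific
    noise: Gaussian on the log2 scale for the microarray platform;
    negative-binomial counts with per-sample upper-quartile scaling and a
    log2(x+1) transform for the sequencing platform.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_base, rng_a, rng_b, _rng_drug = [
        np.random.default_rng(s) for s in ss.spawn(5)
    ]
    collection = _build_collection(config, rng_struct)
    gene_shifts = _planted_shifts(config, collection)
    baselines = rng_base.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    baselines_counts = np.clip(baselines, 3.0, None)
    cohort_a = _generate_platform(
        config, "microarray", "microarray", baselines, gene_shifts, rng_a
    )
    cohort_b = _generate_platform(
        config, "counts", "rnaseq", baselines_counts, gene_shifts, rng_b
    )
    truth = GroundTruth(
        planted={s: [pid for pid, _ in v] for s, v in config.planted.items()},
        effect_sizes={s: {pid: e for pid, e in v} for s, v in config.planted.items()},
        gene_shifts=gene_shifts,
    )
    return cohort_a, cohort_b, collection, truth


def generate_drug_table(
    genes: Sequence[str],
    n_drugs: int = 40,
    density: float = 0.01,
    fraction_druggable: float = 0.3,
    ddi_rate: float = 0.02,
    planted: Mapping[str, str] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[tuple[str, str], str]]:
    """Sparse drug–gene interaction table plus a drug–drug conflict list.

    Each gene is druggable with probability ``fraction_druggable``; each
    (druggable gene, drug) pair carries an interaction with probability
    ``density``, with the interaction type sampled from the standard
    claim-type vocabulary. ``planted`` optionally maps gene id -> 'up'/'down'
    DE direction; each planted gene receives one dedicated counter-regulating
    drug (inhibitor for an up gene, activator for a down gene) so recovery
    experiments have a known homeostasis answer. Returns the interaction
    table, the symmetric drug–drug conflict table, and the planted
    (drug, gene) -> mechanism map.
    """
    if len(genes) == 0:
        raise ValidationError("genes", "gene list must be non-empty")
    if not 0.0 <= density <= 1.0:
        raise ValidationError("density", "must be in [0, 1]")
    if not 0.0 <= fraction_druggable <= 1.0:
        raise ValidationError("fraction_druggable", "must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    drug_names = [f"DRUG{j + 1:04d}" for j in range(n_drugs)]
    druggable = rng.random(len(genes)) < fraction_druggable
    pair_mask = rng.random((len(genes), n_drugs)) < density
    pair_mask &= druggable[:, None]
    rows = []
    for i, j in zip(*np.nonzero(pair_mask)):
        itype = INTERACTION_TYPES[rng.integers(len(INTERACTION_TYPES))]
        source = _SOURCES[rng.integers(len(_SOURCES))]
        rows.append((drug_names[j], genes[i], itype, source))
    planted_effects: dict[tuple[str, str], str] = {}
    if planted:
        for g, direction in sorted(planted.items()):
            if g not in set(genes):
                raise ValidationError("planted", f"gene {g!r} not in gene list")
            mech = "inhibitor" if direction == "up" else "activator"
            drug = f"PLANTED_{mech.upper()[:3]}_{g}"
            rows.append((drug, g, mech, "synthetic"))
            planted_effects[(drug, g)] = mech
    interactions = pd.DataFrame(
        rows, columns=["drug", "gene", "interaction_type", "source"]
    ).drop_duplicates(ignore_index=True)
    all_drugs = sorted(interactions["drug"].unique())
    ddi_rows = []
    for a_idx in range(len(all_drugs)):
        for b_idx in range(a_idx + 1, len(all_drugs)):
            if rng.random() < ddi_rate:
                ddi_rows.append((all_drugs[a_idx], all_drugs[b_idx], "synthetic interaction"))
    ddi = pd.DataFrame(ddi_rows, columns=["drug_a", "drug_b", "note"])
    return interactions, ddi, planted_effects


def default_planted_map(
    subtypes: Sequence[str] = ("Basal", "Her2", "LumA", "LumB"),
    n_per_subtype: int = 3,
    effect: float = 1.5,
    n_pathways: int = 20,
) -> dict[str, list[tuple[str, float]]]:
    """Disjoint planted pathways per subtype: subtype i gets pathways
    [i*n .. (i+1)*n). Raises if the collection is too small."""
    need = len(subtypes) * n_per_subtype
    if need > n_pathways:
        raise ValidationError(
            "planted", f"{need} planted pathways requested but only {n_pathways} exist"
        )
    return {
        s: [(pathway_id(i * n_per_subtype + j), effect) for j in range(n_per_subtype)]
        for i, s in enumerate(subtypes)
    }
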