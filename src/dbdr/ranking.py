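"""PDSz transformation, subtype-level ranking, cross-dataset consensus,
and hierarchical clustering of subtype deregulation profiles.

PDS rows are z-scored across samples (PDSz) so deregulation is comparable
across pathways; each (subtype, dataset) run is summarized by the median
PDSz over that subtype's tumor samples; the top-k pathways of each dataset
are intersected to give the consensus deregulated pathways per subtype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from dbdr.errors import DataError, ValidationError
from dbdr.pds import PDSMatrix
from dbdr.simulate import CONTROL_LABEL

logger = logging.getLogger(__name__)


@dataclass
class PDSzMatrix:
    """Row-standardized PDS: non-degenerate rows have mean 0, sample SD 1."""

    values: pd.DataFrame
    degenerate: dict[str, bool] = field(default_factory=dict)


def pdsz_transform(pds: PDSMatrix | pd.DataFrame) -> PDSzMatrix:
    """Standardize each pathway row over all its samples (ddof=1).

    Zero-SD rows become all zeros, are flagged degenerate, and logged.
    """
    values = pds.values if isinstance(pds, PDSMatrix) else pds
    if values.empty:
        raise ValidationError("pds", "empty PDS matrix")
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    degenerate = {pid: bool(s == 0 or not np.isfinite(s)) for pid, s in sd.items()}
    safe_sd = sd.replace(0, 1.0)
    z = values.sub(mu, axis=0).div(safe_sd, axis=0)
    for pid, flag in degenerate.items():
        if flag:
            z.loc[pid] = 0.0
            logger.warning("pathway %s: constant PDS row, PDSz set to 0", pid)
    return PDSzMatrix(values=z, degenerate=degenerate)


def median_pdsz_by_subtype(
    pdsz: PDSzMatrix | pd.DataFrame, annotation: pd.DataFrame, subtype: str
) -> pd.Series:
    """Median PDSz per pathway over one subtype's tumor samples.

    Controls never enter the median: the summary measures how deregulated
    the subtype is, and control samples would dilute it.
    """
    values = pdsz.values if isinstance(pdsz, PDSzMatrix) else pdsz
    if subtype == CONTROL_LABEL:
        raise DataError("median is defined over tumor subtypes, not controls")
    ids = annotation.index[annotation["subtype"] == subtype]
    ids = [s for s in ids if s in values.columns]
    if not ids:
        raise DataError(f"subtype {subtype!r} has no samples in the matrix")
    med = values[ids].median(axis=1)
    med.name = subtype
    return med


def top_k_pathways(scores: Mapping[str, float] | pd.Series, k: int = 30) -> list[str]:
    """The k highest-scoring pathway ids, descending; ties broken by id."""
    if k < 1:
        raise ValidationError("k", "must be >= 1")
    s = pd.Series(scores)
    if len(s) < k:
        logger.warning("requested top %d of %d pathways; returning all", k, len(s))
    order = sorted(s.index, key=lambda pid: (-s[pid], pid))
    return order[:k]


def cross_dataset_intersection(
    top_a: Sequence[str], top_b: Sequence[str]
) -> list[str]:
    """Pathways deregulated in both datasets' top-k lists.

    Ordered by the mean of the two within-list ranks (ties by pathway id).
    """
    rank_a = {pid: i for i, pid in enumerate(top_a)}
    rank_b = {pid: i for i, pid in enumerate(top_b)}
    common = set(top_a) & set(top_b)
    return sorted(common, key=lambda pid: ((rank_a[pid] + rank_b[pid]) / 2, pid))


@dataclass
class ProfileClustering:
    """Result of agglomerative clustering of deregulation profiles."""

    labels: list[str]
    linkage_matrix: np.ndarray
    distance: pd.DataFrame

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def _correlation_distance(profiles: pd.DataFrame) -> pd.DataFrame:
    corr = profiles.T.corr()
    return 1.0 - corr


def cluster_subtype_profiles(
    profiles: Sequence[tuple[str, pd.Series]]
) -> ProfileClustering:
    """Cluster (subtype, dataset) median-PDSz profiles.

    Uses correlation distance (1 - Pearson) with average linkage — the
    standard expression-profile choice. Profiles must share a pathway
    universe; at least two are required.
    """
    if len(profiles) < 2:
        raise ValidationError("profiles", "need at least 2 profiles")
    labels = [lab for lab, _ in profiles]
    mat = pd.DataFrame({lab: vec for lab, vec in profiles}).T
    if mat.isna().any().any():
        raise DataError("profiles do not share a pathway universe")
    dist = _correlation_distance(mat)
    condensed = squareform(np.clip(dist.to_numpy(), 0.0, None), checks=False)
    z = linkage(condensed, method="average")
    return ProfileClustering(labels=labels, linkage_matrix=z, distance=dist)


def mutual_nearest_pairs(clustering: ProfileClustering) -> list[tuple[str, str]]:
    """Unordered label pairs that are each other's nearest neighbor."""
    d = clustering.distance.to_numpy().astype(float).copy()
    np.fill_diagonal(d, np.inf)
    nn = np.argmin(d, axis=1)
    labels = clustering.labels
    pairs = []
    for i in range(len(labels)):
        j = nn[i]
        if nn[j] == i and i < j:
            pairs.append((labels[i], labels[j]))
    return pairs
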