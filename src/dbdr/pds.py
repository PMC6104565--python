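"""Pathway Deregulation Score (PDS) via control-anchored principal curves.

For each pathway, the member genes' expression is standardized against the
control samples, reduced by PCA, and a principal curve (Hastie–Stuetzle:
alternating projection onto the current polyline and scatterplot smoothing
of each coordinate against arc-length) is fitted through all samples. Each
sample's PDS is its min–max-normalized arc-length position along the curve,
oriented so controls sit at the low end. A PDS near 0 means "close to the
normal tissue end of the curve"; a PDS of 1 marks the most deregulated
sample of the cohort for that pathway.

The analysis is run per (subtype, dataset): the curve is fitted over the
analyzed subtype's tumors together with the controls; other subtypes are
excluded (see :func:`subtype_view`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from dbdr.errors import DataError, ValidationError
from dbdr.genesets import GeneSetCollection
from dbdr.simulate import CONTROL_LABEL, ExpressionCohort

logger = logging.getLogger(__name__)

#: Default engine parameters: PCA keeps the smallest number of components
#: explaining >= 85% variance (capped at 10); the smoother fits local lines
#: over a window of 30% of the points; iteration stops when the relative
#: change of the mean squared projection distance falls below 1e-4.
DEFAULT_PARAMS = {
    "var_expl": 0.85,
    "max_components": 10,
    "max_iter": 50,
    "tol": 1e-4,
    "span": 0.3,
}

MIN_CONTROLS = 3
MIN_GENES = 3
MIN_POINTS = 5
CONTROL_SD_TOL = 1e-8


@dataclass
class PrincipalCurve:
    """A fitted one-dimensional curve through a point cloud.

    ``nodes`` are the ordered polyline vertices; ``lambdas`` holds each
    input point's arc-length parameter along the polyline (non-decreasing
    in the node ordering); ``length`` is the total curve length.
    """

    nodes: np.ndarray
    lambdas: np.ndarray
    length: float
    converged: bool
    n_iter: int
    mean_sq_dist: float


@dataclass
class PathwayMeta:
    """Per-pathway bookkeeping for one PDS run."""

    pathway_id: str
    genes_used: list[str] = field(default_factory=list)
    genes_dropped: list[str] = field(default_factory=list)
    n_components: int = 0
    converged: bool = False
    iterations: int = 0
    degenerate: bool = False
    skipped: bool = False
    reason: str = ""


@dataclass
class PDSMatrix:
    """Pathway-by-sample deregulation scores in [0, 1] plus metadata."""

    values: pd.DataFrame
    meta: dict[str, PathwayMeta]

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def subtype_view(cohort: ExpressionCohort, subtype: str) -> ExpressionCohort:
    """Restrict a cohort to one tumor subtype plus the controls.

    The principal curve for a subtype is anchored by its own controls; other
    subtypes' tumors are excluded from the fit.
    """
    ann = cohort.annotation
    keep = ann.index[(ann["subtype"] == subtype) | (ann["subtype"] == CONTROL_LABEL)]
    if (ann["subtype"] == subtype).sum() == 0:
        raise DataError(f"subtype {subtype!r} absent from annotation")
    return ExpressionCohort(
        matrix=cohort.matrix[keep], annotation=ann.loc[keep], dataset_id=cohort.dataset_id
    )


class DegeneratePathway(Exception):
    """Raised when a pathway cannot be scored; carries a structured record."""

    def __init__(self, meta: PathwayMeta):
        self.meta = meta
        super().__init__(f"pathway {meta.pathway_id}: {meta.reason}")


def standardize_to_controls(
    cohort: ExpressionCohort, members: Sequence[str], pathway_id: str = "?"
) -> tuple[pd.DataFrame, PathwayMeta]:
    """Center and scale each pathway gene by its control mean and SD.

    Genes absent from the matrix or with control SD below tolerance are
    dropped (and logged). Raises :class:`DegeneratePathway` when fewer than
    three usable genes remain or fewer than three control samples exist.
    """
    meta = PathwayMeta(pathway_id=pathway_id)
    controls = cohort.control_ids
    if len(controls) < MIN_CONTROLS:
        meta.skipped = True
        meta.reason = f"only {len(controls)} control samples (need >= {MIN_CONTROLS})"
        raise DegeneratePathway(meta)
    present = [g for g in members if g in cohort.matrix.index]
    meta.genes_dropped = [g for g in members if g not in cohort.matrix.index]
    sub = cohort.matrix.loc[present]
    ctrl = sub[controls]
    mu = ctrl.mean(axis=1)
    sd = ctrl.std(axis=1, ddof=1)
    low_var = sd <= CONTROL_SD_TOL
    if low_var.any():
        dropped = list(sub.index[low_var])
        meta.genes_dropped.extend(dropped)
        logger.info(
            "pathway %s: dropped %d gene(s) with control SD below tolerance",
            pathway_id,
            len(dropped),
        )
    keep = sub.index[~low_var]
    if len(keep) < MIN_GENES:
        meta.skipped = True
        meta.reason = f"only {len(keep)} usable genes after filtering (need >= {MIN_GENES})"
        raise DegeneratePathway(meta)
    meta.genes_used = list(keep)
    z = sub.loc[keep].sub(mu[keep], axis=0).div(sd[keep], axis=0)
    return z, meta


def _local_linear_smooth(lam: np.ndarray, values: np.ndarray, window: int) -> np.ndarray:
    """Local linear scatterplot smoother of each column against ``lam``.

    For every point a straight line is fitted (unweighted least squares)
    over a centered rank-window of ``window`` points and evaluated at that
    point's ``lam``. Exact on collinear data, including the boundaries —
    the property that makes a straight line a fixed point of the curve
    iteration. ``lam`` must be sorted ascending; windows are truncated at
    the edges. Degenerate windows (constant lam) fall back to the window
    mean."""
    n = values.shape[0]
    half = window // 2
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    cnt = (hi - lo).astype(float)

    def cs(a):  # cumulative sums with leading zero row
        return np.concatenate([np.zeros((1,) + a.shape[1:]), np.cumsum(a, axis=0)])

    cx, cxx = cs(lam), cs(lam**2)
    cy, cxy = cs(values), cs(values * lam[:, None])
    sx = cx[hi] - cx[lo]
    sxx = cxx[hi] - cxx[lo]
    sy = cy[hi] - cy[lo]
    sxy = cxy[hi] - cxy[lo]
    denom = cnt * sxx - sx**2
    mean_y = sy / cnt[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (cnt[:, None] * sxy - sx[:, None] * sy) / denom[:, None]
        intercept = mean_y - slope * (sx / cnt)[:, None]
        fitted = intercept + slope * lam[:, None]
    bad = ~np.isfinite(denom) | (np.abs(denom) <= 1e-12 * np.maximum(cnt * sxx, 1.0))
    fitted[bad] = mean_y[bad]
    fitted[~np.isfinite(fitted)] = mean_y[~np.isfinite(fitted)]
    return fitted


def _dedupe_nodes(nodes: np.ndarray) -> np.ndarray:
    if len(nodes) < 2:
        return nodes
    keep = np.ones(len(nodes), dtype=bool)
    diffs = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    keep[1:] = diffs > 0
    return nodes[keep]


def project_to_polyline(
    points: np.ndarray, nodes: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonally project points onto a polyline.

    Returns (arc-length parameters, squared distances). Each point maps to
    its nearest location over all segments; the parameter is the cumulative
    length to the segment start plus the offset within the segment.
    """
    nodes = _dedupe_nodes(np.asarray(nodes, dtype=float))
    pts = np.asarray(points, dtype=float)
    if len(nodes) == 1:
        d2 = ((pts - nodes[0]) ** 2).sum(axis=1)
        return np.zeros(len(pts)), d2
    seg = np.diff(nodes, axis=0)  # (m-1, d)
    seglen2 = (seg**2).sum(axis=1)
    seglen = np.sqrt(seglen2)
    cumlen = np.concatenate([[0.0], np.cumsum(seglen)])
    diff = pts[:, None, :] - nodes[None, :-1, :]  # (n, m-1, d)
    t = np.clip(np.einsum("nsd,sd->ns", diff, seg) / seglen2[None, :], 0.0, 1.0)
    resid = diff - t[:, :, None] * seg[None, :, :]
    d2 = (resid**2).sum(axis=2)
    best = np.argmin(d2, axis=1)
    idx = np.arange(len(pts))
    lam = cumlen[best] + t[idx, best] * seglen[best]
    return lam, d2[idx, best]


def _first_pc(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    center = points.mean(axis=0)
    x = points - center
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    scores = x @ vt[0]
    return scores, center + np.outer(np.sort(scores), vt[0])


def fit_principal_curve(
    points: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-4,
    span: float = 0.3,
) -> PrincipalCurve:
    """Fit a principal curve by the Hastie–Stuetzle projection–smoothing scheme.

    The curve is initialized as the first principal component; each
    iteration (i) projects every point to the nearest point of the current
    polyline and (ii) smooths each coordinate against arc-length with a
    local-linear scatterplot smoother over ``span`` of the points. Iteration
    stops when the relative change of the mean squared projection distance
    falls below ``tol``, or after ``max_iter`` iterations. ``max_iter=0``
    returns the
    initialization (arc-lengths are then the first-PC scores shifted to
    start at zero).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n, d = pts.shape
    if n < MIN_POINTS:
        raise ValidationError("points", f"insufficient points: {n} < {MIN_POINTS}")
    if np.isnan(pts).any():
        raise ValidationError("points", "missing values present")
    if np.allclose(pts, pts[0], atol=0, rtol=0):
        raise ValidationError("points", "zero variance: all points identical")

    scores, init_nodes = _first_pc(pts)
    lam = scores - scores.min()
    if max_iter == 0:
        length = float(lam.max())
        d2 = ((pts - pts.mean(axis=0)) ** 2).sum() / n - (scores**2).sum() / n
        return PrincipalCurve(
            nodes=init_nodes,
            lambdas=lam,
            length=length,
            converged=False,
            n_iter=0,
            mean_sq_dist=float(max(d2, 0.0)),
        )

    window = max(3, int(round(span * n)))
    prev_d2 = np.inf
    converged = False
    mean_d2 = np.inf
    it = 0
    # the iteration can oscillate on noisy data; keep the best iterate
    # (smallest mean squared projection distance) seen so far
    best = (np.inf, init_nodes, lam, 0)
    for it in range(1, max_iter + 1):
        order = np.argsort(lam, kind="stable")
        nodes = _local_linear_smooth(lam[order], pts[order], window)
        lam, d2 = project_to_polyline(pts, nodes)
        mean_d2 = float(d2.mean())
        if mean_d2 < best[0]:
            best = (mean_d2, nodes, lam, it)
        # relative change in mean squared projection distance
        if abs(prev_d2 - mean_d2) <= tol * max(mean_d2, 1e-12):
            converged = True
            break
        prev_d2 = mean_d2
    mean_d2, nodes, lam, best_it = best
    nodes = _dedupe_nodes(nodes)
    length = float(np.linalg.norm(np.diff(nodes, axis=0), axis=1).sum())
    return PrincipalCurve(
        nodes=nodes,
        lambdas=lam,
        length=length,
        converged=converged,
        n_iter=it,
        mean_sq_dist=mean_d2,
    )


def _reduce_pca(
    z: pd.DataFrame, var_expl: float, max_components: int
) -> tuple[np.ndarray, int]:
    """Samples-as-points PCA keeping the smallest k with cumulative
    explained variance >= var_expl, capped at max_components."""
    x = z.to_numpy().T  # samples x genes
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 0:
        return x[:, :1] * 0.0, 0
    frac = np.cumsum(var) / total
    k = int(np.searchsorted(frac, var_expl) + 1)
    k = min(k, max_components, len(s))
    return u[:, :k] * s[:k], k


def pathway_pds(
    cohort: ExpressionCohort,
    members: Sequence[str],
    pathway_id: str = "?",
    params: dict | None = None,
) -> tuple[pd.Series, PathwayMeta]:
    """Score one pathway: PDS per sample in [0, 1].

    Pipeline: control-standardize the member genes, PCA-reduce the samples,
    fit the principal curve over tumors and controls jointly, orient the
    curve so the median control arc-length sits at the low end, and min–max
    normalize arc-lengths to [0, 1]. Degenerate pathways (all samples at the
    control centroid, or too few usable genes) score 0 and are flagged.
    """
    p = {**DEFAULT_PARAMS, **(params or {})}
    z, meta = standardize_to_controls(cohort, members, pathway_id)
    points, k = _reduce_pca(z, p["var_expl"], p["max_components"])
    meta.n_components = k
    samples = list(z.columns)
    try:
        curve = fit_principal_curve(
            points, max_iter=p["max_iter"], tol=p["tol"], span=p["span"]
        )
    except ValidationError:
        meta.degenerate = True
        meta.reason = "all samples coincide in reduced space"
        return pd.Series(0.0, index=samples, name=pathway_id), meta
    meta.converged = curve.converged
    meta.iterations = curve.n_iter
    if not curve.converged:
        logger.debug("pathway %s: curve did not converge in %d iterations",
                     pathway_id, curve.n_iter)
    lam = pd.Series(curve.lambdas, index=samples)
    is_control = cohort.annotation.loc[samples, "subtype"] == CONTROL_LABEL
    if is_control.any() and (~is_control).any():
        if lam[is_control].median() > lam[~is_control].median():
            lam = lam.max() - lam
    rng_span = lam.max() - lam.min()
    if rng_span <= 0:
        meta.degenerate = True
        meta.reason = "degenerate arc-length range"
        return pd.Series(0.0, index=samples, name=pathway_id), meta
    pds = (lam - lam.min()) / rng_span
    pds.name = pathway_id
    return pds, meta


def compute_pds_matrix(
    cohort: ExpressionCohort,
    collection: GeneSetCollection,
    params: dict | None = None,
) -> PDSMatrix:
    """Apply :func:`pathway_pds` to every pathway of a collection.

    Skipped (degenerate) pathways are recorded in the metadata and excluded
    from the matrix; row order follows the collection.
    """
    if len(collection) == 0:
        raise ValidationError("collection", "empty gene set collection")
    rows = {}
    meta: dict[str, PathwayMeta] = {}
    for gs in collection:
        try:
            pds, m = pathway_pds(cohort, gs.members, gs.id, params)
            rows[gs.id] = pds
        except DegeneratePathway as exc:
            m = exc.meta
            logger.warning("pathway %s skipped: %s", gs.id, m.reason)
        meta[gs.id] = m
    values = pd.DataFrame(
        {pid: rows[pid] for pid in collection.ids if pid in rows}
    ).T
    values.index.name = "pathway"
    n_skip = sum(m.skipped for m in meta.values())
    n_nc = sum((not m.skipped) and (not m.converged) and (not m.degenerate)
               for m in meta.values())
    logger.info(
        "PDS: scored %d/%d pathways (%d skipped, %d flagged non-converged)",
        len(values), len(collection), n_skip, n_nc,
    )
    return PDSMatrix(values=values, meta=meta)
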