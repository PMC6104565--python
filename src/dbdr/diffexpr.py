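"""Two-group differential expression on the log2 scale.

One self-contained route serves both platforms (counts arrive already
upper-quartile log2-normalized): per gene, a Welch two-sample t statistic
comparing a tumor subtype against the controls, a two-sided p-value, and
Benjamini–Hochberg adjustment across all tested genes. Status calls use
an absolute log2 fold-change cut of 1 and an adjusted-p cut of 0.001 by
default; since BH-adjusted p < 0.001 implies FDR < 0.1, the stricter bound
governs and the FDR knob stays implicit in ``adjp_cut``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from dbdr.errors import DataError
from dbdr.simulate import CONTROL_LABEL, ExpressionCohort

DEFAULT_LFC_CUT = 1.0
DEFAULT_ADJP_CUT = 0.001
MIN_GROUP_SIZE = 3

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_NS = "not_significant"


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Welch t and two-sided p per row; zero-variance rows with
    equal means get t=0, p=1; with unequal means, p -> 0."""
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    denom2 = va / na + vb / nb
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(denom2)
        df = denom2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    zero_var = denom2 == 0
    t = np.where(zero_var, 0.0, t)
    df = np.where(zero_var | ~np.isfinite(df), 1.0, df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # zero variance, unequal means: infinitely strong evidence
    hard = zero_var & (diff != 0)
    with np.errstate(invalid="ignore"):
        t = np.where(hard, np.sign(diff) * np.inf, t)
    p = np.where(hard, 0.0, p)
    p = np.where(zero_var & (diff == 0), 1.0, p)
    return t, p


def two_group_de(cohort: ExpressionCohort, subtype: str) -> pd.DataFrame:
    """Per-gene DE of one tumor subtype against the controls.

    Returns a DataFrame indexed by gene with columns ``log2FC`` (subtype
    mean minus control mean, log2 scale), ``t``, ``pvalue``, ``adj_pvalue``
    (BH), and ``status`` initialized by the default thresholds.
    """
    ann = cohort.annotation
    if subtype not in set(ann["subtype"]):
        raise DataError(f"subtype {subtype!r} absent from annotation")
    grp = cohort.matrix[ann.index[ann["subtype"] == subtype]].to_numpy()
    ctrl = cohort.matrix[ann.index[ann["subtype"] == CONTROL_LABEL]].to_numpy()
    if grp.shape[1] < MIN_GROUP_SIZE or ctrl.shape[1] < MIN_GROUP_SIZE:
        raise DataError(
            f"need >= {MIN_GROUP_SIZE} samples per group "
            f"(got {grp.shape[1]} {subtype!r}, {ctrl.shape[1]} controls)"
        )
    t, p = _welch(grp, ctrl)
    log2fc = grp.mean(axis=1) - ctrl.mean(axis=1)
    adj = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {"log2FC": log2fc, "t": t, "pvalue": p, "adj_pvalue": adj},
        index=cohort.matrix.index,
    )
    out.index.name = "gene"
    return apply_de_thresholds(out)


def apply_de_thresholds(
    results: pd.DataFrame,
    lfc_cut: float = DEFAULT_LFC_CUT,
    adjp_cut: float = DEFAULT_ADJP_CUT,
) -> pd.DataFrame:
    """Set the status flag: up/down requires |log2FC| > lfc_cut and
    adjusted p < adjp_cut; everything else is not_significant."""
    out = results.copy()
    sig = out["adj_pvalue"] < adjp_cut
    out["status"] = STATUS_NS
    out.loc[sig & (out["log2FC"] > lfc_cut), "status"] = STATUS_UP
    out.loc[sig & (out["log2FC"] < -lfc_cut), "status"] = STATUS_DOWN
    return out
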