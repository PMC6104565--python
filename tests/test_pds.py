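"""Principal-curve engine: analytic limits, oracle equivalence, control
standardization, PDS normalization, and planted-signal response."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from dbdr.errors import ValidationError
from dbdr.experiments import planted_pds_gap
from dbdr.pds import (
    DegeneratePathway,
    compute_pds_matrix,
    fit_principal_curve,
    pathway_pds,
    project_to_polyline,
    standardize_to_controls,
    subtype_view,
)
from dbdr.simulate import ExpressionCohort, pathway_id


def _dense_polyline_oracle(points: np.ndarray, nodes: np.ndarray, per_segment: int = 2000):
    """Brute-force nearest-point distances via a densely sampled polyline."""
    dense = []
    for a, b in zip(nodes[:-1], nodes[1:]):
        ts = np.linspace(0, 1, per_segment, endpoint=False)
        dense.append(a[None, :] + ts[:, None] * (b - a)[None, :])
    dense.append(nodes[-1][None, :])
    dense = np.vstack(dense)
    d2 = ((points[:, None, :] - dense[None, :, :]) ** 2).sum(axis=2)
    return np.sqrt(d2.min(axis=1))


class TestPrincipalCurve:
    def test_straight_line_is_fixed_point(self):
        x = np.linspace(0, 1, 100)
        curve = fit_principal_curve(np.c_[x, 2 * x])
        assert curve.converged
        assert curve.mean_sq_dist * len(x) < 1e-8
        assert np.array_equal(np.argsort(curve.lambdas), np.argsort(x))

    def test_initialization_matches_first_pc_scores(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(50, 3)) @ np.diag([3.0, 1.0, 0.3])
        curve = fit_principal_curve(pts, max_iter=0)
        centered = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        scores = centered @ vt[0]
        # affine relation: residual of least-squares fit is ~0
        design = np.c_[scores, np.ones_like(scores)]
        coef = np.linalg.lstsq(design, curve.lambdas, rcond=None)[0]
        resid = curve.lambdas - design @ coef
        assert np.abs(resid).max() < 1e-10

    def test_quarter_circle_recovers_angle_and_matches_projection_oracle(self):
        rng = np.random.default_rng(1)
        theta = np.sort(rng.uniform(0, np.pi / 2, 200))
        pts = np.c_[np.cos(theta), np.sin(theta)] + rng.normal(0, 0.01, (200, 2))
        curve = fit_principal_curve(pts)
        assert curve.converged
        rho = abs(spearmanr(curve.lambdas, theta).statistic)
        assert rho > 0.99
        _, d2 = project_to_polyline(pts, curve.nodes)
        oracle = _dense_polyline_oracle(pts, curve.nodes)
        assert np.max(np.abs(np.sqrt(d2) - oracle)) < 1e-3

    def test_lambdas_nondecreasing_along_node_order(self):
        rng = np.random.default_rng(2)
        pts = np.c_[np.linspace(0, 4, 120), rng.normal(0, 0.2, 120)]
        curve = fit_principal_curve(pts)
        lam_sorted = np.sort(curve.lambdas)
        assert (np.diff(lam_sorted) >= 0).all()
        assert curve.length >= 0

    def test_errors(self):
        with pytest.raises(ValidationError, match="insufficient points"):
            fit_principal_curve(np.zeros((4, 2)) + np.arange(4)[:, None])
        with pytest.raises(ValidationError, match="zero variance"):
            fit_principal_curve(np.ones((10, 3)))
        bad = np.ones((10, 2)) * np.arange(10)[:, None]
        bad[0, 0] = np.nan
        with pytest.raises(ValidationError, match="missing"):
            fit_principal_curve(bad)


class TestStandardizeToControls:
    def test_control_columns_standardized(self, small_cohort):
        cohort, collection, _ = small_cohort
        z, meta = standardize_to_controls(cohort, collection.members(pathway_id(0)), "p")
        ctrl = z[cohort.control_ids]
        assert np.abs(ctrl.mean(axis=1)).max() < 1e-12
        assert np.abs(ctrl.std(axis=1, ddof=1) - 1).max() < 1e-12
        assert meta.genes_used == list(z.index)

    def test_constant_gene_dropped(self, small_cohort):
        cohort, collection, _ = small_cohort
        members = list(collection.members(pathway_id(0)))
        matrix = cohort.matrix.copy()
        matrix.loc[members[0]] = 3.14
        flat = ExpressionCohort(matrix, cohort.annotation, cohort.dataset_id)
        z, meta = standardize_to_controls(flat, members, "p")
        assert members[0] not in z.index
        assert members[0] in meta.genes_dropped

    def test_too_few_usable_genes_is_degenerate(self, small_cohort):
        cohort, collection, _ = small_cohort
        members = list(collection.members(pathway_id(0)))[:3]
        matrix = cohort.matrix.copy()
        matrix.loc[members[0]] = 0.0
        flat = ExpressionCohort(matrix, cohort.annotation, cohort.dataset_id)
        with pytest.raises(DegeneratePathway) as err:
            standardize_to_controls(flat, members, "p")
        assert "usable genes" in err.value.meta.reason


class TestPathwayPDS:
    def test_analytic_limit_on_collinear_data(self, line_cohort):
        cohort, genes, t = line_cohort
        pds, meta = pathway_pds(cohort, genes, "line")
        expected = (t - t.min()) / (t.max() - t.min())
        assert np.max(np.abs(pds.to_numpy() - expected)) < 1e-6
        assert not meta.degenerate

    def test_pds_range_normalized(self, small_cohort):
        cohort, collection, _ = small_cohort
        pds, _ = pathway_pds(cohort, collection.members(pathway_id(0)), "p")
        assert pds.min() == 0.0
        assert pds.max() == 1.0
        assert ((pds >= 0) & (pds <= 1)).all()

    def test_orientation_invariance_under_negation(self, small_cohort):
        cohort, collection, _ = small_cohort
        members = collection.members(pathway_id(2))
        pds_pos, _ = pathway_pds(cohort, members, "p")
        neg = ExpressionCohort(-cohort.matrix, cohort.annotation, cohort.dataset_id)
        pds_neg, _ = pathway_pds(neg, members, "p")
        assert np.allclose(np.sort(pds_pos.to_numpy()), np.sort(pds_neg.to_numpy()), atol=1e-6)

    def test_controls_anchor_low_end(self, small_cohort):
        cohort, collection, _ = small_cohort
        pds, _ = pathway_pds(cohort, collection.members(pathway_id(0)), "p")
        is_ctrl = cohort.annotation.loc[pds.index, "subtype"] == "Control"
        assert pds[is_ctrl].median() <= pds[~is_ctrl].median()

    def test_planted_pathway_separates_tumors_from_controls(self):
        hits = sum(planted_pds_gap(1.5, 300 + s) > 0 for s in range(20))
        assert hits >= 19

    def test_monotone_response_to_effect_size(self):
        # seed-averaged tumor-control PDS gap is non-decreasing in effect
        gaps = []
        for effect in (0.0, 0.5, 1.5, 3.0):
            gaps.append(np.mean([planted_pds_gap(effect, 400 + s) for s in range(5)]))
        assert all(g2 >= g1 - 0.02 for g1, g2 in zip(gaps, gaps[1:]))


class TestComputePDSMatrix:
    def test_single_pathway_gives_single_row(self, small_cohort):
        cohort, collection, _ = small_cohort
        from dbdr.genesets import GeneSetCollection

        single = GeneSetCollection([collection.entries[0]])
        matrix = compute_pds_matrix(cohort, single)
        assert matrix.values.shape[0] == 1

    def test_pathway_order_independence(self, small_cohort):
        cohort, collection, _ = small_cohort
        from dbdr.genesets import GeneSetCollection

        shuffled = GeneSetCollection(list(reversed(collection.entries)))
        a = compute_pds_matrix(cohort, collection)
        b = compute_pds_matrix(cohort, shuffled)
        assert list(b.values.index) == list(reversed(list(a.values.index)))
        pd.testing.assert_frame_equal(a.values.sort_index(), b.values.sort_index())

    def test_planted_pathways_have_largest_gaps(self, small_two_platform):
        cohort, _, collection, truth = small_two_platform
        view = subtype_view(cohort, "Basal")
        matrix = compute_pds_matrix(view, collection)
        is_ctrl = view.annotation["subtype"] == "Control"
        ctrl_ids = view.annotation.index[is_ctrl]
        tum_ids = view.annotation.index[~is_ctrl]
        gap = matrix.values[tum_ids].mean(axis=1) - matrix.values[ctrl_ids].mean(axis=1)
        top2 = set(gap.sort_values(ascending=False).index[:2])
        assert top2 == set(truth.planted["Basal"])

    def test_empty_collection_rejected(self, small_cohort):
        cohort, _, _ = small_cohort
        from dbdr.genesets import GeneSetCollection

        with pytest.raises(ValidationError, match="collection"):
            compute_pds_matrix(cohort, GeneSetCollection([]))
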