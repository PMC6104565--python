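"""Synthetic-cohort generator: dimensions, determinism, planted effects,
platform behavior, and the drug-table draw."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dbdr.errors import ValidationError
from dbdr.simulate import (
    SimConfig,
    generate_cohort,
    generate_drug_table,
    generate_two_platform_cohorts,
    pathway_id,
)


def _config(**kw):
    base = dict(
        n_genes=1000,
        n_pathways=20,
        genes_per_pathway=50,
        n_tumor=60,
        n_control=30,
        subtypes=("Basal",),
        planted={"Basal": [(pathway_id(i), 1.5) for i in range(3)]},
        seed=7,
    )
    base.update(kw)
    return SimConfig(**base)


class TestGenerateCohort:
    def test_dimensions_and_labels_follow_config(self):
        cohort, collection, truth = generate_cohort(_config())
        assert cohort.matrix.shape == (1000, 90)
        assert (cohort.annotation["subtype"] == "Control").sum() == 30
        assert truth.planted["Basal"] == [pathway_id(i) for i in range(3)]
        assert set(truth.planted["Basal"]) <= set(collection.ids)

    def test_same_seed_reproduces_byte_identical_output(self):
        a, _, _ = generate_cohort(_config())
        b, _, _ = generate_cohort(_config())
        assert a.matrix.to_csv() == b.matrix.to_csv()
        assert a.annotation.to_csv() == b.annotation.to_csv()

    def test_zero_effect_size_means_no_shift(self):
        # mean tumor-control difference over planted genes, pooled over seeds
        diffs = []
        for seed in range(20):
            cfg = _config(
                planted={"Basal": [(pathway_id(0), 0.0)]},
                n_tumor=30,
                n_control=30,
                seed=seed,
            )
            cohort, collection, _ = generate_cohort(cfg)
            genes = list(collection.members(pathway_id(0)))
            tumors = cohort.sample_ids("Basal")
            controls = cohort.control_ids
            sub = cohort.matrix.loc[genes]
            diffs.append((sub[tumors].mean(axis=1) - sub[controls].mean(axis=1)).mean())
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 3 * se + 1e-12

    def test_planted_shift_has_configured_magnitude_and_mix(self):
        cfg = _config(n_tumor=200, n_control=200, seed=3)
        cohort, collection, truth = generate_cohort(cfg)
        shifts = truth.gene_shifts["Basal"]
        members = collection.members(pathway_id(0))
        assert sum(shifts[g] > 0 for g in members) == 25
        assert sum(shifts[g] < 0 for g in members) == 25
        g_up = next(g for g in members if shifts[g] > 0)
        tumors, controls = cohort.sample_ids("Basal"), cohort.control_ids
        observed = cohort.matrix.loc[g_up, tumors].mean() - cohort.matrix.loc[g_up, controls].mean()
        assert observed == pytest.approx(1.5, abs=0.4)

    def test_invalid_config_errors_name_the_field(self):
        with pytest.raises(ValidationError, match="genes_per_pathway"):
            _config(n_genes=100).validate()
        with pytest.raises(ValidationError, match="planted"):
            _config(planted={"Basal": [(pathway_id(0), -1.0)]}).validate()
        with pytest.raises(ValidationError, match="noise_sd"):
            _config(noise_sd=0.0).validate()

    def test_planted_separable_by_t_test(self):
        # sanity floor: with a one-directional mix, a t-test on pathway-mean
        # expression splits planted pathways from background at p < 0.01
        hits = 0
        for seed in range(20):
            cfg = _config(n_tumor=30, n_control=30, up_fraction=1.0, seed=100 + seed)
            cohort, collection, _ = generate_cohort(cfg)
            genes = list(collection.members(pathway_id(0)))
            tumors, controls = cohort.sample_ids("Basal"), cohort.control_ids
            sub = cohort.matrix.loc[genes]
            p = stats.ttest_ind(
                sub[tumors].mean(axis=0), sub[controls].mean(axis=0), equal_var=False
            ).pvalue
            hits += p < 0.01
        assert hits >= 19


class TestTwoPlatforms:
    def test_shared_ground_truth(self, small_two_platform):
        cohort_a, cohort_b, _, truth = small_two_platform
        assert cohort_a.dataset_id != cohort_b.dataset_id
        assert list(cohort_a.matrix.index) == list(cohort_b.matrix.index)
        assert truth.planted["Basal"] == [pathway_id(0), pathway_id(1)]

    def test_counts_platform_upper_quartile_normalized(self, small_two_platform):
        _, cohort_b, _, _ = small_two_platform
        assert (cohort_b.matrix.values >= 0).all()
        prelog = np.power(2.0, cohort_b.matrix.to_numpy()) - 1.0
        uq = np.percentile(prelog, 75, axis=0)
        assert np.allclose(uq, 1000.0, rtol=1e-6)

    def test_cross_platform_shift_correlation(self):
        # per-gene tumor-control shifts of planted genes agree across platforms
        corrs = []
        for seed in range(20):
            cfg = _config(n_tumor=30, n_control=30, seed=200 + seed)
            ca, cb, collection, truth = generate_two_platform_cohorts(cfg)
            genes = [g for g, d in truth.gene_shifts["Basal"].items() if d != 0]
            shifts = []
            for coh in (ca, cb):
                tum, ctl = coh.sample_ids("Basal"), coh.control_ids
                sub = coh.matrix.loc[genes]
                shifts.append(sub[tum].mean(axis=1) - sub[ctl].mean(axis=1))
            corrs.append(np.corrcoef(shifts[0], shifts[1])[0, 1])
        assert np.mean(corrs) > 0.5

    def test_counts_transform_preserves_within_sample_rank(self):
        # upper-quartile scaling + log2 is monotone per sample
        cfg = _config(platform="counts", n_tumor=10, n_control=5, planted={}, seed=9)
        cohort, _, _ = generate_cohort(cfg)
        prelog = np.power(2.0, cohort.matrix.to_numpy()) - 1.0
        col = cohort.matrix.to_numpy()[:, 0]
        assert np.array_equal(np.argsort(col, kind="stable"), np.argsort(prelog[:, 0], kind="stable"))


class TestDrugTable:
    GENES = [f"G{i:05d}" for i in range(1, 201)]

    def test_zero_druggable_fraction_gives_empty_table(self):
        drugs, _, _ = generate_drug_table(self.GENES, fraction_druggable=0.0, seed=1)
        assert drugs.empty

    def test_emitted_genes_subset_of_input(self):
        drugs, _, _ = generate_drug_table(self.GENES, density=0.05, seed=2)
        assert set(drugs["gene"]) <= set(self.GENES)
        assert not drugs.duplicated().any()

    def test_row_count_matches_independent_bernoulli_draw(self):
        # oracle: replay the same seeded draws without the table machinery
        n_drugs, density, frac, seed = 40, 0.03, 0.3, 5
        drugs, _, _ = generate_drug_table(
            self.GENES, n_drugs=n_drugs, density=density,
            fraction_druggable=frac, seed=seed,
        )
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
        druggable = rng.random(len(self.GENES)) < frac
        pair_mask = rng.random((len(self.GENES), n_drugs)) < density
        expected = int((pair_mask & druggable[:, None]).sum())
        assert len(drugs) == expected

    def test_planted_genes_get_counter_regulating_drugs(self):
        drugs, _, effects = generate_drug_table(
            self.GENES, planted={"G00001": "up", "G00002": "down"}, seed=3
        )
        mechs = {g: m for (_, g), m in effects.items()}
        assert mechs == {"G00001": "inhibitor", "G00002": "activator"}
        planted_rows = drugs[drugs["source"] == "synthetic"]
        assert set(planted_rows["gene"]) == {"G00001", "G00002"}

    def test_ddi_table_symmetric_no_self_pairs(self):
        _, ddi, _ = generate_drug_table(self.GENES, density=0.05, ddi_rate=0.2, seed=4)
        assert (ddi["drug_a"] != ddi["drug_b"]).all()
        pairs = {frozenset(p) for p in zip(ddi["drug_a"], ddi["drug_b"])}
        assert len(pairs) == len(ddi)

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValidationError, match="genes"):
            generate_drug_table([], seed=0)
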