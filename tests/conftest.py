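import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from dbdr.simulate import SimConfig, generate_cohort, generate_two_platform_cohorts, pathway_id

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

logging.getLogger("dbdr").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A small single-subtype cohort with two strongly planted pathways."""
    return SimConfig(
        n_genes=200,
        n_pathways=10,
        genes_per_pathway=20,
        n_tumor=20,
        n_control=10,
        subtypes=("Basal",),
        planted={"Basal": [(pathway_id(0), 2.0), (pathway_id(1), 2.0)]},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """(cohort, collection, truth) for the small microarray platform."""
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_two_platform(small_config):
    """(cohort_a, cohort_b, collection, truth) for both platforms."""
    return generate_two_platform_cohorts(small_config)


@pytest.fixture()
def line_cohort():
    """A cohort whose standardized pathway data lie exactly on a line.

    Each pathway gene is an affine function of one latent coordinate per
    sample; controls occupy the low end of the latent axis. The PDS of the
    pathway must then equal the min-max-normalized latent coordinate.
    """
    rng = np.random.default_rng(5)
    n_control, n_tumor = 20, 80
    t = np.concatenate([rng.uniform(0.0, 1.0, n_control), rng.uniform(1.0, 5.0, n_tumor)])
    genes = [f"g{i}" for i in range(6)]
    a = rng.normal(0, 1, len(genes))
    b = rng.normal(1, 0.2, len(genes))
    matrix = pd.DataFrame(
        a[:, None] + b[:, None] * t[None, :],
        index=genes,
        columns=[f"s{j}" for j in range(len(t))],
    )
    ann = pd.DataFrame(
        {
            "subtype": ["Control"] * n_control + ["Basal"] * n_tumor,
            "dataset": "toy",
        },
        index=matrix.columns,
    )
    from dbdr.simulate import ExpressionCohort

    return ExpressionCohort(matrix=matrix, annotation=ann, dataset_id="toy"), genes, t
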