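"""Shared fixtures: a 107-case exact-marginal synthetic cohort, its on-disk
serialization, and one full pipeline run reused across test modules."""

from __future__ import annotations

import pytest

from gastrosubtype import CohortSpec, generate_cohort, write_cohort
from gastrosubtype.pipeline import PipelineConfig, run_pipeline

COHORT_SEED = 20170722


@pytest.fixture(scope="session")
def exact_cohort():
    """107 cases whose marginals reproduce the published tables."""
    spec = CohortSpec(n_cases=107, seed=COHORT_SEED, mode="exact")
    bundles, truths = generate_cohort(spec)
    return bundles, truths


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory, exact_cohort):
    bundles, truths = exact_cohort
    d = tmp_path_factory.mktemp("cohort107")
    write_cohort(bundles, truths, d)
    return d


@pytest.fixture(scope="session")
def pipeline_summary(tmp_path_factory, cohort_dir):
    """One full pipeline run over the 107-case cohort."""
    out = tmp_path_factory.mktemp("reports107")
    config = PipelineConfig(input_dir=cohort_dir, output_dir=out, seed=COHORT_SEED)
    return run_pipeline(config)
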