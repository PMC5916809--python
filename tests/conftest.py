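"""Shared fixtures: one synthetic cohort and one pipeline run per session."""

from __future__ import annotations

import pytest

from fusionscape.pipeline import PipelineConfig, run_pipeline
from fusionscape.synthetic_data import CohortConfig, generate_cohort

SEED = 7


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """Generated synthetic cohort (annotation, truth, tables, files)."""
    outdir = tmp_path_factory.mktemp("cohort")
    return generate_cohort(CohortConfig(seed=SEED), outdir)


@pytest.fixture(scope="session")
def annotation(cohort):
    return cohort["annotation"]


@pytest.fixture(scope="session")
def truth(cohort):
    return cohort["truth"]


@pytest.fixture(scope="session")
def pipeline_run(cohort, tmp_path_factory):
    """Summary + output dir of a full pipeline run on the session cohort."""
    outdir = tmp_path_factory.mktemp("pipeline_out")
    config = PipelineConfig(
        input_dir=cohort["outdir"], output_dir=outdir, seed=SEED
    )
    summary = run_pipeline(config)
    return {"summary": summary, "outdir": outdir, "config": config}
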