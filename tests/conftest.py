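"""Shared fixtures: one synthetic study dataset and one pipeline run.

The dataset uses the generator's default study conditions (~1 Mb genome,
50 planted elements, 5 samples, 13 cultivars); building it and running the
pipeline once per session keeps the suite fast.
"""

from __future__ import annotations

import json

import pytest

from exrte.config import PipelineConfig
from exrte.mobilome import DEFAULT_ACM_CUTOFF
from exrte.pipeline import InputPaths, run_pipeline
from exrte.simulate import SimulationConfig, generate_dataset

STUDY_SEED = 11


@pytest.fixture(scope="session")
def study_dataset(tmp_path_factory):
    """(config, truth, dataset_dir) for the default study conditions."""
    outdir = tmp_path_factory.mktemp("dataset")
    config = SimulationConfig()
    truth = generate_dataset(config, STUDY_SEED, outdir)
    return config, truth, outdir


@pytest.fixture(scope="session")
def study_pipeline(study_dataset, tmp_path_factory):
    """(truth, results_dir, summary) from a full pipeline run."""
    _, truth, dataset_dir = study_dataset
    results = tmp_path_factory.mktemp("results")
    config = PipelineConfig(seed=STUDY_SEED, acm_cutoff=DEFAULT_ACM_CUTOFF)
    summary = run_pipeline(config, InputPaths.from_dataset_dir(dataset_dir), results)
    return truth, results, summary


@pytest.fixture(scope="session")
def study_truth_json(study_dataset):
    _, _, dataset_dir = study_dataset
    with open(dataset_dir / "truth.json") as fh:
        return json.load(fh)
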