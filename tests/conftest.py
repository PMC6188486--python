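import dataclasses

import pytest

from cernet import pipeline, synth


@pytest.fixture(scope="session")
def default_scenario(tmp_path_factory):
    """One full synthetic pipeline run at the default scenario, seed 1."""
    outdir = tmp_path_factory.mktemp("scenario") / "run"
    cfg = pipeline.PipelineConfig(
        synthetic=synth.SynthConfig(), outdir=outdir, seed=1
    )
    report = pipeline.run_pipeline(cfg)
    truth = synth.GroundTruth.from_json(outdir / "ground_truth.json")
    return cfg, report, truth


@pytest.fixture()
def small_synth_config():
    """A reduced scenario for fast unit-level runs."""
    return dataclasses.replace(
        synth.SynthConfig(),
        n_mrna=80,
        n_circ=20,
        n_mirna=15,
        n_planted_pairs=5,
        shared_mirnas_per_planted_pair=3,
        seed=7,
    )
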