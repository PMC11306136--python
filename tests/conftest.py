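import json
from pathlib import Path

import pandas as pd
import pytest
from hypothesis import settings

from cadnet.pipeline import PipelineConfig, run_pipeline
from cadnet.synthetic import FixtureConfig, write_fixture

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

SOURCES = ("string", "mentha", "intact", "biogrid")


@pytest.fixture(scope="session")
def fixture_config() -> FixtureConfig:
    """Default study conditions: 240 samples, loading-0.95 modules."""
    return FixtureConfig(rng_seed=0)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, fixture_config) -> Path:
    outdir = tmp_path_factory.mktemp("fixture")
    write_fixture(fixture_config, outdir)
    return outdir


@pytest.fixture(scope="session")
def ground_truth(fixture_dir) -> dict:
    with open(fixture_dir / "ground_truth.json") as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def expression(fixture_dir) -> pd.DataFrame:
    return pd.read_csv(fixture_dir / "expression.tsv", sep="\t", index_col=0)


def make_pipeline_config(
    fixture_dir: Path, outdir: Path, **overrides
) -> PipelineConfig:
    kwargs = dict(
        catalog=str(fixture_dir / "catalog.tsv"),
        expression=str(fixture_dir / "expression.tsv"),
        edge_files={s: str(fixture_dir / f"{s}.tsv") for s in SOURCES},
        gmt_files=[str(fixture_dir / "sets.gmt")],
        outdir=str(outdir),
    )
    kwargs.update(overrides)
    return PipelineConfig(**kwargs)


@pytest.fixture(scope="session")
def pipeline_config_factory():
    return make_pipeline_config


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory, fixture_dir):
    """One full default-condition pipeline run, shared across tests."""
    outdir = tmp_path_factory.mktemp("pipeline_out")
    config = make_pipeline_config(fixture_dir, outdir)
    manifest = run_pipeline(config)
    return outdir, manifest
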