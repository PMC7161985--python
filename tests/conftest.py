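"""Shared fixtures: a reduced synthetic domain, one fitted delta GAM, and
a completed small pipeline run, all session-scoped so expensive fits
happen once."""

import dataclasses

import numpy as np
import pytest

from sdmfuse.config import RunConfig
from sdmfuse.delta import fit_delta_gam
from sdmfuse.fusion import FusionConfig
from sdmfuse.pipeline import run_pipeline
from sdmfuse.synthetic import (SyntheticConfig, TrueSpecies, gen_environment,
                               gen_survey)


@pytest.fixture(scope="session")
def fast_config():
    return SyntheticConfig(
        years_baseline=(1998, 2011),
        year_obs_end=2015,
        n_stations_per_survey=250,
        n_members=9,
        seed=42,
    )


@pytest.fixture(scope="session")
def environment(fast_config):
    return gen_environment(fast_config)


@pytest.fixture(scope="session")
def test_species():
    return TrueSpecies(
        name="testfish", sst_optimum=13.0, sst_breadth=2.8,
        depth_optimum=100.0, depth_breadth=60.0, max_presence_prob=0.95,
        log_biomass_at_optimum=3.0, lognormal_sigma=0.6,
        true_direction="neutral", true_sensitivity="moderate",
    )


@pytest.fixture(scope="session")
def survey(environment, test_species, fast_config):
    return gen_survey(environment, [test_species], fast_config)


@pytest.fixture(scope="session")
def fitted_delta(survey):
    train = survey[survey["year"] <= 2011]
    return fit_delta_gam(train, "testfish", "fall")


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """A complete small pipeline run; returns (config, outdir)."""
    outdir = tmp_path_factory.mktemp("pipeline")
    cfg = RunConfig(
        outdir=str(outdir),
        seed=11,
        synthetic=SyntheticConfig(
            years_baseline=(2000, 2011), year_obs_end=2015,
            n_stations_per_survey=250, n_members=9, seed=11,
        ),
        fusion=FusionConfig(n_candidates=200),
    )
    run_pipeline(cfg)
    return cfg, outdir


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
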