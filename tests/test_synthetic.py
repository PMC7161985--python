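"""Generator contracts: seeded determinism, construction identities, and
the statistical structure the downstream analysis assumes."""

import dataclasses

import numpy as np
import pytest

from sdmfuse.synthetic import (ExpertPanel, SyntheticConfig, TrueSpecies,
                               allocate_stations, gen_climate_ensemble,
                               gen_environment, gen_expert_votes, gen_survey,
                               stratum_edges)


def small_cfg(**kw):
    base = dict(years_baseline=(2008, 2011), year_obs_end=2012,
                n_stations_per_survey=60, n_members=3, seed=5)
    base.update(kw)
    return SyntheticConfig(**base)


def test_environment_seeded_determinism():
    cfg = small_cfg()
    a, b = gen_environment(cfg), gen_environment(cfg)
    np.testing.assert_array_equal(a.depth.values, b.depth.values)
    np.testing.assert_array_equal(a.sst_monthly.values, b.sst_monthly.values)


def test_sst_monotone_in_latitude_without_noise():
    cfg = small_cfg(sst_noise_sd=0.0, sst_trend=0.0)
    env = gen_environment(cfg)
    col = env.sst_monthly.isel(year=0, month=0, lon=0).values
    assert np.all(np.diff(col) < 0)  # colder northwards


def test_sst_trend_recovered_by_least_squares():
    """With noise off, every cell's yearly regression slope equals the
    configured warming trend exactly."""
    cfg = small_cfg(sst_noise_sd=0.0, sst_trend=0.03,
                    years_baseline=(2000, 2011))
    env = gen_environment(cfg)
    years = env.sst_monthly["year"].values.astype(float)
    series = env.sst_monthly.isel(month=5).values.reshape(years.size, -1)
    slopes = np.polyfit(years, series, 1)[0]
    np.testing.assert_allclose(slopes, 0.03, atol=1e-10)


def test_degenerate_extent_rejected():
    with pytest.raises(ValueError):
        SyntheticConfig(lon_min=-70, lon_max=-70)


def test_ensemble_defaults_and_masking():
    cfg = small_cfg(n_members=27)
    env = gen_environment(cfg)
    ens = gen_climate_ensemble(cfg, env)
    assert len(ens.members) == 27  # ensemble size of the study design
    assert ens.missing_mask.any()
    for m in ens.members:
        vals = m.values[..., ens.missing_mask]
        assert np.isnan(vals).all()
    # coarser than the observed grid
    assert m["lon"].size < env.sst_monthly["lon"].size


def test_zero_perturbation_members_reproduce_observed_climatology():
    from sdmfuse.climate import compute_climatology, regrid_anomalies

    cfg = small_cfg(member_bias_mean=0.0, member_bias_sd=0.0,
                    member_trend_mean=0.0, member_trend_sd=0.0,
                    member_noise_sd=0.0, n_coastal_missing=0)
    env = gen_environment(cfg)
    ens = gen_climate_ensemble(cfg, env)
    obs_clim = compute_climatology(env.sst_monthly, cfg.years_baseline)
    coarse_clim = regrid_anomalies(obs_clim, ens.members[0])
    for m in ens.members:
        clim_m = compute_climatology(m, cfg.years_baseline)
        np.testing.assert_allclose(clim_m.values, coarse_clim.values, atol=1e-10)


def test_too_few_members_rejected():
    with pytest.raises(ValueError):
        small_cfg(n_members=2)


def test_min_two_stations_even_for_tiny_stratum(rng):
    weights = (0.05,) + (10.0,) * 11  # first stratum < 1% of the area
    cfg = small_cfg(n_stations_per_survey=300, strata_weights=weights)
    for _ in range(20):
        counts = allocate_stations(cfg, rng)
        assert counts.min() >= 2
        assert counts.sum() == 300


def test_station_budget_too_small_rejected(rng):
    cfg = small_cfg(n_stations_per_survey=20, n_strata=12)
    with pytest.raises(ValueError):
        allocate_stations(cfg, rng)


def test_allocation_proportional_to_area(rng):
    """Mean allocation over 200 surveys tracks stratum area shares to
    within 3 standard errors (binomial expectation of the rule)."""
    cfg = small_cfg(n_stations_per_survey=300)
    edges = stratum_edges(cfg)
    shares = np.diff(edges) / (edges[-1] - edges[0])
    counts = np.array([allocate_stations(cfg, rng) for _ in range(200)])
    mean = counts.mean(axis=0)
    expected = 300 * shares
    se = np.sqrt(300 * shares * (1 - shares) / 200)
    assert np.all(np.abs(mean - expected) <= 3 * se)


def test_everywhere_suitable_species_always_present(environment):
    cfg = dataclasses.replace(environment.config, years_baseline=(2010, 2011),
                              year_obs_end=2011, n_stations_per_survey=100)
    sp = TrueSpecies("ubiquitous", 13.0, 1e9, 100.0, 1e9,
                     max_presence_prob=1.0)
    env = gen_environment(cfg)
    survey = gen_survey(env, [sp], cfg)
    assert (survey["presence"] == 1).all()


def test_presence_frequency_at_optimum(environment, test_species, survey):
    """Presence frequency near the species optimum converges to
    max_presence_prob within 3 binomial standard errors."""
    sp = test_species
    near = survey[
        (np.abs(survey["sst"] - sp.sst_optimum) < 0.7 * sp.sst_breadth)
        & (np.abs(survey["depth_m"] - sp.depth_optimum) < 0.7 * sp.depth_breadth)
    ]
    assert len(near) >= 500
    # expected presence probability averaged over the retained window
    p_exp = (sp.max_presence_prob
             * sp.response(near["sst"].to_numpy(), near["depth_m"].to_numpy())).mean()
    freq = near["presence"].mean()
    se = np.sqrt(p_exp * (1 - p_exp) / len(near))
    assert abs(freq - p_exp) <= 3 * se


def test_survey_schema_and_zero_biomass_for_absence(survey):
    assert {"tow_id", "year", "season", "lon", "lat", "depth_m", "sst",
            "species", "biomass_kg", "presence"} <= set(survey.columns)
    absent = survey[survey["presence"] == 0]
    assert (absent["biomass_kg"] == 0).all()
    present = survey[survey["presence"] == 1]
    assert (present["biomass_kg"] > 0).all()


def test_vote_tables_have_fixed_sums(test_species, rng):
    panel = ExpertPanel()
    votes = gen_expert_votes(test_species, panel, rng)
    assert votes.per_attribute.shape == (12, 4)
    assert (votes.per_attribute.sum(axis=1) == 25).all()  # 25 votes/attribute
    assert votes.sensitivity.sum() == 300                 # 12 x 25
    assert votes.directional.sum() == 12                  # 3 experts x 4 tallies
    assert (votes.sensitivity >= 0).all() and (votes.directional >= 0).all()


def test_concentrated_panel_votes_land_on_true_bin(test_species, rng):
    panel = ExpertPanel(concentration=1e9)
    votes = gen_expert_votes(test_species, panel, rng)
    assert votes.modal_sensitivity == test_species.true_sensitivity
    assert votes.sensitivity[1] == 300  # "moderate" holds every vote
    assert votes.directional[1] == 12


def test_vote_generation_deterministic_given_rng_state(test_species):
    a = gen_expert_votes(test_species, ExpertPanel(), np.random.default_rng(3))
    b = gen_expert_votes(test_species, ExpertPanel(), np.random.default_rng(3))
    np.testing.assert_array_equal(a.per_attribute, b.per_attribute)
    np.testing.assert_array_equal(a.directional, b.directional)


def test_species_invariants_enforced():
    with pytest.raises(ValueError):
        TrueSpecies("bad", 10, -1, 100, 50)
    with pytest.raises(ValueError):
        TrueSpecies("bad", 10, 3, 100, 50, max_presence_prob=0.0)
    with pytest.raises(ValueError):
        TrueSpecies("bad", 10, 3, 100, 50, true_direction="sideways")
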