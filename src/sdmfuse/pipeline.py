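"""End-to-end pipeline: generate -> downscale -> fit -> validate ->
project -> compare -> fuse, with every stage writing its artifacts under
the run's output directory so later stages (and the digest) can be driven
from disk alone.

Stage RNGs are all derived from the single master seed, so a repeated run
with the same configuration reproduces every artifact byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import climate, fusion, projection, synthetic, vulnerability
from .config import RunConfig
from .delta import DeltaGAMFit, fit_delta_gam, predict_biomass
from .gam import DegenerateModelError
from .validation import auc as auc_stat
from .validation import taylor_stats

log = logging.getLogger("sdmfuse")

_FLOAT_FMT = "%.10g"

STAGES = ("generate", "downscale", "fit", "validate", "project", "compare", "fuse")


def _out(config: RunConfig) -> Path:
    p = Path(config.outdir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _species_panel(config: RunConfig):
    if config.n_species == 8:
        return synthetic.default_species()
    rng = np.random.default_rng([config.seed, 99])
    return synthetic.random_species_panel(config.n_species, rng)


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------- stages

def stage_generate(config: RunConfig) -> dict:
    """Synthesize environment, ensemble, survey and expert votes."""
    out = _out(config)
    scfg = config.synthetic
    species = _species_panel(config)
    env = synthetic.gen_environment(scfg)
    survey = synthetic.gen_survey(env, species, scfg)
    _write_csv(survey, out / "survey.csv")
    climate.save_field(env.depth, out / "env_depth.nc", name="depth")
    climate.save_field(env.sst_monthly, out / "env_sst_monthly.nc")

    panel = synthetic.ExpertPanel()
    vote_rng = np.random.default_rng([config.seed, 4])
    vote_rows, rank_rows = [], []
    for sp in species:
        votes = synthetic.gen_expert_votes(sp, panel, vote_rng)
        for a in range(panel.n_attributes):
            for b, bin_name in enumerate(vulnerability.SENSITIVITY_BINS):
                vote_rows.append((sp.name, f"attr_{a + 1:02d}", bin_name,
                                  int(votes.per_attribute[a, b])))
        for b, bin_name in enumerate(vulnerability.DIRECTION_BINS):
            vote_rows.append((sp.name, "directional", bin_name, int(votes.directional[b])))
        rank_rows.append((sp.name, sp.true_sensitivity, sp.true_direction,
                          votes.certainty("sensitivity"), votes.certainty("directional")))
    _write_csv(pd.DataFrame(vote_rows, columns=["species", "attribute", "bin", "count"]),
               out / "votes.csv")
    _write_csv(pd.DataFrame(rank_rows, columns=["species", "sensitivity_rank", "direction",
                                                "sens_certainty", "dir_certainty"]),
               out / "neva_ranks.csv")
    log.info("generate: %d tows, %d species", survey["tow_id"].nunique(), len(species))
    return {"survey": out / "survey.csv", "votes": out / "votes.csv"}


def load_votes(config: RunConfig) -> dict[str, fusion.ExpertVotes]:
    out = Path(config.outdir)
    df = pd.read_csv(out / "votes.csv")
    votes = {}
    for sp, grp in df.groupby("species"):
        attr = grp[grp["attribute"] != "directional"]
        per_attr = (
            attr.pivot(index="attribute", columns="bin", values="count")
            .reindex(columns=list(vulnerability.SENSITIVITY_BINS))
            .sort_index()
            .to_numpy()
        )
        d = (
            grp[grp["attribute"] == "directional"]
            .set_index("bin")["count"]
            .reindex(list(vulnerability.DIRECTION_BINS))
            .to_numpy()
        )
        votes[sp] = fusion.ExpertVotes(
            species=sp, sensitivity=per_attr.sum(axis=0),
            directional=d, per_attribute=per_attr,
        )
    return votes


def stage_downscale(config: RunConfig) -> dict:
    """Delta-downscale the ensemble and summarise future seasonal SSTs."""
    out = _out(config)
    scfg = config.synthetic
    env = _load_env(config)
    ens = synthetic.gen_climate_ensemble(scfg, env)
    obs_clim = climate.compute_climatology(env.sst_monthly, scfg.years_baseline)

    downscaled_future = []
    for member in ens.members:
        clim_m = climate.compute_climatology(member, scfg.years_baseline)
        clim_m = climate.fill_coastal(clim_m)
        fut = member.sel(year=[scfg.year_future])
        fut = climate.fill_coastal(fut)
        anom = climate.compute_anomalies(fut, clim_m)
        anom = climate.regrid_anomalies(anom, obs_clim)
        anom = climate.fill_coastal(anom)  # edge cells outside the coarse hull
        downscaled_future.append(climate.downscale(anom, obs_clim))
    summary = climate.ensemble_summary(downscaled_future)

    fields = {}
    for season in scfg.seasons:
        base = env.seasonal_sst(season)
        years = base["year"].values
        sel = (years >= config.split_year) & (years <= scfg.year_obs_end)
        fields[f"baseline_{season}"] = base.isel(year=sel).mean("year")
        for scen in config.scenarios:
            fut_season = climate.seasonal_mean(summary[scen], season)
            fields[f"{scen}_{season}"] = fut_season.sel(year=scfg.year_future, drop=True)
    ds = xr.Dataset(fields)
    climate.save_field(ds, out / "sst_scenarios.nc")
    log.info("downscale: %d members summarised", len(ens.members))
    return {"sst_scenarios": out / "sst_scenarios.nc"}


def _load_env(config: RunConfig) -> synthetic.Environment:
    out = Path(config.outdir)
    depth = climate.load_field(out / "env_depth.nc", "depth")
    sst = climate.load_field(out / "env_sst_monthly.nc", "sst")
    return synthetic.Environment(depth=depth, sst_monthly=sst, config=config.synthetic)


def stage_fit(config: RunConfig) -> dict:
    """Fit the two-stage delta GAM per species-season on training years."""
    out = _out(config)
    (out / "fits").mkdir(exist_ok=True)
    survey = pd.read_csv(out / "survey.csv")
    train = survey[survey["year"] <= config.split_year]
    skipped = []
    n_fit = 0
    for species in sorted(train["species"].unique()):
        for season in config.synthetic.seasons:
            try:
                fit = fit_delta_gam(train, species, season, criterion=config.criterion)
            except (DegenerateModelError, ValueError) as err:
                skipped.append((species, season, str(err)))
                continue
            fit.save(out / "fits" / f"{species}_{season}.json")
            n_fit += 1
    _write_csv(pd.DataFrame(skipped, columns=["species", "season", "reason"]),
               out / "fit_skipped.csv")
    log.info("fit: %d models fitted, %d skipped", n_fit, len(skipped))
    return {"fits": out / "fits"}


def _load_fits(config: RunConfig) -> dict[tuple[str, str], DeltaGAMFit]:
    out = Path(config.outdir)
    fits = {}
    for path in sorted((out / "fits").glob("*.json")):
        fit = DeltaGAMFit.load(path)
        fits[(fit.species, fit.season)] = fit
    return fits


def stage_validate(config: RunConfig) -> dict:
    """Held-out AUC and Taylor statistics; AUC-based inclusion filter."""
    out = _out(config)
    survey = pd.read_csv(out / "survey.csv")
    test = survey[survey["year"] > config.split_year]
    fits = _load_fits(config)
    rows = []
    for (species, season), fit in fits.items():
        sub = test[(test["species"] == species) & (test["season"] == season)]
        if len(sub) == 0 or sub["presence"].nunique() < 2:
            continue
        env = {"sst": sub["sst"].to_numpy(), "depth": sub["depth_m"].to_numpy()}
        p = fit.stage1.predict(env, warn_extrapolation=False)
        pred = predict_biomass(fit, env, warn_extrapolation=False)
        st = taylor_stats(sub["biomass_kg"].to_numpy(), pred)
        rows.append({
            "species": species, "season": season,
            "auc": auc_stat(sub["presence"].to_numpy(), p),
            "r": st.r, "crmse": st.crmse, "crmse_norm": st.crmse_norm,
            "sd_ratio": st.sd_ratio, "n_test": len(sub),
        })
    val = pd.DataFrame(rows)
    agg = val.groupby("species")["auc"].agg(auc_min="min", n_seasons="count")
    passing = agg[(agg["n_seasons"] == 2) & (agg["auc_min"] >= config.auc_threshold)].index
    val["included"] = val["species"].isin(passing)
    _write_csv(val, out / "validation.csv")
    log.info("validate: %d/%d species pass AUC >= %.2f in both seasons",
             len(passing), val["species"].nunique(), config.auc_threshold)
    return {"validation": out / "validation.csv"}


def _included_species(config: RunConfig) -> list[str]:
    val = pd.read_csv(Path(config.outdir) / "validation.csv")
    return sorted(val.loc[val["included"], "species"].unique())


def _load_scenario_envs(config: RunConfig):
    out = Path(config.outdir)
    ds = climate.load_field(out / "sst_scenarios.nc", None)
    depth = climate.load_field(out / "env_depth.nc", "depth")
    return ds, depth


def stage_project(config: RunConfig) -> dict:
    """Project percent changes per included species/season/scenario."""
    out = _out(config)
    ds, depth = _load_scenario_envs(config)
    fits = _load_fits(config)
    species_list = _included_species(config)
    regions = projection.default_regions(depth["lat"].values, depth["lon"].values)
    rows, changes = [], []
    for species in species_list:
        for season in config.synthetic.seasons:
            fit = fits.get((species, season))
            if fit is None:
                continue
            base_env = {"sst": ds[f"baseline_{season}"], "depth": depth}
            for scen in config.scenarios:
                fut_env = {"sst": ds[f"{scen}_{season}"], "depth": depth}
                ch = projection.project_change(fit, base_env, fut_env, scenario=scen)
                changes.append(ch)
                row = {
                    "species": species, "season": season, "scenario": scen,
                    "domain_pct_change": ch.domain_pct_change,
                    "domain_pct_change_capped": float(
                        projection.cap_changes(ch.domain_pct_change, config.cap)
                    ),
                    "n_zero_baseline": ch.n_zero_baseline,
                }
                for region in regions:
                    pct = projection.regional_summary(ch, region)
                    row[region.name] = pct
                    row[f"{region.name}_capped"] = float(
                        projection.cap_changes(pct, config.cap)
                    )
                rows.append(row)
    _write_csv(pd.DataFrame(rows), out / "changes.csv")
    climate.save_field(projection.change_fields_to_dataset(changes),
                       out / "change_fields.nc")
    log.info("project: %d change fields", len(changes))
    return {"changes": out / "changes.csv"}


def stage_compare(config: RunConfig) -> dict:
    """SensWeight/directional ranks vs expert ranks; match classifier."""
    out = _out(config)
    ds, depth = _load_scenario_envs(config)
    fits = _load_fits(config)
    species_list = _included_species(config)
    if len(species_list) < 4:
        raise RuntimeError("fewer than 4 included species; ranks are undefined")
    seasons = config.synthetic.seasons

    rows = []
    for species in species_list:
        rec = {"species": species}
        pcts = []
        for season in seasons:
            fit = fits[(species, season)]
            base_env = {"sst": ds[f"baseline_{season}"], "depth": depth}
            fut_env = {"sst": ds[f"mean_{season}"], "depth": depth}
            ch = projection.project_change(fit, base_env, fut_env, scenario="mean")
            rec[f"sens_weight_{season}"] = vulnerability.sens_weight(
                ch.baseline.values, ch.future.values
            )
            pcts.append(ch.domain_pct_change)
        rec["sens_weight_mean"] = float(
            np.mean([rec[f"sens_weight_{s}"] for s in seasons])
        )
        rec["mean_pct_change"] = float(np.mean(pcts))
        rec["direction"] = vulnerability.classify_direction(rec["mean_pct_change"])
        rows.append(rec)
    sens = pd.DataFrame(rows).set_index("species")
    ranked = vulnerability.rank_sensitivity(sens["sens_weight_mean"])
    sdm = sens.join(ranked[["percentile", "rank"]]).rename(
        columns={"rank": "sensitivity_rank"}
    )
    neva = pd.read_csv(out / "neva_ranks.csv").set_index("species")
    comp = vulnerability.compare_ranks(
        sdm[["sensitivity_rank", "direction"]], neva[["sensitivity_rank", "direction"]]
    )
    table = sdm.join(comp.table[["neva_rank", "neva_direction",
                                 "match_sensitivity", "match_direction"]])
    _write_csv(table.reset_index(), out / "comparison.csv")
    _write_csv(comp.sensitivity_confusion, out / "confusion_sensitivity.csv", index=True)
    _write_csv(comp.direction_confusion, out / "confusion_direction.csv", index=True)
    log.info("compare: %d/%d sensitivity, %d/%d direction matches",
             comp.n_sensitivity_matches, len(comp.table),
             comp.n_direction_matches, len(comp.table))

    # random-forest match analysis, when enough certain species are available
    votes = load_votes(config)
    val = pd.read_csv(out / "validation.csv")
    auc_ok = val.groupby("species")["auc"].min()
    eligible = []
    for sp in table.index:
        v = votes[sp]
        certain = {"moderate", "high", "very high"}
        if (v.certainty("sensitivity") in certain
                and v.certainty("directional") in certain
                and auc_ok.get(sp, 0) >= config.auc_threshold):
            eligible.append(sp)
    labels = table.loc[eligible, "match_sensitivity"]
    if len(eligible) >= 20 and labels.nunique() == 2:
        attr = pd.DataFrame(
            {sp: votes[sp].attribute_ranks() for sp in eligible}
        ).T
        attr.columns = [f"attr_{i + 1:02d}" for i in range(attr.shape[1])]
        report = vulnerability.fit_match_classifier(attr, labels, seed=config.seed % (2**31))
        _write_csv(report.importance, out / "rf_importance.csv")
        _write_csv(report.marginal_effects, out / "rf_marginal.csv")
        log.info("compare: RF OOB error %.3f", report.oob_error)
    else:
        log.info("compare: RF skipped (%d eligible species)", len(eligible))
    return {"comparison": out / "comparison.csv"}


def stage_fuse(config: RunConfig) -> dict:
    """Candidate sampling, vote scoring, MAP selection and evaluation."""
    out = _out(config)
    ds, depth = _load_scenario_envs(config)
    fits = _load_fits(config)
    survey = pd.read_csv(out / "survey.csv")
    test = survey[survey["year"] > config.split_year]
    votes = load_votes(config)
    val = pd.read_csv(out / "validation.csv").set_index(["species", "season"])
    species_list = _included_species(config)
    seasons = config.synthetic.seasons

    score_tabs, eval_rows = [], []
    rng = np.random.default_rng([config.seed, 7])
    for species in species_list:
        sp_fits = {s: fits[(species, s)] for s in seasons if (species, s) in fits}
        envs = {}
        for season in sp_fits:
            base_env = {"sst": ds[f"baseline_{season}"].values.ravel(),
                        "depth": depth.values.ravel()}
            fut_env = {"sst": ds[f"mean_{season}"].values.ravel(),
                       "depth": depth.values.ravel()}
            envs[season] = (base_env, fut_env)
        result = fusion.fuse_species(sp_fits, votes[species], envs, config.fusion, rng)
        (out / "map_models").mkdir(exist_ok=True)
        for season in sp_fits:
            (out / "map_models" / f"{species}_{season}.json").write_text(
                json.dumps({
                    "species": species, "season": season,
                    "candidate": int(result.map_index[season]),
                    "theta": list(result.map_theta[season]),
                })
            )
        for season, tab in result.tables.items():
            tab = tab.copy()
            tab.insert(0, "species", species)
            tab.insert(1, "season", season)
            tab["is_map"] = tab["candidate"] == result.map_index[season]
            score_tabs.append(tab)
        for season, fit in sp_fits.items():
            sub = test[(test["species"] == species) & (test["season"] == season)]
            if len(sub) == 0 or sub["presence"].nunique() < 2:
                continue
            stats = fusion.fused_evaluate(fit, result.map_theta[season], sub)
            stats.update(
                species=species, season=season,
                map_index=result.map_index[season],
                sdm_certainty=fusion.sdm_certainty_bin(val.loc[(species, season), "auc"]),
                neva_certainty=votes[species].certainty("sensitivity"),
            )
            eval_rows.append(stats)
    _write_csv(pd.concat(score_tabs, ignore_index=True), out / "candidate_scores.csv")
    fused = pd.DataFrame(eval_rows)
    _write_csv(fused, out / "fused_comparison.csv")
    strat = (
        fused.groupby(["sdm_certainty", "neva_certainty"])[
            ["r_sdm", "r_combined", "crmse_norm_sdm", "crmse_norm_combined",
             "sd_ratio_sdm", "sd_ratio_combined"]
        ]
        .mean()
        .reset_index()
    )
    _write_csv(strat, out / "fused_by_certainty.csv")
    log.info("fuse: %d species-season models fused", len(eval_rows))
    return {"fused": out / "fused_comparison.csv"}


_STAGE_FN = {
    "generate": stage_generate,
    "downscale": stage_downscale,
    "fit": stage_fit,
    "validate": stage_validate,
    "project": stage_project,
    "compare": stage_compare,
    "fuse": stage_fuse,
}


def run_pipeline(config: RunConfig, stages=STAGES) -> dict:
    """Run the requested stages in order; returns the artifact manifest."""
    out = _out(config)
    config.to_yaml(out / "config.yaml")
    manifest = {}
    for stage in stages:
        log.info("--- stage %s", stage)
        try:
            manifest.update({k: str(v) for k, v in _STAGE_FN[stage](config).items()})
        except Exception:
            log.exception("stage %s failed; partial artifacts kept in %s", stage, out)
            raise
    if "fuse" in stages:  # digest needs the late-stage artifacts
        digest = summarize_run(config)
        (out / "digest.txt").write_text(digest)
        manifest["digest"] = str(out / "digest.txt")
    return manifest


def summarize_run(config: RunConfig) -> str:
    """Human-readable digest rebuilt purely from the persisted artifacts."""
    out = Path(config.outdir)
    lines = ["sdmfuse run digest", "=" * 40]
    val = pd.read_csv(out / "validation.csv")
    n_sp = val["species"].nunique()
    n_inc = val.loc[val["included"], "species"].nunique()
    lines.append(f"species with AUC >= {config.auc_threshold:.2f} in both seasons: "
                 f"{n_inc}/{n_sp}")
    lines.append(f"mean held-out AUC: {val['auc'].mean():.3f}; "
                 f"mean correlation: {val['r'].mean():.3f}")
    ch = pd.read_csv(out / "changes.csv")
    for season in config.synthetic.seasons:
        for scen in config.scenarios:
            sub = ch[(ch["season"] == season) & (ch["scenario"] == scen)]
            capped = (sub["domain_pct_change"] > config.cap).sum()
            marker = f" [{capped} capped at {config.cap:.0f}%]" if capped else ""
            lines.append(
                f"{season}/{scen}: mean shelf-wide change "
                f"{sub['domain_pct_change_capped'].mean():+.1f}%{marker}"
            )
    comp = pd.read_csv(out / "comparison.csv")
    lines.append(
        f"sensitivity rank matches: {int(comp['match_sensitivity'].sum())}/{len(comp)}; "
        f"directional matches: {int(comp['match_direction'].sum())}/{len(comp)}"
    )
    fused = pd.read_csv(out / "fused_comparison.csv")
    lines.append(
        "combined vs SDM (mean over models): "
        f"d_r={fused['d_r'].mean():+.4f}, "
        f"d_crmse_norm={fused['d_crmse_norm'].mean():+.4f}, "
        f"d_sd_ratio={fused['d_sd_ratio'].mean():+.4f}"
    )
    return "\n".join(lines) + "\n"
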