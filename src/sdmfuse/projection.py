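"""Relative-biomass projection under future SSTs and percent-change
summaries, shelf-wide and by subregion.

Shelf-wide percent change is, by default, the percent change of the
domain-total relative biomass; regional summaries (Gulf of Maine analogue
vs southern New England/Mid-Atlantic Bight analogue) average per-cell
percent changes within the region. Reported changes may be capped at
+500% for display; the cap is never applied to SensWeight or fusion
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

from .delta import DeltaGAMFit, predict_biomass

SCENARIOS = ("p5", "mean", "p95")


@dataclass
class RegionMask:
    name: str
    mask: np.ndarray  # boolean, (lat, lon)


@dataclass
class ChangeField:
    species: str
    season: str
    scenario: str
    baseline: xr.DataArray     # relative biomass per cell
    future: xr.DataArray
    pct_change: xr.DataArray   # NaN where baseline == 0
    n_zero_baseline: int
    domain_pct_change: float   # change of the domain-total biomass
    domain_pct_change_cellmean: float  # mean of per-cell percent changes


def _env_dict(sst_field: xr.DataArray, depth_field: xr.DataArray) -> dict:
    return {"sst": sst_field.values.ravel(), "depth": depth_field.values.ravel()}


def project_change(
    fit: DeltaGAMFit,
    baseline_env: dict[str, xr.DataArray],
    future_env: dict[str, xr.DataArray],
    scenario: str = "mean",
    warn_extrapolation: bool = False,
) -> ChangeField:
    """Project relative biomass on the grid for both periods.

    ``baseline_env`` and ``future_env`` map "sst" and "depth" to
    (lat, lon) fields on an identical grid. Cells with zero baseline
    biomass are flagged and excluded from per-cell percent changes.
    """
    b_sst, b_dep = baseline_env["sst"], baseline_env["depth"]
    f_sst, f_dep = future_env["sst"], future_env["depth"]
    if b_sst.shape != f_sst.shape or not np.array_equal(
        b_sst["lat"].values, f_sst["lat"].values
    ) or not np.array_equal(b_sst["lon"].values, f_sst["lon"].values):
        raise ValueError("baseline and future environments are on different grids")

    base = predict_biomass(fit, _env_dict(b_sst, b_dep), warn_extrapolation)
    fut = predict_biomass(fit, _env_dict(f_sst, f_dep), warn_extrapolation)
    base_da = b_sst.copy(data=base.reshape(b_sst.shape))
    fut_da = b_sst.copy(data=fut.reshape(b_sst.shape))
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (fut_da - base_da) / base_da
    zero = base_da.values == 0
    pct = pct.where(~zero)
    tot_base, tot_fut = float(base_da.sum()), float(fut_da.sum())
    domain_total = 100.0 * (tot_fut - tot_base) / tot_base if tot_base > 0 else np.nan
    return ChangeField(
        species=fit.species,
        season=fit.season,
        scenario=scenario,
        baseline=base_da.rename("baseline"),
        future=fut_da.rename("future"),
        pct_change=pct.rename("pct_change"),
        n_zero_baseline=int(zero.sum()),
        domain_pct_change=domain_total,
        domain_pct_change_cellmean=float(pct.mean(skipna=True)),
    )


def regional_summary(change: ChangeField, region: RegionMask) -> float:
    """Mean per-cell percent change over the region's member cells."""
    mask = np.asarray(region.mask, dtype=bool)
    if not mask.any():
        raise ValueError(f"region {region.name!r} has no member cells")
    vals = change.pct_change.values[mask]
    return float(np.nanmean(vals))


def cap_changes(values, cap: float = 500.0):
    """One-sided reporting cap: min(value, cap); no lower cap."""
    if cap <= 0:
        raise ValueError("cap must be positive")
    return np.minimum(np.asarray(values, dtype=float), cap)


def default_regions(lat: np.ndarray, lon: np.ndarray,
                    split_lat: float = 41.5) -> list[RegionMask]:
    """Northern (GoM analogue) and southern (SNE-MAB analogue) halves of
    the domain, split at the physiographic-break latitude analogue."""
    LAT = np.broadcast_to(lat[:, None], (lat.size, lon.size))
    return [
        RegionMask("GoM", LAT >= split_lat),
        RegionMask("SNE-MAB", LAT < split_lat),
    ]


def change_fields_to_dataset(changes: list[ChangeField]) -> xr.Dataset:
    """Stack ChangeFields into one Dataset indexed by species/season/scenario."""
    keys = [(c.species, c.season, c.scenario) for c in changes]
    idx = xr.DataArray(
        np.arange(len(changes)), dims="case",
        coords={
            "species": ("case", [k[0] for k in keys]),
            "season": ("case", [k[1] for k in keys]),
            "scenario": ("case", [k[2] for k in keys]),
        },
    )
    ds = xr.Dataset(
        {
            "baseline": xr.concat([c.baseline for c in changes], dim="case"),
            "future": xr.concat([c.future for c in changes], dim="case"),
            "pct_change": xr.concat([c.pct_change for c in changes], dim="case"),
        }
    )
    ds = ds.assign_coords(case=idx["case"],
                          species=idx["species"], season=idx["season"],
                          scenario=idx["scenario"])
    return ds
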