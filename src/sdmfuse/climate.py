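"""Delta downscaling of ensemble sea-surface temperatures.

Monthly SST fields are carried as :class:`xarray.DataArray` objects with
dims ``(year, month, lat, lon)`` ("stacks") or ``(month, lat, lon)``
(climatologies); missing cells are NaN. The delta method computes each
member's anomalies from its own baseline climatology and adds them to the
observed climatology, which implicitly removes member mean biases (the
Gulf Stream warm-bias correction of the source datasets). Ensemble
percentile summaries use order statistics — the 5th/95th percentiles are
the second-coldest and second-warmest member values — rather than
interpolated quantiles.
"""

from __future__ import annotations

import warnings

import numpy as np
import xarray as xr

SEASON_MONTHS = {"spring": (3, 4, 5), "fall": (9, 10, 11)}
SEASONS = tuple(SEASON_MONTHS)


def _check_grid(a: xr.DataArray, b: xr.DataArray) -> None:
    if not (np.array_equal(a["lat"].values, b["lat"].values)
            and np.array_equal(a["lon"].values, b["lon"].values)):
        raise ValueError("lon/lat grids do not match")


def compute_climatology(stack: xr.DataArray, year_range: tuple[int, int]) -> xr.DataArray:
    """Per-(month, cell) mean over the inclusive ``year_range``."""
    y0, y1 = year_range
    years = stack["year"].values
    sel = (years >= y0) & (years <= y1)
    if not sel.any():
        raise ValueError(f"no years of the stack fall in {year_range}")
    clim = stack.isel(year=sel).mean("year", skipna=False)
    clim.attrs["reference_period"] = f"{y0}-{y1}"
    return clim


def compute_anomalies(member: xr.DataArray, climatology: xr.DataArray) -> xr.DataArray:
    """Departures of each year-month field from the monthly climatology."""
    _check_grid(member, climatology)
    anom = member - climatology
    anom.attrs["kind"] = "anomaly"
    return anom


def regrid_anomalies(anomalies: xr.DataArray, target: xr.DataArray | dict) -> xr.DataArray:
    """Bilinear interpolation of anomaly fields onto the target lon/lat grid."""
    if isinstance(target, dict):
        lon, lat = np.asarray(target["lon"]), np.asarray(target["lat"])
    else:
        lon, lat = target["lon"].values, target["lat"].values
    out = anomalies.interp(lon=lon, lat=lat, method="linear")
    return out


def downscale(anomalies: xr.DataArray, observed_climatology: xr.DataArray) -> xr.DataArray:
    """Delta method: observed climatology + anomalies, on the observed grid."""
    _check_grid(anomalies, observed_climatology)
    out = (observed_climatology + anomalies).transpose(*anomalies.dims)
    out.attrs["kind"] = "downscaled"
    return out


def _fill2d(values: np.ndarray, domain: np.ndarray) -> tuple[np.ndarray, int]:
    """One field: iterative 8-neighbour (queen adjacency) mean fill.

    Returns the filled array and the count of in-domain cells that could
    never be filled (isolated missing regions).
    """
    v = values.copy()
    while True:
        missing = np.isnan(v) & domain
        if not missing.any():
            return v, 0
        padded = np.pad(v, 1, constant_values=np.nan)
        stacked = np.stack([
            padded[1 + di:padded.shape[0] - 1 + di, 1 + dj:padded.shape[1] - 1 + dj]
            for di in (-1, 0, 1) for dj in (-1, 0, 1) if not (di == 0 and dj == 0)
        ])
        counts = np.sum(~np.isnan(stacked), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(stacked, axis=0)
        fillable = missing & (counts > 0)
        if not fillable.any():
            return v, int(missing.sum())
        v[fillable] = means[fillable]


def fill_coastal(field: xr.DataArray, domain: xr.DataArray | np.ndarray | None = None) -> xr.DataArray:
    """Gap-fill missing in-domain cells with the mean of bordering cells.

    Bordering cells are the 8-neighbourhood; passes repeat until no cell
    changes, so multi-cell-deep gaps fill outside-in. Cells that can never
    acquire a non-missing neighbour are left NaN and reported via a
    warning and the ``n_unfillable`` attribute.
    """
    if domain is None:
        dom = np.ones(field.shape[-2:], dtype=bool)
    else:
        dom = np.asarray(domain.values if isinstance(domain, xr.DataArray) else domain, dtype=bool)
    vals = field.values.reshape(-1, *field.shape[-2:]).copy()
    unfillable = 0
    for i in range(vals.shape[0]):
        vals[i], bad = _fill2d(vals[i], dom)
        unfillable = max(unfillable, bad)
    out = field.copy(data=vals.reshape(field.shape))
    out.attrs["n_unfillable"] = unfillable
    if unfillable:
        warnings.warn(f"{unfillable} in-domain cells are unfillable (no neighbours)",
                      stacklevel=2)
    return out


def ensemble_summary(members: list[xr.DataArray]) -> xr.Dataset:
    """Ensemble mean and order-statistic percentiles per (year, month, cell).

    ``p5`` is the second-coldest member value and ``p95`` the
    second-warmest, following the source convention for a 27-member
    ensemble; at least 3 members are required for these order statistics
    to be defined.
    """
    if len(members) < 3:
        raise ValueError(f"ensemble summary needs >= 3 members, got {len(members)}")
    for m in members[1:]:
        _check_grid(members[0], m)
    stacked = np.stack([m.values for m in members])
    srt = np.sort(stacked, axis=0)
    template = members[0]
    return xr.Dataset(
        {
            "mean": template.copy(data=stacked.mean(axis=0)),
            "p5": template.copy(data=srt[1]),
            "p95": template.copy(data=srt[-2]),
        }
    )


def seasonal_mean(stack: xr.DataArray, season: str) -> xr.DataArray:
    """Per-year seasonal field: mean of MAM (spring) or SON (fall) months."""
    if season not in SEASON_MONTHS:
        raise ValueError(f"season must be one of {SEASONS}, got {season!r}")
    months = SEASON_MONTHS[season]
    have = set(np.atleast_1d(stack["month"].values).tolist())
    missing = [m for m in months if m not in have]
    if missing:
        raise ValueError(f"stack lacks months {missing} needed for {season}")
    out = stack.sel(month=list(months)).mean("month", skipna=False)
    out.attrs["season"] = season
    return out


def save_field(field: xr.DataArray | xr.Dataset, path, name: str = "sst") -> None:
    """Write a gridded field as NetCDF-3 with CF-style coordinates."""
    ds = field.to_dataset(name=name) if isinstance(field, xr.DataArray) else field
    ds = ds.copy()
    if "lon" in ds.coords:
        ds["lon"].attrs.update(units="degrees_east", standard_name="longitude")
    if "lat" in ds.coords:
        ds["lat"].attrs.update(units="degrees_north", standard_name="latitude")
    ds.to_netcdf(path, engine="scipy")


def load_field(path, name: str | None = "sst"):
    ds = xr.open_dataset(path, engine="scipy").load()
    ds.close()
    if name is not None and name in ds:
        return ds[name]
    return ds
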