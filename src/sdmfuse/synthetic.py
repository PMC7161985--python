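"""Synthetic study system: environment, climate ensemble, trawl survey,
and expert vote generators.

Everything downstream of the real (restricted) inputs — bottom-trawl
biomass records, observed and ensemble SST fields, bathymetry, and expert
vote sheets — is emulated here with the statistical structure the analysis
assumes: stratified-random station allocation proportional to stratum area
with a two-station minimum, presence and positive biomass responding
smoothly (Gaussian kernels) to seasonal SST and depth with lognormal noise,
ensemble members as biased/trended perturbations of an observed-analogue
climatology with missing coastal cells, and expert votes drawn from
multinomial distributions concentrated on each species' true rank.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy.ndimage import gaussian_filter

from .climate import SEASONS, compute_climatology, regrid_anomalies, seasonal_mean
from .vulnerability import DIRECTION_BINS, SENSITIVITY_BINS


@dataclass
class SyntheticConfig:
    """Study-domain and sampling configuration.

    Defaults give a 20x20-cell shelf analogue (10 degrees of longitude and
    latitude), 12 latitudinal strata, 300 stations per seasonal survey,
    a 1982-2011 baseline with observations through 2015, a single 2055
    future year, and a 27-member ensemble.
    """

    grid_nx: int = 20
    grid_ny: int = 20
    lon_min: float = -76.0
    lon_max: float = -66.0
    lat_min: float = 35.0
    lat_max: float = 45.0
    years_baseline: tuple[int, int] = (1982, 2011)
    year_obs_end: int = 2015
    year_future: int = 2055
    seasons: tuple[str, str] = ("spring", "fall")
    n_strata: int = 12
    n_stations_per_survey: int = 300
    n_members: int = 27
    seed: int = 20200416
    # environment shape
    sst_lat_gradient: float = -0.8   # degC per degree latitude
    sst_trend: float = 0.03          # degC per year
    sst_noise_sd: float = 0.4        # degC, smooth field noise
    # ensemble member perturbations
    member_bias_sd: float = 0.75     # degC spread of member mean biases
    member_bias_mean: float = 1.5    # degC warm bias before delta correction
    member_trend_mean: float = 0.035  # degC per year
    member_trend_sd: float = 0.008
    member_noise_sd: float = 0.3
    n_coastal_missing: int = 6       # coarse coastal cells missing in members
    strata_weights: tuple | None = None  # relative stratum areas

    def __post_init__(self):
        if self.grid_nx < 4 or self.grid_ny < 4:
            raise ValueError("grid must be at least 4x4 cells")
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise ValueError("degenerate (zero-area) lon/lat extent")
        if self.n_members < 3:
            raise ValueError("ensemble needs at least 3 members")
        if tuple(sorted(self.seasons)) != tuple(sorted(SEASONS)):
            raise ValueError(f"seasons must be exactly {SEASONS}")

    def lon(self) -> np.ndarray:
        dx = (self.lon_max - self.lon_min) / self.grid_nx
        return self.lon_min + dx * (np.arange(self.grid_nx) + 0.5)

    def lat(self) -> np.ndarray:
        dy = (self.lat_max - self.lat_min) / self.grid_ny
        return self.lat_min + dy * (np.arange(self.grid_ny) + 0.5)

    def obs_years(self) -> np.ndarray:
        return np.arange(self.years_baseline[0], self.year_obs_end + 1)


@dataclass
class TrueSpecies:
    """Ground-truth response surface and vulnerability class of one species."""

    name: str
    sst_optimum: float          # degC
    sst_breadth: float          # degC
    depth_optimum: float        # m
    depth_breadth: float        # m
    max_presence_prob: float = 0.9
    log_biomass_at_optimum: float = 3.0  # log(kg)
    lognormal_sigma: float = 0.6
    true_direction: str = "neutral"
    true_sensitivity: str = "moderate"
    sst_optimum2: float | None = None   # optional second thermal mode
    mix_weight: float = 0.5

    def __post_init__(self):
        if self.sst_breadth <= 0 or self.depth_breadth <= 0:
            raise ValueError("response breadths must be positive")
        if not (0 < self.max_presence_prob <= 1):
            raise ValueError("max_presence_prob must be in (0, 1]")
        if self.lognormal_sigma < 0:
            raise ValueError("lognormal_sigma must be >= 0")
        if self.true_direction not in DIRECTION_BINS:
            raise ValueError(f"true_direction must be one of {DIRECTION_BINS}")
        if self.true_sensitivity not in SENSITIVITY_BINS:
            raise ValueError(f"true_sensitivity must be one of {SENSITIVITY_BINS}")

    def response(self, sst, depth) -> np.ndarray:
        """Habitat suitability in [0, 1]: product of Gaussian kernels."""
        sst = np.asarray(sst, dtype=float)
        depth = np.asarray(depth, dtype=float)
        g1 = np.exp(-0.5 * ((sst - self.sst_optimum) / self.sst_breadth) ** 2)
        if self.sst_optimum2 is not None:
            g2 = np.exp(-0.5 * ((sst - self.sst_optimum2) / self.sst_breadth) ** 2)
            g1 = self.mix_weight * g1 + (1 - self.mix_weight) * g2
        gd = np.exp(-0.5 * ((depth - self.depth_optimum) / self.depth_breadth) ** 2)
        return g1 * gd


@dataclass
class ExpertPanel:
    """Vote-sheet structure of the expert elicitation.

    Five experts with five tallies each score 12 sensitivity attributes
    over four bins (25 votes per attribute, 300 in total); three experts
    with four tallies each score the directional effect over three bins
    (12 votes). ``concentration`` controls how tightly simulated votes
    cluster on the species' true bin (Dirichlet perturbation of a one-hot
    probability vector).
    """

    n_experts_sensitivity: int = 5
    tallies_per_expert_sensitivity: int = 5
    n_attributes: int = 12
    n_experts_directional: int = 3
    tallies_per_expert_directional: int = 4
    concentration: float = 8.0

    def __post_init__(self):
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        for f in ("n_experts_sensitivity", "tallies_per_expert_sensitivity",
                  "n_attributes", "n_experts_directional",
                  "tallies_per_expert_directional"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be >= 1")

    @property
    def votes_per_attribute(self) -> int:
        return self.n_experts_sensitivity * self.tallies_per_expert_sensitivity

    @property
    def directional_votes(self) -> int:
        return self.n_experts_directional * self.tallies_per_expert_directional


@dataclass
class Environment:
    depth: xr.DataArray                # (lat, lon), m, positive
    sst_monthly: xr.DataArray          # (year, month, lat, lon), degC
    config: SyntheticConfig
    _seasonal_cache: dict = field(default_factory=dict, repr=False)

    def seasonal_sst(self, season: str) -> xr.DataArray:
        if season not in self._seasonal_cache:
            self._seasonal_cache[season] = seasonal_mean(self.sst_monthly, season)
        return self._seasonal_cache[season]


@dataclass
class ClimateEnsemble:
    members: list[xr.DataArray]        # (year, month, lat, lon) on coarse grid
    missing_mask: np.ndarray           # coarse (lat, lon) bool, True = missing
    biases: np.ndarray
    trends: np.ndarray
    config: SyntheticConfig


def _smooth_noise(rng: np.random.Generator, shape, sd: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(shape)
    white = rng.normal(size=shape)
    sm = gaussian_filter(white, sigma=2.0, mode="reflect")
    s = sm.std()
    return sm / s * sd if s > 0 else sm


def gen_environment(config: SyntheticConfig) -> Environment:
    """Static depth field and monthly observed-analogue SST stack.

    SST is a latitudinal gradient plus a seasonal cycle, a linear warming
    trend, and seeded smooth spatial noise; depth increases smoothly
    offshore (eastward) with mild meridional structure.
    """
    rng = np.random.default_rng([config.seed, 1])
    lon, lat = config.lon(), config.lat()
    LON, LAT = np.meshgrid(lon, lat)

    u = (LON - config.lon_min) / (config.lon_max - config.lon_min)
    v = (LAT - config.lat_min) / (config.lat_max - config.lat_min)
    depth_vals = 15.0 + 280.0 * u**1.3 + 30.0 * np.sin(2 * np.pi * v) * u
    depth_vals += _smooth_noise(rng, depth_vals.shape, 8.0)
    depth_vals = np.clip(depth_vals, 5.0, None)
    depth = xr.DataArray(depth_vals, coords={"lat": lat, "lon": lon},
                         dims=("lat", "lon"), name="depth", attrs={"units": "m"})

    years = config.obs_years()
    months = np.arange(1, 13)
    lat_mid = (config.lat_min + config.lat_max) / 2
    base = 12.0 + config.sst_lat_gradient * (LAT - lat_mid)
    cycle = 6.0 * np.cos(2 * np.pi * (months - 8) / 12.0)
    sst = np.empty((years.size, months.size, lat.size, lon.size))
    for iy, y in enumerate(years):
        for im, m in enumerate(months):
            sst[iy, im] = (
                base
                + cycle[im]
                + config.sst_trend * (y - years[0])
                + _smooth_noise(rng, base.shape, config.sst_noise_sd)
            )
    sst_da = xr.DataArray(
        sst,
        coords={"year": years, "month": months, "lat": lat, "lon": lon},
        dims=("year", "month", "lat", "lon"),
        name="sst",
        attrs={"units": "degC"},
    )
    return Environment(depth=depth, sst_monthly=sst_da, config=config)


def gen_climate_ensemble(config: SyntheticConfig, env: Environment) -> ClimateEnsemble:
    """Ensemble members on a coarser grid, 1982 through the future year.

    Each member is the observed-analogue baseline climatology (interpolated
    to the coarse grid) plus a member-specific mean bias, linear trend, and
    smooth noise. A fixed set of coastal (westernmost) cells is missing in
    every member to exercise gap-filling.
    """
    if config.n_members < 3:
        raise ValueError("ensemble needs at least 3 members")
    rng = np.random.default_rng([config.seed, 2])
    obs_clim = compute_climatology(env.sst_monthly, config.years_baseline)
    lon_c = env.sst_monthly["lon"].values[::2]
    lat_c = env.sst_monthly["lat"].values[::2]
    clim_c = regrid_anomalies(obs_clim, {"lon": lon_c, "lat": lat_c})

    missing = np.zeros((lat_c.size, lon_c.size), dtype=bool)
    n_missing = min(config.n_coastal_missing, lat_c.size)
    rows = rng.choice(lat_c.size, size=n_missing, replace=False)
    missing[rows, 0] = True  # western (coastal) edge

    years = np.arange(config.years_baseline[0], config.year_future + 1)
    months = np.arange(1, 13)
    biases = config.member_bias_mean + rng.normal(0, config.member_bias_sd, config.n_members)
    trends = config.member_trend_mean + rng.normal(0, config.member_trend_sd, config.n_members)
    if config.member_bias_sd == 0 and config.member_bias_mean == 0:
        biases = np.zeros(config.n_members)
    if config.member_trend_sd == 0 and config.member_trend_mean == 0:
        trends = np.zeros(config.n_members)

    members = []
    clim_vals = clim_c.values  # (month, lat, lon)
    for i in range(config.n_members):
        vals = np.empty((years.size, months.size, lat_c.size, lon_c.size))
        for iy, y in enumerate(years):
            dy = y - years[0]
            for im in range(12):
                vals[iy, im] = (
                    clim_vals[im]
                    + biases[i]
                    + trends[i] * dy
                    + _smooth_noise(rng, clim_vals[im].shape, config.member_noise_sd)
                )
        vals[:, :, missing] = np.nan
        members.append(
            xr.DataArray(
                vals,
                coords={"year": years, "month": months, "lat": lat_c, "lon": lon_c},
                dims=("year", "month", "lat", "lon"),
                name=f"member_{i:02d}",
            )
        )
    return ClimateEnsemble(members=members, missing_mask=missing,
                           biases=biases, trends=trends, config=config)


def stratum_edges(config: SyntheticConfig) -> np.ndarray:
    """Latitudinal band edges of the survey strata (unequal areas)."""
    w = (np.asarray(config.strata_weights, dtype=float)
         if config.strata_weights is not None
         else np.linspace(1.0, 3.0, config.n_strata))
    if w.size != config.n_strata or np.any(w <= 0):
        raise ValueError("strata_weights must be positive with one entry per stratum")
    cum = np.r_[0.0, np.cumsum(w)] / w.sum()
    return config.lat_min + cum * (config.lat_max - config.lat_min)


def allocate_stations(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Random station allocation proportional to stratum area, min 2 each.

    Stations are drawn multinomially with probabilities equal to stratum
    area shares; strata falling below two stations are topped up by
    reassigning stations from the currently largest allocations.
    """
    n = config.n_stations_per_survey
    if n < 2 * config.n_strata:
        raise ValueError(
            f"station budget {n} cannot give 2 stations to each of "
            f"{config.n_strata} strata"
        )
    edges = stratum_edges(config)
    shares = np.diff(edges) / (edges[-1] - edges[0])
    counts = rng.multinomial(n, shares)
    while counts.min() < 2:
        counts[np.argmax(counts)] -= 1
        counts[np.argmin(counts)] += 1
    return counts


def _interp_points(fld: xr.DataArray, lats, lons) -> np.ndarray:
    pts = fld.interp(
        lat=xr.DataArray(lats, dims="station"),
        lon=xr.DataArray(lons, dims="station"),
        method="linear",
    )
    return pts.values


def gen_survey(
    env: Environment,
    species_list: list[TrueSpecies],
    config: SyntheticConfig,
    years: np.ndarray | None = None,
) -> pd.DataFrame:
    """Stratified-random seasonal surveys with per-species catches.

    One row per (tow, species): presence ~ Bernoulli(max_presence_prob x
    habitat suitability), positive biomass lognormal about the species'
    response surface, zero biomass recorded for absences.
    """
    rng = np.random.default_rng([config.seed, 3])
    if years is None:
        years = env.sst_monthly["year"].values
    edges = stratum_edges(config)
    lat_cells, lon_cells = config.lat(), config.lon()
    lat_lo, lat_hi = lat_cells[0], lat_cells[-1]
    lon_lo, lon_hi = lon_cells[0], lon_cells[-1]

    rows = []
    for year in years:
        for season in config.seasons:
            sst_field = env.seasonal_sst(season).sel(year=year)
            counts = allocate_stations(config, rng)
            lats, lons, strata = [], [], []
            for s, c in enumerate(counts):
                lo = np.clip(edges[s], lat_lo, lat_hi)
                hi = np.clip(edges[s + 1], lat_lo, lat_hi)
                lats.append(rng.uniform(lo, hi, c))
                lons.append(rng.uniform(lon_lo, lon_hi, c))
                strata.append(np.full(c, s))
            lats = np.concatenate(lats)
            lons = np.concatenate(lons)
            strata = np.concatenate(strata)
            depth = _interp_points(env.depth, lats, lons)
            sst = _interp_points(sst_field, lats, lons)
            tow_ids = np.array([f"{year}-{season}-{i:04d}" for i in range(lats.size)])
            for sp in species_list:
                resp = np.asarray(sp.response(sst, depth), dtype=float)
                p = sp.max_presence_prob * resp
                present = rng.random(lats.size) < p
                mu = sp.log_biomass_at_optimum + np.log(np.maximum(resp, 1e-12))
                noise = rng.normal(0, sp.lognormal_sigma, lats.size)
                biomass = np.where(present, np.exp(mu + noise), 0.0)
                rows.append(pd.DataFrame({
                    "tow_id": tow_ids, "year": int(year), "season": season,
                    "lon": lons, "lat": lats, "stratum": strata,
                    "depth_m": depth, "sst": sst, "species": sp.name,
                    "biomass_kg": biomass, "presence": present.astype(int),
                }))
    return pd.concat(rows, ignore_index=True)


def gen_expert_votes(species: TrueSpecies, panel: ExpertPanel,
                     rng: np.random.Generator):
    """Multinomial vote tables concentrated on the species' true bins.

    Per sensitivity attribute, the 4-bin vote probabilities are a Dirichlet
    perturbation of a one-hot vector on the true sensitivity bin (alpha =
    concentration x one-hot + 1/2); the 25 attribute votes are multinomial
    under them. Directional votes (12 over 3 bins) are built the same way
    around the true direction.
    """
    from .fusion import ExpertVotes

    s_idx = SENSITIVITY_BINS.index(species.true_sensitivity)
    d_idx = DIRECTION_BINS.index(species.true_direction)
    per_attribute = np.zeros((panel.n_attributes, 4), dtype=int)
    for a in range(panel.n_attributes):
        alpha = np.full(4, 0.5)
        alpha[s_idx] += panel.concentration
        p = rng.dirichlet(alpha)
        per_attribute[a] = rng.multinomial(panel.votes_per_attribute, p)
    alpha_d = np.full(3, 0.5)
    alpha_d[d_idx] += panel.concentration
    directional = rng.multinomial(panel.directional_votes, rng.dirichlet(alpha_d))
    return ExpertVotes(
        species=species.name,
        sensitivity=per_attribute.sum(axis=0),
        directional=directional,
        per_attribute=per_attribute,
    )


def default_species() -> list[TrueSpecies]:
    """Eight fixed species spanning thermal niches and vulnerability ranks."""
    return [
        TrueSpecies("cold_groundfish", 8.0, 3.0, 180.0, 90.0, 0.9, 3.5, 0.6,
                    "negative", "very high"),
        TrueSpecies("cold_forage", 9.5, 3.5, 80.0, 60.0, 0.95, 4.0, 0.7,
                    "negative", "high"),
        TrueSpecies("mid_elasmobranch", 12.0, 4.5, 120.0, 100.0, 0.85, 3.0, 0.6,
                    "neutral", "moderate"),
        TrueSpecies("generalist_flatfish", 13.0, 6.0, 90.0, 120.0, 0.9, 3.2, 0.5,
                    "neutral", "low"),
        TrueSpecies("deep_invert", 10.0, 5.0, 260.0, 80.0, 0.8, 2.8, 0.8,
                    "neutral", "moderate"),
        TrueSpecies("warm_coastal", 17.0, 4.0, 40.0, 50.0, 0.9, 3.0, 0.7,
                    "positive", "high"),
        TrueSpecies("warm_migrant", 19.0, 4.0, 60.0, 70.0, 0.85, 2.5, 0.9,
                    "positive", "moderate"),
        TrueSpecies("pelagic_forage", 14.5, 5.0, 70.0, 90.0, 0.95, 4.2, 0.8,
                    "neutral", "low"),
    ]


def random_species_panel(n: int, rng: np.random.Generator) -> list[TrueSpecies]:
    """A randomized species panel for larger-scale experiments."""
    out = []
    for i in range(n):
        sst_opt = rng.uniform(7, 20)
        direction = ("positive" if sst_opt > 15.5
                     else "negative" if sst_opt < 10.5 else "neutral")
        out.append(
            TrueSpecies(
                name=f"species_{i:02d}",
                sst_optimum=float(sst_opt),
                sst_breadth=float(rng.uniform(2.5, 6)),
                depth_optimum=float(rng.uniform(30, 260)),
                depth_breadth=float(rng.uniform(50, 150)),
                max_presence_prob=float(rng.uniform(0.75, 0.95)),
                log_biomass_at_optimum=float(rng.uniform(2.5, 4.0)),
                lognormal_sigma=float(rng.uniform(0.5, 0.9)),
                true_direction=direction,
                true_sensitivity=str(rng.choice(SENSITIVITY_BINS)),
            )
        )
    return out
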