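"""Two-stage delta GAMs for trawl-survey biomass.

Stage 1 is a binomial-logit GAM of presence/absence on smooths of seasonal
sea-surface temperature and depth; stage 2 is a Gaussian GAM of log positive
biomass on the same smooths, fitted only to tows where the species was
caught. Overall relative biomass at a point is the product of the predicted
presence probability and the exponentiated stage-2 prediction. No
retransformation (smearing) correction is applied to the exponentiation;
the resulting lognormal back-transform bias is documented in the methods
note.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .gam import DegenerateModelError, StageFit, fit_gam
from .splines import SmoothTerm

DEFAULT_MIN_TOWS = 30
DEFAULT_MIN_PRESENCES = 15


@dataclass
class DeltaGAMFit:
    species: str
    season: str
    stage1: StageFit  # binomial logit, presence/absence
    stage2: StageFit  # Gaussian identity, log positive biomass
    train_years: tuple[int, int]
    n_tows: int
    n_presences: int

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "season": self.season,
            "stage1": self.stage1.to_dict(),
            "stage2": self.stage2.to_dict(),
            "train_years": list(self.train_years),
            "n_tows": self.n_tows,
            "n_presences": self.n_presences,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DeltaGAMFit":
        return cls(
            species=d["species"],
            season=d["season"],
            stage1=StageFit.from_dict(d["stage1"]),
            stage2=StageFit.from_dict(d["stage2"]),
            train_years=tuple(d["train_years"]),
            n_tows=d["n_tows"],
            n_presences=d["n_presences"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "DeltaGAMFit":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_smooths(k: int = 10, shrinkage: bool = True) -> list[SmoothTerm]:
    return [SmoothTerm("sst", k=k, shrinkage=shrinkage),
            SmoothTerm("depth", k=k, shrinkage=shrinkage)]


def fit_delta_gam(
    survey: pd.DataFrame,
    species: str,
    season: str,
    smooths: list[SmoothTerm] | None = None,
    criterion: str = "reml",
    min_tows: int = DEFAULT_MIN_TOWS,
    min_presences: int = DEFAULT_MIN_PRESENCES,
) -> DeltaGAMFit:
    """Fit the two-stage delta GAM for one species-season.

    ``survey`` needs columns species, season, year, sst, depth_m,
    biomass_kg, presence. Refuses to fit when there are too few tows or too
    few positive records; an all-presence or all-absence response raises
    :class:`~sdmfuse.gam.DegenerateModelError`.
    """
    sub = survey[(survey["species"] == species) & (survey["season"] == season)]
    if len(sub) < min_tows:
        raise ValueError(
            f"{species}/{season}: {len(sub)} tows < required minimum {min_tows}"
        )
    pos = sub[sub["biomass_kg"] > 0]
    if len(pos) < min_presences:
        raise ValueError(
            f"{species}/{season}: {len(pos)} presences < required minimum {min_presences}"
        )
    env_all = {"sst": sub["sst"].to_numpy(), "depth": sub["depth_m"].to_numpy()}
    y1 = sub["presence"].to_numpy(dtype=float)
    if smooths is None:
        smooths = default_smooths()
    smooths2 = [SmoothTerm(t.variable, k=t.k, shrinkage=t.shrinkage) for t in smooths]

    stage1 = fit_gam(env_all, y1, "binomial", smooths, criterion=criterion)
    env_pos = {"sst": pos["sst"].to_numpy(), "depth": pos["depth_m"].to_numpy()}
    stage2 = fit_gam(env_pos, np.log(pos["biomass_kg"].to_numpy()), "gaussian",
                     smooths2, criterion=criterion)
    years = sub["year"]
    return DeltaGAMFit(
        species=species,
        season=season,
        stage1=stage1,
        stage2=stage2,
        train_years=(int(years.min()), int(years.max())),
        n_tows=len(sub),
        n_presences=len(pos),
    )


def predict_presence(fit: DeltaGAMFit, env: dict, warn_extrapolation: bool = True) -> np.ndarray:
    """Probability of presence (inverse-logit of the stage-1 predictor)."""
    return fit.stage1.predict(env, warn_extrapolation=warn_extrapolation)


def predict_log_biomass(fit: DeltaGAMFit, env: dict, beta: np.ndarray | None = None,
                        warn_extrapolation: bool = True) -> np.ndarray:
    """Stage-2 (conditional log positive biomass) prediction."""
    return fit.stage2.predict(env, beta=beta, warn_extrapolation=warn_extrapolation)


def predict_biomass(fit: DeltaGAMFit, env: dict, warn_extrapolation: bool = True) -> np.ndarray:
    """Overall relative biomass: p(presence) x exp(log positive biomass)."""
    p = predict_presence(fit, env, warn_extrapolation)
    return p * np.exp(predict_log_biomass(fit, env, warn_extrapolation=warn_extrapolation))


def smooth_curve(
    fit: DeltaGAMFit,
    variable: str,
    grid: np.ndarray,
    beta: np.ndarray | None = None,
) -> np.ndarray:
    """Stage-2 partial prediction curve along ``grid``.

    The other covariate is held at its stage-2 training mean.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty prediction grid")
    names = [t.variable for t in fit.stage2.smooths]
    if variable not in names:
        raise ValueError(f"variable must be one of {names}, got {variable!r}")
    env = {}
    for term in fit.stage2.smooths:
        if term.variable == variable:
            env[term.variable] = grid
        else:
            env[term.variable] = np.full(grid.size, term.x_mean)
    return fit.stage2.predict(env, beta=beta, warn_extrapolation=False)
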