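"""Bayes-theorem fusion of the fitted SDM with expert vote data.

Candidate stage-2 (log positive biomass) coefficient vectors are sampled
from a multivariate normal centred on the fitted coefficients with the
fitted covariance. Each candidate is scored by

    log posterior = log MVN prior(theta)
                  + log multinomial(sensitivity votes | sensitivity bin probs)
                  + log multinomial(directional votes | directional bin probs)

where the bin probabilities come from a Normal(F_mn, F_SD) distribution of
the candidate's future per-cell projections evaluated against percentiles
of its baseline per-cell projections: the {0,20,40,60,80,100} percentiles
split the axis into six intervals mapped symmetrically onto the four
sensitivity bins (outer tails -> very high, centre -> low), and the
{33,67} percentiles split it into the three directional bins. The
maximum-a-posteriori candidate is the "combined" model; the presence/
absence stage is never varied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm

from .delta import DeltaGAMFit, predict_presence
from .vulnerability import DIRECTION_BINS, SENSITIVITY_BINS


@dataclass
class FusionConfig:
    n_candidates: int = 1000
    sens_cutpoints: tuple = (0, 20, 40, 60, 80, 100)
    dir_cutpoints: tuple = (33, 67)
    season_mode: str = "summed"      # "summed" across seasons or "per_season"
    loglik_combine: str = "add"      # "add" (Bayes) or "multiply_logs" (literal)

    def __post_init__(self):
        for cuts, lo, hi in ((self.sens_cutpoints, 0, 100), (self.dir_cutpoints, 0, 100)):
            arr = np.asarray(cuts, dtype=float)
            if np.any(np.diff(arr) <= 0) or arr.min() < lo or arr.max() > hi:
                raise ValueError("percentile cutpoints must be strictly increasing in [0, 100]")
        if self.season_mode not in ("summed", "per_season"):
            raise ValueError("season_mode must be 'summed' or 'per_season'")
        if self.loglik_combine not in ("add", "multiply_logs"):
            raise ValueError("loglik_combine must be 'add' or 'multiply_logs'")


@dataclass
class ExpertVotes:
    """Attribute-summed sensitivity votes (4 bins) and directional votes (3)."""

    species: str
    sensitivity: np.ndarray            # (4,) ints, low..very high
    directional: np.ndarray            # (3,) ints, negative..positive
    per_attribute: np.ndarray | None = None  # (n_attributes, 4)

    def __post_init__(self):
        self.sensitivity = np.asarray(self.sensitivity, dtype=int)
        self.directional = np.asarray(self.directional, dtype=int)
        if self.sensitivity.shape != (4,) or self.directional.shape != (3,):
            raise ValueError("sensitivity needs 4 bins and directional 3")
        if (self.sensitivity < 0).any() or (self.directional < 0).any():
            raise ValueError("vote counts must be nonnegative")
        if self.per_attribute is not None:
            self.per_attribute = np.asarray(self.per_attribute, dtype=int)
            if not np.array_equal(self.per_attribute.sum(axis=0), self.sensitivity):
                raise ValueError("per-attribute votes do not sum to the bin totals")

    @property
    def modal_sensitivity(self) -> str:
        return SENSITIVITY_BINS[int(np.argmax(self.sensitivity))]

    @property
    def modal_direction(self) -> str:
        return DIRECTION_BINS[int(np.argmax(self.directional))]

    def attribute_ranks(self) -> np.ndarray:
        """Modal bin (1-4) of each attribute's votes."""
        if self.per_attribute is None:
            raise ValueError("per-attribute votes were not recorded")
        return np.argmax(self.per_attribute, axis=1) + 1

    def certainty(self, which: str = "sensitivity") -> str:
        """Certainty label from the modal bin's vote share."""
        counts = self.sensitivity if which == "sensitivity" else self.directional
        frac = counts.max() / counts.sum()
        if frac < 0.4:
            return "low"
        if frac < 0.55:
            return "moderate"
        if frac < 0.75:
            return "high"
        return "very high"


def _psd_cholesky(cov: np.ndarray) -> np.ndarray:
    """Cholesky factor after escalating jitter; raises if hopeless."""
    cov = (cov + cov.T) / 2.0
    base = np.trace(cov) / cov.shape[0]
    for eps in (0.0, 1e-10, 1e-8, 1e-6, 1e-4):
        try:
            return np.linalg.cholesky(cov + eps * base * np.eye(cov.shape[0])), eps * base
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("stage-2 covariance is not positive semidefinite")


def sample_candidates(fit: DeltaGAMFit, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` stage-2 coefficient vectors theta ~ MVN(beta, V)."""
    beta, cov = fit.stage2.beta, fit.stage2.cov
    if np.allclose(cov, 0):  # degenerate MVN: every draw is the mean
        return np.tile(beta, (n, 1))
    L, _ = _psd_cholesky(cov)
    z = rng.standard_normal((n, beta.size))
    return beta[None, :] + z @ L.T


def candidate_projections(
    fit: DeltaGAMFit,
    thetas: np.ndarray,
    baseline_env: dict,
    future_env: dict,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell relative biomass for every candidate, both periods.

    Returns arrays of shape (n_candidates, n_cells). The presence
    probability comes from the original stage-1 fit and is identical for
    all candidates; only the exponentiated stage-2 factor varies.
    """
    thetas = np.atleast_2d(thetas)
    out = []
    for env in (baseline_env, future_env):
        X = fit.stage2.design_matrix(env, warn_extrapolation=False)
        p1 = predict_presence(fit, env, warn_extrapolation=False)
        out.append(np.exp(thetas @ X.T) * p1[None, :])
    base, fut = out
    if base.shape[1] != fut.shape[1]:
        raise ValueError("baseline and future environments differ in cell count")
    return base, fut


def sensitivity_bin_probs(
    baseline_cells: np.ndarray,
    f_mn: float,
    f_sd: float,
    cutpoints: tuple = (0, 20, 40, 60, 80, 100),
) -> np.ndarray:
    """(P_low, P_moderate, P_high, P_very_high) under Normal(f_mn, f_sd).

    The six baseline percentiles define seven intervals of the biomass
    axis whose Normal masses map symmetrically onto the four bins:
    beyond the min/max -> very high, outer flanks -> high, inner flanks
    -> moderate, centre -> low. The construction telescopes, so the four
    probabilities sum to 1 exactly.
    """
    baseline_cells = np.asarray(baseline_cells, dtype=float).ravel()
    if baseline_cells.size < 6:
        raise ValueError("need at least 6 baseline cells for the percentile grid")
    if not f_sd > 0:
        raise ValueError("future projection SD must be positive")
    p0, p20, p40, p60, p80, p100 = (
        norm.cdf(np.percentile(baseline_cells, cutpoints), loc=f_mn, scale=f_sd)
    )
    p_vh = p0 + (1.0 - p100)
    p_high = (p20 - p0) + (p100 - p80)
    p_mod = (p40 - p20) + (p80 - p60)
    p_low = p60 - p40
    return np.array([p_low, p_mod, p_high, p_vh])


def directional_bin_probs(
    baseline_cells: np.ndarray,
    f_mn: float,
    f_sd: float,
    cutpoints: tuple = (33, 67),
) -> np.ndarray:
    """(P_negative, P_neutral, P_positive): Normal mass below the 33rd
    baseline percentile, between the 33rd and 67th, and above the 67th."""
    baseline_cells = np.asarray(baseline_cells, dtype=float).ravel()
    if baseline_cells.size < 3:
        raise ValueError("need at least 3 baseline cells")
    if not f_sd > 0:
        raise ValueError("future projection SD must be positive")
    c33, c67 = norm.cdf(np.percentile(baseline_cells, cutpoints), loc=f_mn, scale=f_sd)
    return np.array([c33, c67 - c33, 1.0 - c67])


def multinomial_logpmf(counts: np.ndarray, probs: np.ndarray) -> float:
    """Log multinomial pmf; -inf when a bin with votes has zero probability."""
    counts = np.asarray(counts, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if counts.shape != probs.shape:
        raise ValueError("counts and probabilities differ in length")
    bad = (probs <= 0) & (counts > 0)
    if bad.any():
        return -np.inf
    with np.errstate(divide="ignore"):
        logp = np.where(counts > 0, counts * np.log(np.maximum(probs, 1e-300)), 0.0)
    return float(gammaln(counts.sum() + 1) - gammaln(counts + 1).sum() + logp.sum())


def vote_loglik(votes: ExpertVotes, sens_probs: np.ndarray, dir_probs: np.ndarray
                ) -> tuple[float, float]:
    """Log probabilities of the sensitivity and directional vote counts."""
    return (
        multinomial_logpmf(votes.sensitivity, sens_probs),
        multinomial_logpmf(votes.directional, dir_probs),
    )


def candidate_logprior(thetas: np.ndarray, fit: DeltaGAMFit) -> np.ndarray:
    """MVN log density of each candidate at the fitted mean/covariance."""
    thetas = np.atleast_2d(thetas)
    beta, cov = fit.stage2.beta, fit.stage2.cov
    L, jitter = _psd_cholesky(cov)
    diff = thetas - beta[None, :]
    sol = np.linalg.solve(L, diff.T)
    quad = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    p = beta.size
    return -0.5 * (quad + logdet + p * np.log(2 * np.pi))


def score_candidates(
    fit: DeltaGAMFit,
    thetas: np.ndarray,
    votes: ExpertVotes,
    baseline_env: dict,
    future_env: dict,
    config: FusionConfig,
) -> pd.DataFrame:
    """Score every candidate for one seasonal fit against the votes.

    Returns a table with per-candidate F_mn, F_SD, bin probabilities, log
    prior, vote log likelihoods, and the log posterior (prior + both
    likelihood components in log space).
    """
    base, fut = candidate_projections(fit, thetas, baseline_env, future_env)
    n = thetas.shape[0]
    f_mn = fut.mean(axis=1)
    f_sd = fut.std(axis=1, ddof=0)
    rows = np.empty((n, 12))
    for i in range(n):
        sp = sensitivity_bin_probs(base[i], f_mn[i], f_sd[i], config.sens_cutpoints)
        dp = directional_bin_probs(base[i], f_mn[i], f_sd[i], config.dir_cutpoints)
        ls, ld = vote_loglik(votes, sp, dp)
        rows[i] = np.r_[sp, dp, ls, ld, base[i].mean(), base[i].std(ddof=0), 0.0]
    log_prior = candidate_logprior(thetas, fit)
    tab = pd.DataFrame(
        rows[:, :10],
        columns=["p_low", "p_moderate", "p_high", "p_very_high",
                 "p_negative", "p_neutral", "p_positive",
                 "log_lik_sens", "log_lik_dir", "b_mn"],
    )
    tab.insert(0, "candidate", np.arange(n))
    tab["f_mn"] = f_mn
    tab["f_sd"] = f_sd
    tab["log_prior"] = log_prior
    if config.loglik_combine == "add":
        tab["log_posterior"] = tab["log_prior"] + tab["log_lik_sens"] + tab["log_lik_dir"]
    else:  # literal reading of "multiplying the logged probabilities"
        tab["log_posterior"] = (
            tab["log_prior"] * (tab["log_lik_sens"] + tab["log_lik_dir"])
        )
    return tab


def posterior_select(table: pd.DataFrame) -> int:
    """Index of the MAP candidate; ties broken by the lowest index."""
    lp = table["log_posterior"].to_numpy()
    if not np.isfinite(lp).any():
        raise ValueError("no candidate has a finite log posterior")
    return int(np.flatnonzero(lp == np.nanmax(lp))[0])


@dataclass
class FusionResult:
    species: str
    tables: dict            # season -> per-candidate score table
    thetas: dict            # season -> (n, p) candidate draws
    map_index: dict         # season -> selected candidate index
    map_theta: dict         # season -> MAP coefficient vector
    combined_table: pd.DataFrame | None = None


def fuse_species(
    fits: dict[str, DeltaGAMFit],
    votes: ExpertVotes,
    envs: dict[str, tuple[dict, dict]],
    config: FusionConfig,
    rng: np.random.Generator,
) -> FusionResult:
    """Run the fusion for one species across its seasonal fits.

    ``envs[season] = (baseline_env, future_env)``. Under the default
    ``season_mode="summed"`` the i-th draws of each season are paired,
    seasonal vote log likelihoods and log priors are summed, and a single
    joint MAP index is selected; ``"per_season"`` selects independently.
    """
    tables, thetas = {}, {}
    for season, fit in fits.items():
        th = sample_candidates(fit, config.n_candidates, rng)
        thetas[season] = th
        tables[season] = score_candidates(
            fit, th, votes, envs[season][0], envs[season][1], config
        )
    if config.season_mode == "summed":
        combined = pd.DataFrame({"candidate": np.arange(config.n_candidates)})
        for col in ("log_prior", "log_lik_sens", "log_lik_dir", "log_posterior"):
            combined[col] = sum(t[col].to_numpy() for t in tables.values())
        idx = posterior_select(combined)
        map_index = {season: idx for season in fits}
    else:
        combined = None
        map_index = {season: posterior_select(t) for season, t in tables.items()}
    map_theta = {s: thetas[s][map_index[s]] for s in fits}
    return FusionResult(
        species=votes.species, tables=tables, thetas=thetas,
        map_index=map_index, map_theta=map_theta, combined_table=combined,
    )


def sdm_certainty_bin(auc_value: float) -> str:
    """S3-style SDM certainty: AUC in [0.7, 1.0] split into four equal bins."""
    edges = np.linspace(0.7, 1.0, 5)
    idx = int(np.clip(np.searchsorted(edges, auc_value, side="right") - 1, 0, 3))
    return SENSITIVITY_BINS[idx]  # same low..very high labels


def fused_evaluate(
    fit: DeltaGAMFit,
    theta_map: np.ndarray,
    test: pd.DataFrame,
) -> dict:
    """Paired validation statistics: SDM-only vs combined (MAP) model.

    Both models are evaluated on the same held-out tows; the stage-1
    presence model is shared, so AUC is identical by construction and the
    comparison concentrates on the Taylor statistics of overall biomass.
    """
    from .validation import auc, taylor_stats

    if len(test) == 0:
        raise ValueError("empty test set")
    env = {"sst": test["sst"].to_numpy(), "depth": test["depth_m"].to_numpy()}
    p1 = predict_presence(fit, env, warn_extrapolation=False)
    pred_sdm = p1 * np.exp(fit.stage2.predict(env, warn_extrapolation=False))
    pred_map = p1 * np.exp(fit.stage2.predict(env, beta=theta_map, warn_extrapolation=False))
    obs = test["biomass_kg"].to_numpy()
    labels = test["presence"].to_numpy()
    out = {"auc_sdm": auc(labels, p1), "auc_combined": auc(labels, p1)}
    for name, pred in (("sdm", pred_sdm), ("combined", pred_map)):
        st = taylor_stats(obs, pred)
        out[f"r_{name}"] = st.r
        out[f"crmse_norm_{name}"] = st.crmse_norm
        out[f"sd_ratio_{name}"] = st.sd_ratio
    for stat in ("r", "crmse_norm", "sd_ratio"):
        out[f"d_{stat}"] = out[f"{stat}_combined"] - out[f"{stat}_sdm"]
    return out
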