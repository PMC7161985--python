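"""Sensitivity and directional-effect ranking of SDM projections, and
comparison against expert vulnerability-assessment ranks.

The sensitivity weight of a species is

    SensWeight = sum_k |baseline_k - future_k| / sum_k future_k

over the m grid cells of the domain, averaged across fall and spring, then
converted to one of four ranks by its percentile among all species.
Directional effect is the season-averaged domain percent change thresholded
at +/-25%. A random-forest classifier probes which expert sensitivity
attributes drive match/mismatch between the two ranking systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

SENSITIVITY_BINS = ("low", "moderate", "high", "very high")
DIRECTION_BINS = ("negative", "neutral", "positive")


def sens_weight(baseline, future) -> float:
    """Sum of absolute per-cell changes scaled by total future biomass."""
    baseline = np.asarray(baseline, dtype=float).ravel()
    future = np.asarray(future, dtype=float).ravel()
    if baseline.shape != future.shape:
        raise ValueError("baseline and future must have the same cell count")
    tot = future.sum()
    if tot <= 0:
        raise ValueError("total future biomass is zero; SensWeight undefined")
    return float(np.abs(baseline - future).sum() / tot)


def percentile_of_rank(weights: np.ndarray) -> np.ndarray:
    """(rank-1)/(N-1)*100 percentile; ties share the minimum percentile."""
    weights = np.asarray(weights, dtype=float)
    n = weights.size
    ranks = rankdata(weights, method="min")
    return (ranks - 1) / (n - 1) * 100.0


def _sens_bin(p: float) -> str:
    if p < 25:
        return "low"
    if p < 50:
        return "moderate"
    if p < 75:
        return "high"
    return "very high"


def rank_sensitivity(weights: pd.Series | dict) -> pd.DataFrame:
    """Map per-species mean SensWeights to percentile-based sensitivity ranks.

    Quartile cutpoints: 0-25% low, 25-50% moderate, 50-75% high,
    75-100% very high.
    """
    w = pd.Series(weights, dtype=float)
    if len(w) < 4:
        raise ValueError("percentile ranking needs at least 4 species")
    pct = percentile_of_rank(w.to_numpy())
    return pd.DataFrame(
        {
            "species": w.index,
            "sens_weight": w.to_numpy(),
            "percentile": pct,
            "rank": [_sens_bin(p) for p in pct],
        }
    ).set_index("species")


def classify_direction(mean_pct_change: float) -> str:
    """Directional effect from the season-averaged percent change.

    Below -25% is negative, above +25% positive; the closed band
    [-25, 25] (boundaries included) is neutral.
    """
    x = float(mean_pct_change)
    if not np.isfinite(x):
        raise ValueError("percent change must be finite")
    if x < -25:
        return "negative"
    if x > 25:
        return "positive"
    return "neutral"


@dataclass
class RankComparison:
    table: pd.DataFrame
    sensitivity_confusion: pd.DataFrame  # 4x4, SDM rank x expert rank
    direction_confusion: pd.DataFrame    # 3x3
    n_sensitivity_matches: int
    n_direction_matches: int
    excluded_species: list = field(default_factory=list)


def compare_ranks(sdm: pd.DataFrame, neva: pd.DataFrame) -> RankComparison:
    """Per-species match flags and confusion matrices.

    ``sdm`` needs columns sensitivity_rank, direction; ``neva`` the same
    (expert overall ranks); both indexed by species. Species present in
    only one source are excluded and reported.
    """
    common = sdm.index.intersection(neva.index)
    if len(common) == 0:
        raise ValueError("no species shared between SDM and expert tables")
    excluded = sorted(set(sdm.index).symmetric_difference(neva.index))
    tab = pd.DataFrame(
        {
            "sdm_rank": sdm.loc[common, "sensitivity_rank"],
            "neva_rank": neva.loc[common, "sensitivity_rank"],
            "sdm_direction": sdm.loc[common, "direction"],
            "neva_direction": neva.loc[common, "direction"],
        }
    )
    tab["match_sensitivity"] = tab["sdm_rank"] == tab["neva_rank"]
    tab["match_direction"] = tab["sdm_direction"] == tab["neva_direction"]
    sens_conf = (
        pd.crosstab(tab["sdm_rank"], tab["neva_rank"])
        .reindex(index=SENSITIVITY_BINS, columns=SENSITIVITY_BINS, fill_value=0)
    )
    dir_conf = (
        pd.crosstab(tab["sdm_direction"], tab["neva_direction"])
        .reindex(index=DIRECTION_BINS, columns=DIRECTION_BINS, fill_value=0)
    )
    return RankComparison(
        table=tab,
        sensitivity_confusion=sens_conf,
        direction_confusion=dir_conf,
        n_sensitivity_matches=int(tab["match_sensitivity"].sum()),
        n_direction_matches=int(tab["match_direction"].sum()),
        excluded_species=excluded,
    )


@dataclass
class MatchClassifierReport:
    oob_error: float
    importance: pd.DataFrame        # per attribute, permutation importance
    marginal_effects: pd.DataFrame  # attribute, level, p_mismatch
    model: object


def fit_match_classifier(
    attribute_ranks: pd.DataFrame,
    match_labels: pd.Series,
    seed: int = 0,
    n_trees: int = 500,
    min_species: int = 20,
) -> MatchClassifierReport:
    """Random forest classifying rank match/mismatch from the 12 expert
    sensitivity-attribute ranks (ordinal, encoded 1-4).

    Reports the out-of-bag error, permutation importance per attribute,
    and marginal probability-of-mismatch curves per attribute level.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.inspection import permutation_importance

    X = attribute_ranks.astype(float)
    y = np.asarray(match_labels).astype(bool)
    if len(X) < min_species:
        raise ValueError(f"need >= {min_species} species, got {len(X)}")
    if y.all() or (~y).all():
        raise ValueError("both match and mismatch labels are required")
    rf = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, random_state=seed, n_jobs=1
    )
    rf.fit(X.to_numpy(), y)
    oob_error = 1.0 - rf.oob_score_
    perm = permutation_importance(
        rf, X.to_numpy(), y, n_repeats=20, random_state=seed, n_jobs=1
    )
    importance = pd.DataFrame(
        {"attribute": X.columns, "importance": perm.importances_mean,
         "importance_sd": perm.importances_std}
    ).sort_values("importance", ascending=False, kind="stable").reset_index(drop=True)

    # marginal ("partial dependence") probability of a mismatch per level
    mismatch_col = list(rf.classes_).index(False)
    rows = []
    for attr in X.columns:
        for level in (1, 2, 3, 4):
            Xm = X.copy()
            Xm[attr] = level
            p_miss = rf.predict_proba(Xm.to_numpy())[:, mismatch_col].mean()
            rows.append({"attribute": attr, "level": level, "p_mismatch": p_miss})
    marginal = pd.DataFrame(rows)
    return MatchClassifierReport(
        oob_error=float(oob_error), importance=importance,
        marginal_effects=marginal, model=rf,
    )
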