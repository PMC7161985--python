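"""Classification skill (AUC) and Taylor-diagram statistics.

AUC is computed in its Mann-Whitney form: the probability that a randomly
chosen presence receives a higher score than a randomly chosen absence,
with ties counted one half. Taylor statistics summarise calibration and
variability skill: Pearson correlation, centered RMSE, and the ratio of
prediction to observation standard deviations; standard deviations are
population (divide-by-n) by default, as in the Taylor-diagram literature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


def auc(labels, scores) -> float:
    """Area under the ROC curve, Mann-Whitney form (ties count 1/2)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have the same length")
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both presences and absences")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class TaylorStats:
    r: float          # Pearson correlation
    crmse: float      # centered RMSE, response units
    crmse_norm: float  # centered RMSE / SD(obs)
    sd_obs: float
    sd_pred: float
    sd_ratio: float   # SD(pred) / SD(obs)

    def as_dict(self) -> dict:
        return {
            "r": self.r, "crmse": self.crmse, "crmse_norm": self.crmse_norm,
            "sd_obs": self.sd_obs, "sd_pred": self.sd_pred, "sd_ratio": self.sd_ratio,
        }


def taylor_stats(obs, pred, ddof: int = 0) -> TaylorStats:
    """Taylor-diagram statistics of predictions against observations.

    Satisfies the law-of-cosines identity
    ``crmse**2 = sd_pred**2 + sd_obs**2 - 2*sd_pred*sd_obs*r``.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.size < 3:
        raise ValueError("obs and pred must be equal-length with at least 3 points")
    sd_obs = float(np.std(obs, ddof=ddof))
    sd_pred = float(np.std(pred, ddof=ddof))
    if sd_obs == 0:
        raise ValueError("observations have zero variance")
    oc = obs - obs.mean()
    pc = pred - pred.mean()
    denom = np.sqrt(np.sum(oc**2) * np.sum(pc**2))
    r = float(np.sum(oc * pc) / denom) if denom > 0 else 0.0
    n = obs.size - ddof
    crmse = float(np.sqrt(np.sum((pc - oc) ** 2) / n))
    return TaylorStats(
        r=r,
        crmse=crmse,
        crmse_norm=crmse / sd_obs,
        sd_obs=sd_obs,
        sd_pred=sd_pred,
        sd_ratio=sd_pred / sd_obs,
    )


def taylor_diagram(stats: dict[str, TaylorStats], path=None):
    """Polar Taylor diagram of normalized statistics, one point per label."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(111, projection="polar")
    ax.set_thetamin(0)
    ax.set_thetamax(90)
    for label, st in stats.items():
        theta = np.arccos(np.clip(st.r, -1, 1))
        ax.plot(theta, st.sd_ratio, "o", label=label)
    ax.plot(0, 1.0, "k*", markersize=12, label="reference")
    ax.set_rmax(max(1.5, max((s.sd_ratio for s in stats.values()), default=1) * 1.1))
    ax.set_xlabel("normalized SD (radius), correlation (angle)")
    ax.legend(fontsize=7, loc="upper right", bbox_to_anchor=(1.3, 1.1))
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
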