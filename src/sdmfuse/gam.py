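"""Penalized-spline generalized additive models.

Fits models of the form

    g(E[y]) = intercept + f_1(x_1) + f_2(x_2) + ...

where each f_j is a penalized cubic B-spline smooth (see
:mod:`sdmfuse.splines`). Supported families are binomial with logit link
(presence/absence) and Gaussian with identity link (log positive biomass).
Smoothing parameters are chosen by REML (Laplace-approximate for the
binomial family) or GCV; with shrinkage enabled each smooth carries a second
penalty on the null space of its wiggliness penalty, so REML can shrink an
uninformative term to effectively zero degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit

from .splines import SmoothTerm

_LOG_LAMBDA_BOUNDS = (-10.0, 28.0)


class DegenerateModelError(ValueError):
    """Raised when a stage cannot be fitted (e.g. single-class response)."""


@dataclass
class StageFit:
    """One fitted stage of a delta GAM.

    Holds everything needed to rebuild a design row for any covariate
    combination: the coefficient vector ``beta``, its Bayesian posterior
    covariance ``cov``, the link, the residual ``scale`` (identity stage),
    per-smooth smoothing parameters and effective degrees of freedom, and
    the smooth-term basis descriptors.
    """

    link: str  # "logit" or "identity"
    beta: np.ndarray
    cov: np.ndarray
    scale: float
    smooths: list[SmoothTerm]
    slices: list[slice]
    log_lambda: np.ndarray
    edf: dict[str, float]
    criterion: str
    n_obs: int
    deviance: float = np.nan
    y_mean: float = field(default=np.nan)

    def design_matrix(self, env: dict[str, np.ndarray], warn_extrapolation: bool = True) -> np.ndarray:
        blocks = [
            term.design(np.asarray(env[term.variable], dtype=float).ravel(), warn_extrapolation)
            for term in self.smooths
        ]
        return np.column_stack([np.ones(blocks[0].shape[0])] + blocks)

    def linear_predictor(
        self,
        env: dict[str, np.ndarray],
        beta: np.ndarray | None = None,
        warn_extrapolation: bool = True,
    ) -> np.ndarray:
        b = self.beta if beta is None else np.asarray(beta)
        return self.design_matrix(env, warn_extrapolation) @ b

    def predict(self, env: dict[str, np.ndarray], beta: np.ndarray | None = None,
                warn_extrapolation: bool = True) -> np.ndarray:
        eta = self.linear_predictor(env, beta, warn_extrapolation)
        return expit(eta) if self.link == "logit" else eta

    def to_dict(self) -> dict:
        return {
            "link": self.link,
            "beta": self.beta.tolist(),
            "cov": self.cov.tolist(),
            "scale": self.scale,
            "smooths": [t.to_dict() for t in self.smooths],
            "slices": [[s.start, s.stop] for s in self.slices],
            "log_lambda": self.log_lambda.tolist(),
            "edf": self.edf,
            "criterion": self.criterion,
            "n_obs": self.n_obs,
            "deviance": self.deviance,
            "y_mean": self.y_mean,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StageFit":
        return cls(
            link=d["link"],
            beta=np.asarray(d["beta"]),
            cov=np.asarray(d["cov"]),
            scale=d["scale"],
            smooths=[SmoothTerm.from_dict(t) for t in d["smooths"]],
            slices=[slice(a, b) for a, b in d["slices"]],
            log_lambda=np.asarray(d["log_lambda"]),
            edf=d["edf"],
            criterion=d["criterion"],
            n_obs=d["n_obs"],
            deviance=d.get("deviance", np.nan),
            y_mean=d.get("y_mean", np.nan),
        )


def _penalty_blocks(smooths, slices, p):
    """One penalty matrix per smooth, embedded in R^pxp.

    With shrinkage, the null (linear) space of the wiggliness penalty is
    folded in under the same smoothing parameter at one tenth of the
    smallest strictly positive penalty eigenvalue — small enough not to
    bias ordinary smoothing, while a very large smoothing parameter can
    still drive the whole term to zero.
    """
    blocks = []
    for term, sl in zip(smooths, slices):
        S_term = term.S
        if term.shrinkage:
            ev = np.linalg.eigvalsh(term.S)
            eps = 0.1 * ev[ev > 1e-10 * ev.max()].min()
            S_term = S_term + eps * term.S_null
        Sw = np.zeros((p, p))
        Sw[sl, sl] = S_term
        blocks.append((sl, Sw))
    return blocks


def _total_penalty(blocks, rho):
    p = blocks[0][1].shape[0]
    S = np.zeros((p, p))
    for i, (_sl, Sw) in enumerate(blocks):
        S += np.exp(rho[i]) * Sw
    return S


def _logdet_penalty(blocks, rho):
    """log pseudo-determinant of the total penalty (block diagonal by smooth)."""
    total = 0.0
    for i, (sl, Sw) in enumerate(blocks):
        Ssub = np.exp(rho[i]) * Sw[sl, sl]
        ev = np.linalg.eigvalsh(Ssub)
        total += np.sum(np.log(ev[ev > 1e-12 * ev.max()]))
    return total


def _pirls_binomial(X, y, S, max_iter=100, tol=1e-9):
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log((y.mean() + 1e-6) / (1 - y.mean() + 1e-6))
    dev_old = np.inf
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        XtW = X.T * w
        A = XtW @ X + S
        beta_new = np.linalg.solve(A, XtW @ z)
        eta = X @ beta_new
        mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
        dev = -2 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))
        pen_dev = dev + beta_new @ S @ beta_new
        beta = beta_new
        if abs(pen_dev - dev_old) < tol * (abs(pen_dev) + 0.1):
            dev_old = pen_dev
            break
        dev_old = pen_dev
    w = np.clip(mu * (1 - mu), 1e-10, None)
    return beta, dev, w


def _fit_given_rho(X, y, blocks, rho, family):
    S = _total_penalty(blocks, rho)
    n, p = X.shape
    if family == "gaussian":
        A = X.T @ X + S
        beta = np.linalg.solve(A, X.T @ y)
        resid = y - X @ beta
        dev = float(resid @ resid)
        w = np.ones(n)
    else:
        beta, dev, w = _pirls_binomial(X, y, S)
        A = (X.T * w) @ X + S
    return beta, dev, w, A, S


def _reml_score(X, y, blocks, rho, family):
    beta, dev, w, A, S = _fit_given_rho(X, y, blocks, rho, family)
    n, p = X.shape
    M = 1  # penalty null-space dimension: only the intercept is unpenalized
    sign, logdet_A = np.linalg.slogdet(A)
    logdet_S = _logdet_penalty(blocks, rho)
    if family == "gaussian":
        Dp = dev + beta @ S @ beta
        phi = Dp / (n - M)
        score = (
            Dp / (2 * phi)
            + (n - M) / 2 * np.log(2 * np.pi * phi)
            + 0.5 * logdet_A
            - 0.5 * logdet_S
        )
    else:
        # Laplace-approximate REML: penalized log-likelihood + determinant terms
        pen_ll = -dev / 2 - beta @ S @ beta / 2
        score = -pen_ll + 0.5 * logdet_A - 0.5 * logdet_S
    return score


def _gcv_score(X, y, blocks, rho, family):
    beta, dev, w, A, S = _fit_given_rho(X, y, blocks, rho, family)
    n = X.shape[0]
    XtWX = (X.T * w) @ X
    edf = float(np.trace(np.linalg.solve(A, XtWX)))
    return n * dev / (n - edf) ** 2


def fit_gam(
    env: dict[str, np.ndarray],
    y: np.ndarray,
    family: str,
    smooths: list[SmoothTerm],
    criterion: str = "reml",
) -> StageFit:
    """Fit a penalized-spline GAM of ``y`` on the given smooth terms.

    Parameters
    ----------
    env : mapping of covariate name -> values (one entry per smooth term).
    y : response; binary in {0,1} for ``family="binomial"``.
    family : "binomial" (logit link) or "gaussian" (identity link).
    smooths : smooth-term specifications; bases are fitted to the data here.
    criterion : "reml" (default) or "gcv" smoothing-parameter selection.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if family == "binomial" and (y.min() == y.max()):
        raise DegenerateModelError(
            "presence/absence response has a single class; stage-1 model is degenerate"
        )
    if family not in ("binomial", "gaussian"):
        raise ValueError(f"unknown family {family!r}")
    if criterion not in ("reml", "gcv"):
        raise ValueError(f"unknown criterion {criterion!r}")

    design_blocks = []
    slices = []
    start = 1
    for term in smooths:
        x = np.asarray(env[term.variable], dtype=float).ravel()
        if x.size != n:
            raise ValueError(f"covariate '{term.variable}' length mismatch")
        Xb = term.build(x)
        design_blocks.append(Xb)
        slices.append(slice(start, start + term.n_coef))
        start += term.n_coef
    X = np.column_stack([np.ones(n)] + design_blocks)
    p = X.shape[1]
    blocks = _penalty_blocks(smooths, slices, p)
    n_rho = len(smooths)

    score_fn = _reml_score if criterion == "reml" else _gcv_score
    obj = lambda rho: score_fn(X, y, blocks, rho, family)
    # multi-start: the smoothing-criterion surface can hold the optimizer in
    # an under-smoothed basin, so also start from a heavily penalized model
    best = None
    for start in (np.zeros(n_rho), np.full(n_rho, 14.0)):
        res = optimize.minimize(
            obj,
            x0=start,
            method="Powell",
            bounds=[_LOG_LAMBDA_BOUNDS] * n_rho,
            options={"maxiter": 40, "xtol": 1e-3, "ftol": 1e-5},
        )
        if best is None or res.fun < best.fun:
            best = res
    rho = np.clip(best.x, *_LOG_LAMBDA_BOUNDS)

    beta, dev, w, A, S = _fit_given_rho(X, y, blocks, rho, family)
    XtWX = (X.T * w) @ X
    F = np.linalg.solve(A, XtWX)
    edf_diag = np.diag(F)
    edf = {"total": float(np.trace(F))}
    for term, sl in zip(smooths, slices):
        edf[term.variable] = float(edf_diag[sl].sum())
    if family == "gaussian":
        scale = dev / max(n - edf["total"], 1.0)
    else:
        scale = 1.0
    cov = np.linalg.inv(A) * scale
    cov = (cov + cov.T) / 2.0
    return StageFit(
        link="logit" if family == "binomial" else "identity",
        beta=beta,
        cov=cov,
        scale=float(scale),
        smooths=smooths,
        slices=slices,
        log_lambda=rho,
        edf=edf,
        criterion=criterion,
        n_obs=n,
        deviance=float(dev),
        y_mean=float(y.mean()),
    )
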