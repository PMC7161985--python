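"""Penalized cubic B-spline smooth terms.

Each smooth term is a cubic B-spline basis with interior knots at covariate
quantiles, an exact integrated-squared-second-derivative wiggliness penalty,
a sum-to-zero identifiability constraint, and an optional null-space
("double") penalty so that the whole term can be shrunk out of the model,
not just its wiggly part.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

DEGREE = 3  # cubic


class ExtrapolationWarning(UserWarning):
    """Covariate values outside the training range were clamped."""


def _knot_vector(x: np.ndarray, k: int) -> np.ndarray:
    """Clamped knot vector giving ``k`` cubic B-spline basis functions.

    Interior knots sit at quantiles of the observed covariate, boundary
    knots at the observed extremes (repeated DEGREE+1 times).
    """
    if k < 4:
        raise ValueError(f"basis dimension k must be >= 4, got {k}")
    n_interior = k - DEGREE - 1
    lo, hi = float(np.min(x)), float(np.max(x))
    if not hi > lo:
        raise ValueError("covariate is constant; cannot build a spline basis")
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.quantile(x, qs)
    # quantile ties collapse basis functions; nudge onto a strict grid
    interior = np.maximum.accumulate(interior)
    if np.any(np.diff(np.r_[lo, interior, hi]) <= 0):
        interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    return np.r_[[lo] * (DEGREE + 1), interior, [hi] * (DEGREE + 1)]


def _raw_design(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    lo, hi = t[0], t[-1]
    xc = np.clip(x, lo, hi)
    X = BSpline.design_matrix(xc, t, DEGREE, extrapolate=False).toarray()
    return X


def _second_derivative_penalty(t: np.ndarray, k: int) -> np.ndarray:
    """S with S_ij = integral of B_i'' B_j'' over the basis support.

    B'' of a cubic spline is piecewise linear, so 2-point Gauss-Legendre
    per knot span integrates the product exactly.
    """
    spans = np.unique(t)
    # Gauss-Legendre nodes/weights on [-1, 1]
    g = 1.0 / np.sqrt(3.0)
    nodes, wts = np.array([-g, g]), np.array([1.0, 1.0])
    S = np.zeros((k, k))
    d2cols = []
    for j in range(k):
        c = np.zeros(k)
        c[j] = 1.0
        d2cols.append(BSpline(t, c, DEGREE).derivative(2))
    for a, b in zip(spans[:-1], spans[1:]):
        mid, half = (a + b) / 2.0, (b - a) / 2.0
        xs = mid + half * nodes
        D = np.column_stack([d2(xs) for d2 in d2cols])
        S += half * (D * wts[:, None]).T @ D
    return S


@dataclass
class SmoothTerm:
    """A fitted-basis smooth of one covariate."""

    variable: str
    k: int = 10
    shrinkage: bool = True
    knots: np.ndarray = field(default=None, repr=False)
    Z: np.ndarray = field(default=None, repr=False)  # constraint transform
    S: np.ndarray = field(default=None, repr=False)  # wiggliness penalty
    S_null: np.ndarray = field(default=None, repr=False)
    x_mean: float = None
    x_min: float = None
    x_max: float = None

    @property
    def n_coef(self) -> int:
        return self.k - 1

    def build(self, x: np.ndarray) -> np.ndarray:
        """Fit the basis to training values and return the design block."""
        x = np.asarray(x, dtype=float)
        self.knots = _knot_vector(x, self.k)
        self.x_mean = float(np.mean(x))
        self.x_min, self.x_max = float(np.min(x)), float(np.max(x))
        X = _raw_design(x, self.knots)
        c = X.mean(axis=0)
        # null space of the sum-to-zero constraint via a Householder rotation
        Q, _ = np.linalg.qr(c[:, None], mode="complete")
        self.Z = Q[:, 1:]
        S0 = _second_derivative_penalty(self.knots, self.k)
        S = self.Z.T @ S0 @ self.Z
        S = (S + S.T) / 2.0
        # rescale so smoothing parameters are comparable across terms
        S /= np.linalg.norm(S, ord=2)
        self.S = S
        evals, evecs = np.linalg.eigh(S)
        null = evecs[:, evals < 1e-10 * evals.max()]
        self.S_null = null @ null.T
        return X @ self.Z

    def design(self, x: np.ndarray, warn_extrapolation: bool = True) -> np.ndarray:
        """Design block for new covariate values.

        Values outside the training range are clamped to the boundary
        (constant extrapolation) and flagged.
        """
        x = np.asarray(x, dtype=float)
        outside = (x < self.x_min) | (x > self.x_max)
        if warn_extrapolation and np.any(outside):
            warnings.warn(
                f"{int(outside.sum())}/{x.size} values of '{self.variable}' lie "
                f"outside the training range [{self.x_min:.3g}, {self.x_max:.3g}]; "
                "predictions there are held at the boundary",
                ExtrapolationWarning,
                stacklevel=2,
            )
        return _raw_design(x, self.knots) @ self.Z

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "k": self.k,
            "shrinkage": self.shrinkage,
            "knots": self.knots.tolist(),
            "Z": self.Z.tolist(),
            "x_mean": self.x_mean,
            "x_min": self.x_min,
            "x_max": self.x_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SmoothTerm":
        term = cls(variable=d["variable"], k=d["k"], shrinkage=d["shrinkage"])
        term.knots = np.asarray(d["knots"])
        term.Z = np.asarray(d["Z"])
        term.x_mean = d["x_mean"]
        term.x_min = d["x_min"]
        term.x_max = d["x_max"]
        return term
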