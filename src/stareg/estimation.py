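"""EM + PAVA estimation of the four-group mixture from paired p-values.

The unknowns are the four prior weights (xi00, xi01, xi10, xi11) and the two
non-null p-value densities f1, f2, constrained to be non-increasing on
[0, 1].  Treating the per-study significance indicators as latent, EM
alternates

* E-step: posterior responsibilities of the four joint states per gene,
* M-step: xi_kl as the responsibility means; f1 and f2 as weighted
  Grenander estimators — the non-increasing density that maximizes the
  responsibility-weighted log-likelihood, computed as the left derivative
  of the least concave majorant of the weighted empirical CDF via the
  pool-adjacent-violators algorithm (PAVA) on the CDF chord slopes.

Both M-step blocks are exact maximizers of the expected complete-data
log-likelihood, so the marginal log-likelihood never decreases.  The fit
has no tuning parameters; the config only exposes numerical tolerances,
and nothing in here draws random numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import isotonic_regression

from .model_core import (
    DENSITY_FLOOR,
    FourGroupModel,
    MixtureParams,
    MonotoneDensity,
    PairedPValues,
    evaluate_density,
)

__all__ = ["EMConfig", "EMTrace", "PosteriorWeights", "pava_isotonic",
           "grenander_density", "em_fit"]

#: mixture weights below this are floored and the vector renormalized,
#: so no responsibility ever hits 0/0
_XI_FLOOR = 1e-8


@dataclass(frozen=True)
class EMConfig:
    """Numerical knobs of the EM fit (no statistical tuning parameters)."""

    tol: float = 1e-6          # relative log-likelihood change for convergence
    max_iter: int = 200
    init: str = "default"
    floor: float = DENSITY_FLOOR

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")


@dataclass(frozen=True)
class EMTrace:
    loglik_per_iter: np.ndarray
    n_iter: int
    converged: bool


@dataclass(frozen=True)
class PosteriorWeights:
    """m x 4 posterior state probabilities, columns in order 00, 01, 10, 11."""

    gamma: np.ndarray

    @property
    def w1(self) -> np.ndarray:
        """Posterior probability that study 1 is non-null: gamma(1,0)+gamma(1,1)."""
        return self.gamma[:, 2] + self.gamma[:, 3]

    @property
    def w2(self) -> np.ndarray:
        """Posterior probability that study 2 is non-null: gamma(0,1)+gamma(1,1)."""
        return self.gamma[:, 1] + self.gamma[:, 3]


def pava_isotonic(values, weights=None, direction: str = "non-increasing") -> np.ndarray:
    """Weighted least-squares monotone fit (pool-adjacent-violators).

    Returns the minimizer of sum_k w_k (x_k - v_k)^2 over monotone x,
    block-constant where adjacent violators were pooled.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) == 0:
        raise ValueError("values must be a non-empty 1-d sequence")
    if weights is None:
        weights = np.ones_like(values)
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != values.shape:
            raise ValueError("weights must match values in length")
        if np.any(weights <= 0):
            raise ValueError("weights must be positive")
    if direction not in ("non-increasing", "non-decreasing"):
        raise ValueError(f"unknown direction {direction!r}")
    res = isotonic_regression(values, weights=weights,
                              increasing=(direction == "non-decreasing"))
    return np.asarray(res.x)


def grenander_density(pvalues, weights=None) -> MonotoneDensity:
    """Weighted Grenander estimator: the non-increasing density MLE.

    Equals the left derivative of the least concave majorant (LCM) of the
    weighted empirical CDF of the p-values on [0, 1], with the tail
    completed to a knot at 1 (height 0 beyond the largest observation).
    Computed by non-increasing PAVA on the CDF chord slopes weighted by the
    interval widths.  Ties are pooled at their shared knot.
    """
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.ndim != 1 or len(pvalues) == 0:
        raise ValueError("pvalues must be a non-empty 1-d sequence")
    if np.any((pvalues < 0) | (pvalues > 1)):
        raise ValueError("pvalues must lie in [0, 1]")
    if weights is None:
        weights = np.ones_like(pvalues)
    else:
        weights = np.asarray(weights, dtype=float)
        if np.any(weights < 0):
            raise ValueError("weights must be non-negative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("all weights are zero: empty mixture component")

    order = np.argsort(pvalues, kind="stable")
    x = pvalues[order]
    w = weights[order]
    # pool exact ties into one knot
    ux, start = np.unique(x, return_index=True)
    cumw = np.cumsum(w)
    F = cumw[np.append(start[1:] - 1, len(w) - 1)] / total

    knots = np.concatenate(([0.0], ux))
    cdf = np.concatenate(([0.0], F))
    if knots[-1] < 1.0:
        knots = np.append(knots, 1.0)
        cdf = np.append(cdf, 1.0)
    widths = np.diff(knots)
    slopes = np.diff(cdf) / widths
    heights = pava_isotonic(slopes, weights=widths, direction="non-increasing")
    heights = np.maximum(heights, 0.0)
    # merge equal adjacent heights into single intervals
    keep = np.concatenate(([True], np.abs(np.diff(heights)) > 1e-14))
    knots = np.concatenate((knots[:-1][keep], [1.0]))
    heights = heights[keep]
    # renormalize away accumulated floating-point drift
    heights = heights / float(np.sum(heights * np.diff(knots)))
    return MonotoneDensity(knots=knots, heights=heights)


def _initial_model(data: PairedPValues) -> FourGroupModel:
    """Interior starting point; densities seeded from the small-p halves."""
    xi0 = MixtureParams(0.85, 0.05, 0.05, 0.05)
    f_init = []
    for p in (data.p1, data.p2):
        w = (p < np.median(p)).astype(float)
        f_init.append(grenander_density(p, w))
    return FourGroupModel(params=xi0, f1=f_init[0], f2=f_init[1])


def em_fit(data: PairedPValues, config: EMConfig = EMConfig()):
    """Fit the four-group mixture by EM with Grenander (PAVA) M-steps.

    Returns ``(model, posterior, trace)``.  The log-likelihood trace is
    non-decreasing; non-convergence within ``max_iter`` yields a warning
    and ``trace.converged == False``, never an exception.
    """
    model = _initial_model(data)
    f1v = np.maximum(evaluate_density(model.f1, data.p1), config.floor)
    f2v = np.maximum(evaluate_density(model.f2, data.p2), config.floor)
    xi = model.params.as_array()
    f1, f2 = model.f1, model.f2

    logliks = []
    converged = False
    gamma = None
    for _ in range(config.max_iter):
        # E-step
        comp = np.stack([xi[0] * np.ones(data.m), xi[1] * f2v,
                         xi[2] * f1v, xi[3] * f1v * f2v], axis=1)
        denom = comp.sum(axis=1)
        ll = float(np.sum(np.log(denom)))
        gamma = comp / denom[:, None]

        if logliks and abs(ll - logliks[-1]) / (abs(logliks[-1]) + 1.0) < config.tol:
            logliks.append(ll)
            converged = True
            break
        logliks.append(ll)

        # M-step: weights
        xi = gamma.mean(axis=0)
        low = xi < _XI_FLOOR
        xi = np.maximum(xi, _XI_FLOOR)
        xi /= xi.sum()
        # M-step: densities (skipped for a collapsed component, keeping the
        # previous estimate)
        if not (low[2] and low[3]):
            f1 = grenander_density(data.p1, gamma[:, 2] + gamma[:, 3])
            f1v = np.maximum(f1.evaluate(data.p1), config.floor)
        if not (low[1] and low[3]):
            f2 = grenander_density(data.p2, gamma[:, 1] + gamma[:, 3])
            f2v = np.maximum(f2.evaluate(data.p2), config.floor)

    if not converged:
        warnings.warn(
            f"EM did not converge in {config.max_iter} iterations "
            f"(relative tolerance {config.tol})", RuntimeWarning)

    model = FourGroupModel(
        params=MixtureParams(*np.asarray(xi, dtype=float)), f1=f1, f2=f2)
    trace = EMTrace(loglik_per_iter=np.asarray(logliks),
                    n_iter=len(logliks), converged=converged)
    return model, PosteriorWeights(gamma=gamma), trace
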