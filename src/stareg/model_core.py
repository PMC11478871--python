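"""Four-group mixture model for paired p-values and exact Lfdr evaluation.

Replicability analysis asks, gene by gene, whether a signal is present in
*both* of two independent studies.  Each study contributes a p-value that is
Uniform(0,1) under its own null.  Writing ``theta_ji`` for the hidden
significance indicator of gene ``i`` in study ``j``, the joint hidden state
``(theta_1i, theta_2i)`` takes one of four values with prior probabilities
``xi_kl``, and the pair of p-values has the mixture density

    f(p1, p2) = xi00 + xi01 * f2(p2) + xi10 * f1(p1) + xi11 * f1(p1) * f2(p2),

where the null density is the constant 1 and ``f1``, ``f2`` are the study
specific non-null densities, assumed non-increasing (the monotone likelihood
ratio condition).  The composite replicability null is "significant in at
most one study", and its posterior probability given the pair of p-values is
the local false discovery rate

    Lfdr(p1, p2) = [xi00 + xi01 * f2(p2) + xi10 * f1(p1)] / f(p1, p2),

which is componentwise non-decreasing in (p1, p2) under the monotone
likelihood ratio condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence, Union

import numpy as np

__all__ = [
    "PairedPValues",
    "MixtureParams",
    "MonotoneDensity",
    "FourGroupModel",
    "LfdrResult",
    "evaluate_density",
    "compute_lfdr",
    "mixture_log_likelihood",
    "DENSITY_FLOOR",
    "P_VALUE_CLIP",
]

#: Heights are floored at this value whenever a density enters a ratio or a
#: logarithm, so the mixture density stays strictly positive on (0,1)^2.
DENSITY_FLOOR = 1e-10

#: p-values of exactly 0 or 1 are pulled inside the open interval at
#: ingestion; this changes no ordering but keeps log-likelihoods finite.
P_VALUE_CLIP = 1e-15

# A density is either the non-increasing step function below or any callable
# x -> f(x); the callable form exists so exact analytic densities can be
# pushed through the same Lfdr formula.
DensityLike = Union["MonotoneDensity", Callable[[np.ndarray], np.ndarray]]


@dataclass(frozen=True)
class PairedPValues:
    """Paired p-values (p_1i, p_2i) for m genes from two studies."""

    gene_ids: np.ndarray
    p1: np.ndarray
    p2: np.ndarray

    def __post_init__(self) -> None:
        gene_ids = np.asarray(self.gene_ids)
        p1 = np.asarray(self.p1, dtype=float)
        p2 = np.asarray(self.p2, dtype=float)
        if not (len(gene_ids) == len(p1) == len(p2)):
            raise ValueError("gene_ids, p1 and p2 must have equal length")
        if len(p1) < 1:
            raise ValueError("at least one gene is required")
        if len(np.unique(gene_ids)) != len(gene_ids):
            raise ValueError("gene_ids must be unique")
        for name, p in (("p1", p1), ("p2", p2)):
            if not np.all(np.isfinite(p)):
                raise ValueError(f"{name} contains non-finite values")
            if p.min() < 0.0 or p.max() > 1.0:
                raise ValueError(f"{name} contains values outside [0, 1]")
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "p1", np.clip(p1, P_VALUE_CLIP, 1.0 - P_VALUE_CLIP))
        object.__setattr__(self, "p2", np.clip(p2, P_VALUE_CLIP, 1.0 - P_VALUE_CLIP))

    @property
    def m(self) -> int:
        return len(self.p1)


@dataclass(frozen=True)
class MixtureParams:
    """Prior probabilities xi_kl of the four joint hidden states."""

    xi00: float
    xi01: float
    xi10: float
    xi11: float

    def __post_init__(self) -> None:
        xi = self.as_array()
        if np.any(xi < 0):
            raise ValueError("mixture weights must be non-negative")
        if abs(xi.sum() - 1.0) > 1e-12:
            raise ValueError("mixture weights must sum to 1")

    def as_array(self) -> np.ndarray:
        """Weights in state order (0,0), (0,1), (1,0), (1,1)."""
        return np.array([self.xi00, self.xi01, self.xi10, self.xi11], dtype=float)


@dataclass(frozen=True)
class MonotoneDensity:
    """Non-increasing step density on [0, 1].

    ``knots`` are the K+1 breakpoints (starting at 0, ending at 1) and
    ``heights`` the K interval values.  Intervals are left-open,
    right-closed (the first also contains 0): the value at an interior
    breakpoint is the slope of the interval ending there.  This is the
    left derivative of the least concave majorant, the convention under
    which the Grenander estimator evaluated at the observations attains
    the maximized likelihood.
    """

    knots: np.ndarray
    heights: np.ndarray

    def __post_init__(self) -> None:
        knots = np.asarray(self.knots, dtype=float)
        heights = np.asarray(self.heights, dtype=float)
        if knots.ndim != 1 or heights.ndim != 1 or len(knots) != len(heights) + 1:
            raise ValueError("need K+1 knots for K heights")
        if knots[0] != 0.0 or knots[-1] != 1.0:
            raise ValueError("knots must start at 0 and end at 1")
        if np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        if np.any(heights < 0):
            raise ValueError("heights must be non-negative")
        if np.any(np.diff(heights) > 1e-12):
            raise ValueError("heights must be non-increasing")
        total = float(np.sum(heights * np.diff(knots)))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"density must integrate to 1 (got {total!r})")
        object.__setattr__(self, "knots", knots)
        object.__setattr__(self, "heights", heights)

    def evaluate(self, x) -> np.ndarray:
        """Step-function value at ``x`` (scalar or array), left-continuous:
        the value on each interval (knot_{k}, knot_{k+1}]."""
        x = np.asarray(x, dtype=float)
        if np.any((x < 0.0) | (x > 1.0)):
            raise ValueError("x must lie in [0, 1]")
        idx = np.searchsorted(self.knots, x, side="left") - 1
        idx = np.clip(idx, 0, len(self.heights) - 1)
        return self.heights[idx]

    def __call__(self, x) -> np.ndarray:
        return self.evaluate(x)


UNIFORM_DENSITY = MonotoneDensity(knots=np.array([0.0, 1.0]), heights=np.array([1.0]))


@dataclass(frozen=True)
class FourGroupModel:
    """Mixture weights plus the two study-specific non-null densities.

    The null density is hard-coded as Uniform(0, 1); only the non-null
    densities f1 (study 1) and f2 (study 2) are free.
    """

    params: MixtureParams
    f1: DensityLike
    f2: DensityLike


@dataclass(frozen=True)
class LfdrResult:
    """Per-gene local false discovery rates plus the model that produced them."""

    lfdr: np.ndarray
    model: FourGroupModel
    gene_ids: np.ndarray = field(default=None)


def evaluate_density(d: DensityLike, x) -> np.ndarray:
    """Evaluate a density at ``x`` in [0,1]; step densities are left-continuous."""
    if isinstance(d, MonotoneDensity):
        return d.evaluate(x)
    return np.asarray(d(np.asarray(x, dtype=float)), dtype=float)


def _component_likelihoods(model: FourGroupModel, data: PairedPValues, floor: float):
    """The four per-gene component likelihoods, in state order 00, 01, 10, 11."""
    f1v = np.maximum(evaluate_density(model.f1, data.p1), floor)
    f2v = np.maximum(evaluate_density(model.f2, data.p2), floor)
    xi = model.params
    ones = np.ones(data.m)
    return np.stack(
        [xi.xi00 * ones, xi.xi01 * f2v, xi.xi10 * f1v, xi.xi11 * f1v * f2v], axis=1
    )


def compute_lfdr(
    model: FourGroupModel, data: PairedPValues, floor: float = DENSITY_FLOOR
) -> LfdrResult:
    """Posterior probability of the composite replicability null per gene.

    Lfdr_i = [xi00 + xi01 f2(p2i) + xi10 f1(p1i)] / f(p1i, p2i), where the
    denominator is the full four-term mixture density.  Density values are
    floored at ``floor`` so the ratio is always defined.
    """
    comp = _component_likelihoods(model, data, floor)
    denom = comp.sum(axis=1)
    if np.any(denom <= 0.0):
        raise ZeroDivisionError("mixture density vanished; model is degenerate")
    lfdr = (denom - comp[:, 3]) / denom
    return LfdrResult(lfdr=np.clip(lfdr, 0.0, 1.0), model=model, gene_ids=data.gene_ids)


def mixture_log_likelihood(
    model: FourGroupModel, data: PairedPValues, floor: float = DENSITY_FLOOR
) -> float:
    """Marginal log-likelihood sum_i log f(p1i, p2i) of the four-group mixture."""
    denom = _component_likelihoods(model, data, floor).sum(axis=1)
    ll = float(np.sum(np.log(denom)))
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite log-likelihood; density not floored")
    return ll
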