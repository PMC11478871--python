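"""Normal-model simulation harness and operating-characteristic metrics.

The generator draws, for each of m genes, a joint hidden state
(theta_1, theta_2) from the four-group prior, then per study j a summary
statistic X_j ~ N(theta_j * mu_j, sigma_j^2), and converts the z-statistic
Z_j = X_j / sigma_j to a one-sided p-value p_j = 1 - Phi(Z_j).  A gene is
truly replicable when both hidden indicators are 1.  Replicates use
independently derived substreams of one root seed, so experiments are
reproducible run to run and method to method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve

from . import baselines
from .api import replicability_analysis
from .estimation import EMConfig
from .inference import Decision
from .model_core import MixtureParams, PairedPValues

__all__ = ["SimulationConfig", "TruthLabels", "EvalMetrics", "simulate_pair",
           "evaluate_decision", "roc_auc", "run_experiment", "METHODS"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the normal data-generating model."""

    m: int = 10_000
    xi: MixtureParams = field(
        default_factory=lambda: MixtureParams(0.85, 0.05, 0.05, 0.05))
    mu1: float = 2.0
    mu2: float = 2.0
    sigma1: float = 1.0
    sigma2: float = 1.0
    seed: int = 0
    n_reps: int = 100

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be at least 1")
        if min(self.mu1, self.mu2) <= 0 or min(self.sigma1, self.sigma2) <= 0:
            raise ValueError("non-null means and standard deviations must be positive")
        if self.n_reps < 1:
            raise ValueError("n_reps must be at least 1")


@dataclass(frozen=True)
class TruthLabels:
    theta1: np.ndarray
    theta2: np.ndarray

    @property
    def replicable(self) -> np.ndarray:
        return (self.theta1 == 1) & (self.theta2 == 1)


@dataclass(frozen=True)
class EvalMetrics:
    fdp: float
    power: float


def simulate_pair(config: SimulationConfig,
                  rep_index: int = 0) -> Tuple[PairedPValues, TruthLabels]:
    """One replicate of paired one-sided p-values with ground-truth states.

    Deterministic given ``(config.seed, rep_index)``.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(rep_index,)))
    # states in order (0,0), (0,1), (1,0), (1,1)
    state = rng.choice(4, size=config.m, p=config.xi.as_array())
    theta1 = (state >= 2).astype(int)
    theta2 = (state % 2).astype(int)
    x1 = rng.normal(theta1 * config.mu1, config.sigma1)
    x2 = rng.normal(theta2 * config.mu2, config.sigma2)
    p1 = norm.sf(x1 / config.sigma1)
    p2 = norm.sf(x2 / config.sigma2)
    gene_ids = np.array([f"g{i:06d}" for i in range(config.m)])
    return (PairedPValues(gene_ids=gene_ids, p1=p1, p2=p2),
            TruthLabels(theta1=theta1, theta2=theta2))


def evaluate_decision(decision: Decision, truth: TruthLabels) -> EvalMetrics:
    """Realized false discovery proportion and power of one decision."""
    rej = np.asarray(decision.rejected, dtype=bool)
    repl = truth.replicable
    if len(rej) != len(repl):
        raise ValueError("decision and truth have different lengths")
    r = rej.sum()
    fdp = float((rej & ~repl).sum() / max(r, 1))
    power = float((rej & repl).sum() / max(repl.sum(), 1))
    return EvalMetrics(fdp=fdp, power=power)


def roc_auc(scores, truth: TruthLabels):
    """ROC curve and AUC for a score where smaller means more significant.

    FPR = false discoveries / true nulls, TPR = power; tied scores collapse
    into one threshold step; AUC by the trapezoid rule.
    """
    scores = np.asarray(scores, dtype=float)
    y = truth.replicable.astype(int)
    if y.min() == y.max():
        raise ValueError("both replicable and non-replicable genes are required")
    fpr, tpr, _ = roc_curve(y, -scores)
    return (fpr, tpr), float(_auc(fpr, tpr))


METHODS = ("stareg", "maxp", "adhoc_bh")


def _run_method(method: str, data: PairedPValues, alpha: float,
                em_config: EMConfig) -> Decision:
    if method == "stareg":
        return replicability_analysis(data, alpha, em_config).decision
    if method == "maxp":
        return baselines.maxp(data, alpha)
    if method == "adhoc_bh":
        return baselines.adhoc_bh(data, alpha)
    raise ValueError(f"unknown method {method!r}")


def run_experiment(config: SimulationConfig, alpha: float = 0.05,
                   methods: Iterable[str] = METHODS,
                   em_config: EMConfig = EMConfig()) -> pd.DataFrame:
    """Replicated operating-characteristic experiment.

    Simulates ``config.n_reps`` datasets, runs each method on each, and
    returns per-method mean FDP (the empirical FDR) and mean power with
    Monte-Carlo standard errors.
    """
    methods = list(methods)
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    fdp = {m: [] for m in methods}
    power = {m: [] for m in methods}
    for rep in range(config.n_reps):
        data, truth = simulate_pair(config, rep)
        for method in methods:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    decision = _run_method(method, data, alpha, em_config)
            except Exception as exc:  # annotate with the replicate index
                raise RuntimeError(
                    f"method {method!r} failed on replicate {rep}") from exc
            metrics = evaluate_decision(decision, truth)
            fdp[method].append(metrics.fdp)
            power[method].append(metrics.power)

    rows = []
    n = config.n_reps
    for method in methods:
        f = np.asarray(fdp[method])
        p = np.asarray(power[method])
        rows.append({
            "method": method,
            "m": config.m,
            "xi00": config.xi.xi00, "xi01": config.xi.xi01,
            "xi10": config.xi.xi10, "xi11": config.xi.xi11,
            "mu1": config.mu1, "mu2": config.mu2,
            "sigma1": config.sigma1, "sigma2": config.sigma2,
            "alpha": alpha,
            "mean_fdr": f.mean(),
            "mcse_fdr": f.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0,
            "mean_power": p.mean(),
            "mcse_power": p.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0,
            "n_reps": n,
        })
    return pd.DataFrame(rows)
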