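"""Lfdr-based replicability decisions: plug-in FDR estimator, step-up rule,
and the cumulative-mean gene ranking.

With per-gene local false discovery rates Lfdr_i in hand, rejecting
``{i : Lfdr_i <= lam}`` has estimated FDR

    FDR*(lam) = sum_i Lfdr_i 1{Lfdr_i <= lam} / sum_i 1{Lfdr_i <= lam},

the average posterior null probability among the rejected.  The data-driven
threshold is lam_m = sup{lam : FDR*(lam) <= alpha}, which coincides with the
step-up rule: reject the k-hat genes with smallest Lfdr, where k-hat is the
largest k whose running mean of ordered Lfdr values stays at or below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Decision", "fdr_star", "step_up", "rank_genes"]


@dataclass(frozen=True)
class Decision:
    """Per-gene rejection indicators with the threshold that produced them."""

    rejected: np.ndarray
    threshold: float
    alpha: float

    @property
    def k_hat(self) -> int:
        return int(np.sum(self.rejected))


def fdr_star(lfdr, lam: float) -> float:
    """Plug-in FDR estimate of the rejection region {Lfdr <= lam}.

    Returns 0 when the region is empty.
    """
    lfdr = np.asarray(lfdr, dtype=float)
    mask = lfdr <= lam
    r = int(mask.sum())
    if r == 0:
        return 0.0
    return float(lfdr[mask].sum() / r)


def step_up(lfdr, alpha: float) -> Decision:
    """Adaptive step-up rule on ordered Lfdr values at nominal level ``alpha``.

    Finds the largest k whose mean of the k smallest Lfdr values is <= alpha
    and rejects by thresholding at the k-th order statistic.  The rule is a
    value threshold, so genes tied at the same Lfdr are in or out as a
    block: the threshold is the largest observed value lam with
    FDR*(lam) <= alpha, which for tie-free data is exactly the running-mean
    step-up rule.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly between 0 and 1")
    lfdr = np.asarray(lfdr, dtype=float)
    ordered = np.sort(lfdr, kind="stable")
    running_mean = np.cumsum(ordered) / np.arange(1, len(ordered) + 1)
    # candidate k's are the ends of tie blocks; elsewhere the running mean
    # does not correspond to a value threshold
    block_end = np.append(np.diff(ordered) > 0, True)
    passing = np.nonzero((running_mean <= alpha) & block_end)[0]
    if len(passing) == 0:
        threshold = 0.0
        rejected = np.zeros(len(lfdr), dtype=bool)
        # a gene with Lfdr exactly 0 would have passed at k=1, so none is cut
    else:
        threshold = float(ordered[passing[-1]])
        rejected = lfdr <= threshold
    return Decision(rejected=rejected, threshold=threshold, alpha=alpha)


def rank_genes(lfdr):
    """Rank genes by cumulative means of ordered Lfdr values.

    Returns ``(order, scores)``: ``order`` indexes genes by ascending Lfdr
    and ``scores[i] = mean(Lfdr_(1..i+1))`` is the score of the gene at rank
    i, non-decreasing by construction.  Ranking by these running means (the
    estimated FDR of the top-i list) is how gene lists are fed to
    enrichment analysis.
    """
    lfdr = np.asarray(lfdr, dtype=float)
    order = np.argsort(lfdr, kind="stable")
    scores = np.cumsum(lfdr[order]) / np.arange(1, len(lfdr) + 1)
    return order, scores
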