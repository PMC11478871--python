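"""Simple comparator procedures for replicability analysis.

Two widely used ad hoc strategies serve as baselines:

* ``adhoc_bh`` — run Benjamini-Hochberg separately in each study and call
  the intersection of the two rejection sets replicable.  This does not
  control the replicability FDR when the studies disagree often.
* ``maxp`` — apply Benjamini-Hochberg to the per-gene maximum of the two
  p-values.  Valid but typically very conservative, since the maximum of a
  null and a non-null p-value is stochastically much larger than uniform
  suggests.
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

from .inference import Decision
from .model_core import PairedPValues

__all__ = ["bh", "adhoc_bh", "maxp"]


def bh(pvalues, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg step-up: reject the k largest-index order
    statistics with p_(i) <= i*alpha/m; plain (non-adaptive) variant."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly between 0 and 1")
    pvalues = np.asarray(pvalues, dtype=float)
    if np.any((pvalues < 0) | (pvalues > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(pvalues, alpha=alpha, method="fdr_bh")
    return reject


def adhoc_bh(data: PairedPValues, alpha: float) -> Decision:
    """BH within each study at level ``alpha``; replicable = intersection."""
    rejected = bh(data.p1, alpha) & bh(data.p2, alpha)
    return Decision(rejected=rejected, threshold=float("nan"), alpha=alpha)


def maxp(data: PairedPValues, alpha: float) -> Decision:
    """BH at level ``alpha`` on the per-gene maximum p-value."""
    q = np.maximum(data.p1, data.p2)
    return Decision(rejected=bh(q, alpha), threshold=float("nan"), alpha=alpha)
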