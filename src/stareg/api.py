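"""High-level one-call workflow: fit, score, decide."""

from __future__ import annotations

from typing import NamedTuple

from .estimation import EMConfig, EMTrace, em_fit
from .inference import Decision, step_up
from .model_core import FourGroupModel, LfdrResult, PairedPValues, compute_lfdr

__all__ = ["StaregResult", "replicability_analysis"]


class StaregResult(NamedTuple):
    lfdr: LfdrResult
    decision: Decision
    model: FourGroupModel
    trace: EMTrace


def replicability_analysis(
    data: PairedPValues, alpha: float = 0.05, config: EMConfig = EMConfig()
) -> StaregResult:
    """Fit the four-group mixture, compute per-gene Lfdr, and apply the
    Lfdr step-up rule at nominal FDR level ``alpha``."""
    model, _, trace = em_fit(data, config)
    lfdr = compute_lfdr(model, data, floor=config.floor)
    decision = step_up(lfdr.lfdr, alpha)
    return StaregResult(lfdr=lfdr, decision=decision, model=model, trace=trace)
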