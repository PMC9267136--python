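"""In silico triage: which VUS qualify for RNA analysis.

The rule combines a SpliceAI Δ-score gate with classical splice-site
predictor panels (NNSplice, MaxEntScan, GeneSplicer, SpliceSiteFinder-like):

* SpliceAI Δ must exceed 0.2 (strictly), and
* either at least two tools predict a novel 5'/3' splice site, or the
  natural site is weakened (one tool calls a complete loss, or MaxEntScan
  drops by >= 15% of the wild-type score while SSF drops by >= 5%).

Missing scores never trigger a clause.  A policy switch turns the SpliceAI
gate into an independent OR-clause instead of a conjunctive gate.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ScorePanel", "SelectionResult", "select_for_rna"]

SPLICEAI_GATE = 0.2
MAXENT_REDUCTION_MIN = 15.0
SSF_REDUCTION_MIN = 5.0
DENOVO_TOOLS_MIN = 2


@dataclass(frozen=True)
class ScorePanel:
    """Splice-prediction scores for one variant.

    ``denovo_calls`` / ``natural_loss_complete_calls`` count predictor
    tools (0..4); reductions are percent of the wild-type site score.
    """

    spliceai_delta: float | None = None
    denovo_calls: int = 0
    natural_loss_complete_calls: int = 0
    maxent_reduction_percent: float | None = None
    ssf_reduction_percent: float | None = None
    spice_positive: bool | None = None  # carried through, not used by the rule

    def __post_init__(self) -> None:
        for name in ("maxent_reduction_percent", "ssf_reduction_percent"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.spliceai_delta is not None and not 0 <= self.spliceai_delta <= 1:
            raise ValueError(f"spliceai_delta outside [0, 1]: {self.spliceai_delta}")
        for name in ("denovo_calls", "natural_loss_complete_calls"):
            v = getattr(self, name)
            if not 0 <= v <= 4:
                raise ValueError(f"{name} must be in 0..4, got {v}")


@dataclass(frozen=True)
class SelectionResult:
    selected: bool
    triggered_rules: tuple[str, ...]


def select_for_rna(
    panel: ScorePanel, spliceai_gate_conjunctive: bool = True
) -> SelectionResult:
    """Apply the triage rule to one score panel.

    Boundary semantics: SpliceAI Δ = 0.2 exactly fails the gate ("higher
    than 0.2"); MaxEnt reduction of exactly 15% (with SSF >= 5%) passes.
    """
    triggered: list[str] = []
    gate = panel.spliceai_delta is not None and panel.spliceai_delta > SPLICEAI_GATE
    if gate:
        triggered.append(f"spliceai>{SPLICEAI_GATE:g}")
    if panel.denovo_calls >= DENOVO_TOOLS_MIN:
        triggered.append(f"denovo>={DENOVO_TOOLS_MIN}tools")
    loss = panel.natural_loss_complete_calls >= 1 or (
        panel.maxent_reduction_percent is not None
        and panel.ssf_reduction_percent is not None
        and panel.maxent_reduction_percent >= MAXENT_REDUCTION_MIN
        and panel.ssf_reduction_percent >= SSF_REDUCTION_MIN
    )
    if loss:
        triggered.append("natural-ss-loss")
    other = panel.denovo_calls >= DENOVO_TOOLS_MIN or loss
    if spliceai_gate_conjunctive:
        selected = gate and other
        triggered.append("policy:spliceai-gate-conjunctive")
    else:
        selected = gate or other
        triggered.append("policy:spliceai-independent-or")
    return SelectionResult(selected, tuple(triggered))
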