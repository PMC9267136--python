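"""Splicing-impact classification (1S / 2S / 3S).

The three tiers summarize what the RNA data say about a variant:

* **1S** — no variant-associated aberrant event; splicing unaffected.
* **2S** — partial or uncertain impairment: aberrant events are present but
  either full-length transcript is still produced from the variant allele,
  or (without an exonic tag SNP) completeness cannot be determined.
* **3S** — complete impairment: aberrant events present and, judged by an
  exonic tag SNP, the variant allele produces essentially no full-length
  transcript.

3S therefore *requires* an exonic tag: intronic variants are absent from
mature mRNA and can never be shown to make zero full-length transcript,
which is exactly why their functional evidence is capped at moderate
strength downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .junctions import EventQuantification

__all__ = ["SplicingResult", "classify_splicing"]

CLASS_NO_EFFECT = "1S"
CLASS_PARTIAL = "2S"
CLASS_COMPLETE = "3S"


@dataclass
class SplicingResult:
    """Per-variant bundle of quantified events and tag-SNP observations."""

    variant: str
    events: list[EventQuantification] = field(default_factory=list)
    tag_available: bool = False
    alt_fulllength_percent: float | None = None
    splicing_class: str | None = None

    @property
    def associated_events(self) -> list[EventQuantification]:
        return [q for q in self.events if q.variant_associated]

    @property
    def total_aberrant_percent(self) -> float:
        return float(sum(q.carrier_percent for q in self.associated_events))


def classify_splicing(
    result: SplicingResult, noise_alt_percent: float = 1.0
) -> str:
    """Assign 1S/2S/3S and store it on the result.

    ``noise_alt_percent`` is the tolerance below which residual alt-allele
    full-length signal is treated as noise (sequencing error / index
    hopping) rather than genuine leaky full-length production.
    """
    if not result.associated_events:
        cls = CLASS_NO_EFFECT
    elif (
        result.tag_available
        and result.alt_fulllength_percent is not None
        and result.alt_fulllength_percent < noise_alt_percent
    ):
        cls = CLASS_COMPLETE
    else:
        cls = CLASS_PARTIAL
    result.splicing_class = cls
    return cls
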