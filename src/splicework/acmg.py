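"""ACMG/AMP evidence items, splicing-specific strength modifiers, and the
five-tier combining rules.

Evidence codes carry a default strength implied by their letter class
(PVS very strong, PS strong, PM moderate, PP supporting; BA stand-alone,
BS strong, BP supporting).  RNA-assay practice modifies these:

* ``PS3`` stays strong only when the assay shows the variant allele makes
  *no* full-length transcript (splicing class 3S, tag SNP required).
* ``PS3-m`` — moderate: impairment observed but completeness undecidable
  (typically intronic variants without an exonic tag).
* ``BS3-SA`` — stand-alone benign for silent/intronic variants whose
  predicted splice effect is functionally disproven; it forces a
  likely-benign call even against co-occurring supporting-level
  computational evidence (which would otherwise deadlock the variant at
  VUS forever).

Combined classes are rendered with numeric prefixes: 1-B, 2-LB, 3-VUS,
4-LP, 5-P.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import IntEnum

__all__ = [
    "Strength",
    "EvidenceItem",
    "EvidenceSet",
    "EvidenceParseError",
    "parse_evidence",
    "parse_items",
    "derive_functional_evidence",
    "combine",
    "reclassification_summary",
    "CLASS_BENIGN",
    "CLASS_LIKELY_BENIGN",
    "CLASS_VUS",
    "CLASS_LIKELY_PATHOGENIC",
    "CLASS_PATHOGENIC",
]

CLASS_BENIGN = "1-B"
CLASS_LIKELY_BENIGN = "2-LB"
CLASS_VUS = "3-VUS"
CLASS_LIKELY_PATHOGENIC = "4-LP"
CLASS_PATHOGENIC = "5-P"


class Strength(IntEnum):
    SUPPORTING = 1
    MODERATE = 2
    STRONG = 3
    VERY_STRONG = 4
    STAND_ALONE = 5


class EvidenceParseError(ValueError):
    pass


_CODES = (
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
    + ["BA1"]
    + [f"BS{i}" for i in range(1, 5)]
    + [f"BP{i}" for i in range(1, 8)]
)
VALID_CODES = frozenset(_CODES)

_DEFAULT_STRENGTH = {
    "PVS": Strength.VERY_STRONG,
    "PS": Strength.STRONG,
    "PM": Strength.MODERATE,
    "PP": Strength.SUPPORTING,
    "BA": Strength.STAND_ALONE,
    "BS": Strength.STRONG,
    "BP": Strength.SUPPORTING,
}

_SUFFIX_STRENGTH = {
    "m": Strength.MODERATE,
    "supp": Strength.SUPPORTING,
    "sa": Strength.STAND_ALONE,
    "s": Strength.STRONG,
    "vs": Strength.VERY_STRONG,
}
_STRENGTH_SUFFIX = {
    Strength.MODERATE: "m",
    Strength.SUPPORTING: "supp",
    Strength.STAND_ALONE: "SA",
    Strength.STRONG: "s",
    Strength.VERY_STRONG: "vs",
}


def default_strength(code: str) -> Strength:
    prefix = code[:3] if code.startswith("PVS") else code[:2]
    return _DEFAULT_STRENGTH[prefix]


@dataclass(frozen=True)
class EvidenceItem:
    code: str
    strength: Strength
    direction: str  # "pathogenic" | "benign"

    @classmethod
    def make(cls, code: str, strength: Strength | None = None) -> "EvidenceItem":
        if code not in VALID_CODES:
            raise EvidenceParseError(f"unknown evidence code {code!r}")
        direction = "benign" if code.startswith("B") else "pathogenic"
        return cls(code, strength or default_strength(code), direction)

    def render(self) -> str:
        if self.strength == default_strength(self.code):
            return self.code
        return f"{self.code}-{_STRENGTH_SUFFIX[self.strength]}"


_TOKEN_RE = re.compile(r"^([A-Z]+\d+)(?:-(\w+))?$")


def _parse_token(token: str) -> EvidenceItem:
    m = _TOKEN_RE.match(token.strip())
    if m is None:
        raise EvidenceParseError(f"malformed evidence token {token!r}")
    code, suffix = m.group(1), m.group(2)
    if code not in VALID_CODES:
        raise EvidenceParseError(f"unknown evidence code in token {token!r}")
    strength = None
    if suffix is not None:
        key = suffix.lower()
        if key not in _SUFFIX_STRENGTH:
            raise EvidenceParseError(f"unknown strength suffix in {token!r}")
        strength = _SUFFIX_STRENGTH[key]
    return EvidenceItem.make(code, strength)


def parse_items(text: str) -> tuple[EvidenceItem, ...]:
    """Parse a comma-joined evidence string, e.g. ``"PM2, PP3, PS3-m"``.

    Whitespace-separated runs inside a comma token (a stray missing comma)
    are tolerated.  Unknown tokens raise, naming the offender.
    """
    items: dict[str, EvidenceItem] = {}
    for chunk in text.split(","):
        for token in chunk.split():
            item = _parse_token(token)
            items[item.code] = item  # unique by code, last occurrence wins
    return tuple(items.values())


@dataclass
class EvidenceSet:
    variant: str
    items: tuple[EvidenceItem, ...] = ()

    @property
    def combined_class(self) -> str:
        return combine(self.items)

    def render(self) -> str:
        return ", ".join(item.render() for item in self.items)


def parse_evidence(text: str, variant: str = "") -> EvidenceSet:
    return EvidenceSet(variant, parse_items(text))


# ---------------------------------------------------------------------------
# functional evidence from a splicing result


def derive_functional_evidence(
    splicing_class: str,
    tag_available: bool,
    total_aberrant_percent: float,
    variant_kind: str,
    insignificance_threshold: float = 2.0,
) -> EvidenceItem | None:
    """Suggest the RNA-assay functional evidence item for one variant.

    * 3S → PS3 at full strength (no full-length transcript from the
      variant allele, demonstrated via tag SNP).
    * 2S with substantial impairment → PS3-m (moderate; completeness not
      established).
    * No significant impairment (1S, or 2S staying at/below the
      insignificance threshold) → BS3-SA, but only for silent/intronic
      variants: a missense with normal splicing has an untested protein
      effect, so no benign functional claim is made.

    The suggestion never overrides curator-supplied evidence strings; it is
    reported alongside them.
    """
    if variant_kind not in ("silent", "intronic", "missense", "other"):
        raise ValueError(f"unknown variant kind {variant_kind!r}")
    if splicing_class == "3S":
        return EvidenceItem.make("PS3")
    significant = total_aberrant_percent > insignificance_threshold
    if splicing_class == "2S" and significant:
        return EvidenceItem.make("PS3", Strength.MODERATE)
    if variant_kind in ("silent", "intronic"):
        return EvidenceItem.make("BS3", Strength.STAND_ALONE)
    return None


# ---------------------------------------------------------------------------
# combining rules


def _count(items, direction: str) -> dict[Strength, int]:
    out = {s: 0 for s in Strength}
    for item in items:
        if item.direction == direction:
            out[item.strength] += 1
    return out


def _pathogenic_tier(p: dict[Strength, int]) -> str:
    vs, s, m, sup = (
        p[Strength.VERY_STRONG],
        p[Strength.STRONG],
        p[Strength.MODERATE],
        p[Strength.SUPPORTING],
    )
    pathogenic = (
        (vs >= 1 and (s >= 1 or m >= 2 or (m == 1 and sup == 1) or sup >= 2))
        or vs >= 2
        or s >= 2
        or (s == 1 and (m >= 3 or (m == 2 and sup >= 2) or (m == 1 and sup >= 4)))
    )
    if pathogenic:
        return CLASS_PATHOGENIC
    likely = (
        (vs >= 1 and m == 1)
        or (s == 1 and 1 <= m <= 2)
        or (s == 1 and sup >= 2)
        or m >= 3
        or (m == 2 and sup >= 2)
        or (m == 1 and sup >= 4)
    )
    if likely:
        return CLASS_LIKELY_PATHOGENIC
    return CLASS_VUS


def _benign_tier(b: dict[Strength, int]) -> str:
    if b[Strength.STAND_ALONE] >= 1 or b[Strength.STRONG] >= 2:
        return CLASS_BENIGN
    if (b[Strength.STRONG] >= 1 and b[Strength.SUPPORTING] >= 1) or b[
        Strength.SUPPORTING
    ] >= 2:
        return CLASS_LIKELY_BENIGN
    return CLASS_VUS


def combine(items) -> str:
    """Combine evidence items into the five-tier classification.

    Standard combining rules on resolved strengths, with two splicing-
    workflow extensions: any stand-alone benign item other than BA1
    (i.e. BS3-SA) forces 2-LB regardless of co-occurring supporting-level
    pathogenic evidence, and a genuine conflict (both directions satisfied
    above supporting level) yields 3-VUS.
    """
    items = tuple(items)
    sa_items = [
        i for i in items
        if i.direction == "benign" and i.strength == Strength.STAND_ALONE
    ]
    has_ba1 = any(i.code == "BA1" for i in sa_items)
    has_bs3_sa = any(i.code != "BA1" for i in sa_items)

    p_tier = _pathogenic_tier(_count(items, "pathogenic"))
    b_counts = _count(items, "benign")
    if has_bs3_sa:
        # stand-alone functional benign: weaker than BA1 semantics — it
        # settles the variant at likely benign unless the pathogenic side
        # independently reaches LP/P (a real conflict).
        if p_tier != CLASS_VUS:
            return CLASS_VUS
        return CLASS_LIKELY_BENIGN
    b_tier = _benign_tier(b_counts) if not has_ba1 else CLASS_BENIGN
    if p_tier != CLASS_VUS and b_tier != CLASS_VUS:
        return CLASS_VUS  # conflicting evidence
    if p_tier != CLASS_VUS:
        return p_tier
    return b_tier


def reclassification_summary(sets: list[EvidenceSet]) -> dict:
    """Tally reclassification away from VUS over a list of evidence sets.

    Assumes every variant entered the workflow as 3-VUS (the study design:
    only VUS qualify for RNA analysis).
    """
    if not sets:
        raise ValueError("need at least one evidence set")
    n = len(sets)
    classes = [s.combined_class for s in sets]
    counts: dict[str, int] = {}
    for c in classes:
        counts[c] = counts.get(c, 0) + 1
    reclassified = sum(1 for c in classes if c != CLASS_VUS)
    benignward = sum(1 for c in classes if c in (CLASS_BENIGN, CLASS_LIKELY_BENIGN))
    pathward = sum(
        1 for c in classes if c in (CLASS_LIKELY_PATHOGENIC, CLASS_PATHOGENIC)
    )
    return {
        "n": n,
        "counts": counts,
        "n_reclassified": reclassified,
        "percent_reclassified": 100.0 * reclassified / n,
        "percent_likely_benign": 100.0 * benignward / n,
        "percent_likely_pathogenic": 100.0 * pathward / n,
    }
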