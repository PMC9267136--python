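"""Bundled reference cohort: 12 spliceogenic VUS in hereditary-cancer genes.

This module encodes, as package data, the observations from a published
clinical RNA-seq series characterizing 12 variants beyond the canonical
GT-AG dinucleotides in APC, ATM, FH, LZTR1, MSH6, PALB2, RAD51C and TP53:
per-event r. descriptions, carrier/control expression percentages, exonic
tag-SNP allele observations, and the curator evidence strings.  It is the
package's standing fixture — every module can be exercised against it —
and the input to ``scripts/acceptance.py``.

The transcript models are *synthetic but constrained*: exon boundaries
that the printed c. coordinates force (e.g. exon 16 of the LZTR1 model
spans c.1786–1942; the ATM model's intron 38 is exactly 2175 nt so that
its two pseudoexons measure 137 and 120 nt) are encoded exactly, all other
exon/intron sizes are filler.  Genomic anchors are arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .classify import SplicingResult, classify_splicing
from .events import SpliceEvent, event_from_r
from .junctions import EventQuantification, compare_to_controls
from .transcript import TranscriptModel, parse_c_position, variant_c_position

__all__ = [
    "CohortEvent",
    "CohortVariant",
    "cohort_models",
    "reference_cohort",
    "splicing_result",
    "cohort_run_config",
]

_ND = [0.0, 0.0, 0.0, 0.0, 0.0]  # event not detected in any control


@dataclass(frozen=True)
class CohortEvent:
    symbol: str
    r_description: str
    protein_change: str
    carrier_percent: float
    control_percents: tuple[float, ...] = tuple(_ND)


@dataclass(frozen=True)
class CohortVariant:
    variant: str
    gene: str
    kind: str  # "intronic" | "missense" | "silent"
    events: tuple[CohortEvent, ...]
    alt_fulllength_percent: float | None  # None: no exonic tag (intronic)
    evidence: str
    second_patient_percents: tuple[float, ...] = ()

    @property
    def position(self):
        return variant_c_position(self.variant)


def _sizes_from_boundaries(boundaries: dict[int, int]) -> list[int]:
    """Exon sizes whose cumulative sums hit the required c. end positions,
    linearly interpolated between the constrained ordinals."""
    sizes: list[int] = []
    prev_ord, prev_end = 0, 0
    for ordinal in sorted(boundaries):
        span = boundaries[ordinal] - prev_end
        k = ordinal - prev_ord
        if k < 1 or span < k:
            raise ValueError("boundaries must be strictly increasing with room "
                             "for at least 1 nt per exon")
        base, rem = divmod(span, k)
        sizes.extend([base + 1] * rem + [base] * (k - rem))
        prev_ord, prev_end = ordinal, boundaries[ordinal]
    return sizes


def _model(
    gene: str,
    chrom: str,
    strand: str,
    boundaries: dict[int, int],
    intron_sizes: dict[int, int] | None = None,
    default_intron: int = 400,
    first_exon_number: int = 1,
    genomic_start: int = 100_000,
) -> TranscriptModel:
    sizes = _sizes_from_boundaries(boundaries)
    introns = []
    for i in range(len(sizes) - 1):
        number = first_exon_number + i  # intron n follows exon n
        introns.append((intron_sizes or {}).get(number, default_intron))
    return TranscriptModel.from_exon_sizes(
        f"{gene}-model", gene, chrom, strand, sizes, introns,
        genomic_start=genomic_start, first_exon_number=first_exon_number,
    )


def cohort_models() -> dict[str, TranscriptModel]:
    """Transcript models for the eight cohort genes."""
    return {
        "APC": _model(
            "APC", "chr5", "+", {9: 1408, 10: 1608},
            intron_sizes={10: 1200}, first_exon_number=2,
        ),
        "ATM": _model(
            "ATM", "chr11", "+",
            {3: 186, 38: 5762, 52: 7788, 53: 7927, 54: 8100},
            intron_sizes={38: 2175},
        ),
        "FH": _model("FH", "chr1", "+", {8: 1236, 10: 1650},
                     intron_sizes={8: 900}),
        "LZTR1": _model("LZTR1", "chr22", "+", {15: 1785, 16: 1942, 17: 2100}),
        "MSH6": _model("MSH6", "chr2", "+", {6: 3556, 7: 3646, 8: 3800}),
        "PALB2": _model(
            "PALB2", "chr16", "+",
            {4: 2313, 5: 2514, 9: 3400, 10: 3600, 12: 4000},
        ),
        "RAD51C": _model("RAD51C", "chr17", "+", {8: 1026, 9: 1200}),
        "TP53": _model(
            "TP53", "chr17", "-", {1: 74, 2: 180, 3: 300},
            first_exon_number=2, genomic_start=200_000,
        ),
    }


def reference_cohort() -> list[CohortVariant]:
    """The 12 cohort variants with their RNA observations and evidence."""
    c = CohortEvent
    return [
        CohortVariant(
            "APC:c.1408+743_1408+745delinsACG", "APC", "intronic",
            (
                c("▼10A", "r.1408_1409ins1408+647_1408+744",
                  "p.(Gly471Serfs*60)", 27.0),
                c("▼10B", "r.1408_1409ins1408+602_1408+744",
                  "p.(Gly470Alafs*13)", 0.3),
            ),
            None, "PM2, PP3, PS3-m, PP4",
        ),
        CohortVariant(
            "ATM:c.172G>T", "ATM", "missense",
            (
                c("Δ3qA", "r.171_185del", "p.(Trp57*)", 41.4),
                c("Δ3qB", "r.171_195del", "p.(Trp57Cysfs*14)", 1.3),
            ),
            8.0, "PM2-supp, PP3, PS3-m",
        ),
        CohortVariant(
            "ATM:c.5763-1056G>A", "ATM", "intronic",
            (
                c("▼38A", "r.5762_5763ins5762+985_5763-1055",
                  "p.(Arg1921Serfs*6)", 20.8),
                c("▼38B", "r.5762_5763ins5762+1002_5763-1055",
                  "p.(Arg1921Serfs*12)", 1.6),
            ),
            None, "PM2-supp, PP3, PS3-m",
        ),
        CohortVariant(
            "ATM:c.7816A>G", "ATM", "missense",
            (
                c("Δ53", "r.7789_7927del", "p.(Asp2597Lysfs*3)", 3.0,
                  (0.3, 0.4, 0.6, 0.9, 1.3)),  # mean 0.7, range 0.3–1.3
            ),
            43.0, "PP3",
        ),
        CohortVariant(
            "FH:c.1237-11C>G", "FH", "intronic",
            (
                c("▼8p", "r.1236_1237ins1237-1_1237-10",
                  "p.(Ile413Serfs*5)", 40.0),
            ),
            None, "PM2, PP3, PS3-m, PP4",
        ),
        CohortVariant(
            "LZTR1:c.1942G>T", "LZTR1", "missense",
            (
                c("Δ16q", "r.1831_1942del", "p.(Val611Alafs*4)", 36.0),
                c("Δ16", "r.1786_1942del", "p.(Glu596Alafs*4)", 2.0),
            ),
            0.0, "PM2, PP3, PS3, PP4",  # only the wild-type allele seen
        ),
        CohortVariant(
            "MSH6:c.3646+5G>A", "MSH6", "intronic",
            (
                c("Δ7", "r.3557_3646del", "p.(Glu1187_Gly1216del)", 6.8),
            ),
            None, "PM2, PP3, PM4",
        ),
        CohortVariant(
            "PALB2:c.2379C>T", "PALB2", "silent",
            (
                c("Δ5q", "r.2378_2514del", "p.(Gly793Aspfs*2)", 1.7),
            ),
            44.0, "BS3-SA, BS1, PP3",
            second_patient_percents=(0.3,),
        ),
        CohortVariant(
            "PALB2:c.3495G>A", "PALB2", "silent",
            (), 48.0, "BS3-SA, BS1 PP3",  # evidence string as curated
        ),
        CohortVariant(
            "RAD51C:c.1027-3C>G", "RAD51C", "intronic",
            (
                c("Δ9pA", "r.1027_1032del", "p.(Pro343_Gln344del)", 10.5,
                  (0.35, 0.45, 0.0, 0.0, 0.0)),  # naturally occurring, mean 0.16
                c("Δ9pB", "r.1027_1078del", "p.(Pro343Lysfs*4)", 4.9),
                c("Δ9pC", "r.1027_1081del", "p.(Pro343Valfs*3)", 0.04),
            ),
            None, "PM2, PP3, PS3-m",
        ),
        CohortVariant(
            "RAD51C:c.779G>A", "RAD51C", "missense",
            (), 45.0, "PM2, PP3",
        ),
        CohortVariant(
            "TP53:c.74+23C>T", "TP53", "intronic",
            (
                c("▼2q", "r.74_75ins74+1_74+21", "p.(Leu26*)", 1.1),
            ),
            None, "BS3-SA",
            second_patient_percents=(1.7,),
        ),
    ]


def splicing_result(
    variant: CohortVariant,
    model: TranscriptModel | None = None,
    min_carrier_percent: float = 0.1,
    fold_over_controls: float = 3.0,
    noise_alt_percent: float = 1.0,
) -> SplicingResult:
    """Run the control comparison and splicing classifier on one cohort
    variant, returning the classified :class:`SplicingResult`."""
    model = model or cohort_models()[variant.gene]
    quants = []
    for ev in variant.events:
        parsed = event_from_r(ev.r_description, model, support=ev.carrier_percent)
        associated, why = compare_to_controls(
            ev.carrier_percent,
            list(ev.control_percents),
            min_carrier_percent=min_carrier_percent,
            fold_over_controls=fold_over_controls,
        )
        quants.append(
            EventQuantification(
                parsed, ev.carrier_percent, list(ev.control_percents),
                variant_associated=associated, rationale=why,
            )
        )
    result = SplicingResult(
        variant=variant.variant,
        events=quants,
        tag_available=variant.kind != "intronic"
        and variant.alt_fulllength_percent is not None,
        alt_fulllength_percent=variant.alt_fulllength_percent,
    )
    classify_splicing(result, noise_alt_percent=noise_alt_percent)
    return result


def cohort_run_config() -> dict:
    """Pipeline run configuration reproducing the cohort characterization
    from its precomputed event quantifications."""
    models = cohort_models()
    transcripts = []
    for gene, m in models.items():
        transcripts.append(
            {
                "id": m.transcript_id,
                "gene": gene,
                "chrom": m.chrom,
                "strand": m.strand,
                "exons": [list(x) for x in m.exons],
                "first_exon_number": m.first_exon_number,
            }
        )
    variants = []
    for v in reference_cohort():
        variants.append(
            {
                "variant": v.variant,
                "transcript": f"{v.gene}-model",
                "kind": v.kind,
                "evidence": v.evidence,
                "alt_fulllength_percent": v.alt_fulllength_percent,
                "events": [
                    {
                        "r": ev.r_description,
                        "carrier_percent": ev.carrier_percent,
                        "control_percents": list(ev.control_percents),
                    }
                    for ev in v.events
                ],
            }
        )
    return {"transcripts": transcripts, "variants": variants}
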