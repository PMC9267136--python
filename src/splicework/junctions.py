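"""Splice-junction tables, per-read records, detection and quantification.

Junction keys are ``(chrom, start, end, strand)`` with 1-based inclusive
intron coordinates, matching the STAR ``SJ.out.tab`` convention, always in
genomic orientation.  Only uniquely-mapped read counts are used by default.

Quantification follows the per-junction ratio approach used in clinical
RNA assays: for an aberrant junction supported by ``a`` reads competing
with canonical junction(s) supported by ``n`` reads, the event's expression
is reported as ``100 * a / (a + n)`` — the fraction of transcripts at that
locus carrying the aberration.  The literal ``a / n`` ratio is available
behind ``mode="literal"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .events import (
    EventKind,
    SpliceEvent,
    event_from_junction,
    merge_pseudoexon,
    name_events,
)
from .transcript import CPosition, TranscriptModel

__all__ = [
    "JunctionKey",
    "JunctionTable",
    "ReadRecord",
    "EventQuantification",
    "NoCoverage",
    "read_sj_tab",
    "write_sj_tab",
    "read_reads_tsv",
    "write_reads_tsv",
    "detect_aberrant",
    "event_junctions",
    "replaced_introns",
    "quantify_event",
    "total_aberrant",
    "allele_fulllength_fraction",
    "compare_to_controls",
]

JunctionKey = tuple[str, int, int, str]

_STRAND_CODE = {"0": ".", "1": "+", "2": "-"}
_CODE_STRAND = {".": 0, "+": 1, "-": 2}

_SJ_MAX_COUNT = 2**31 - 1


class NoCoverage(ValueError):
    """No informative reads at the region needed for a quantification."""


@dataclass
class JunctionTable:
    """Per-sample unique-read counts keyed by junction."""

    sample_id: str
    counts: dict[JunctionKey, int] = field(default_factory=dict)

    def add(self, key: JunctionKey, count: int) -> None:
        if count < 0:
            raise ValueError(f"negative junction count for {key}")
        self.counts[key] = self.counts.get(key, 0) + count

    def get(self, key: JunctionKey) -> int:
        return self.counts.get(key, 0)

    def __eq__(self, other) -> bool:  # sample ids are labels, not content
        return isinstance(other, JunctionTable) and self.counts == other.counts


@dataclass(frozen=True)
class ReadRecord:
    """One sequenced molecule: its junction chain and, when the read covers
    the variant position, the allele observed there."""

    read_id: str
    junction_chain: tuple[JunctionKey, ...] = ()
    allele: str | None = None  # "ref" | "alt" | None (not covered)


@dataclass
class EventQuantification:
    event: SpliceEvent
    carrier_percent: float
    control_percents: list[float] = field(default_factory=list)
    variant_associated: bool = False
    rationale: str = ""

    def __post_init__(self) -> None:
        for p in [self.carrier_percent, *self.control_percents]:
            if not 0.0 <= p <= 100.0:
                raise ValueError(f"percent out of [0, 100]: {p}")


# ---------------------------------------------------------------------------
# SJ.out.tab I/O


def read_sj_tab(
    path: str, sample_id: str | None = None, use_multimappers: bool = False
) -> JunctionTable:
    """Load a STAR ``SJ.out.tab`` file.

    Columns: chrom, intron start (1-based), intron end (1-based, last
    intronic base), strand code (0 undetermined / 1 + / 2 -), motif,
    annotated flag, unique reads, multimapped reads, max overhang.
    """
    table = JunctionTable(sample_id or str(path))
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            f = line.split()
            if len(f) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 columns, got {len(f)}"
                )
            try:
                chrom = f[0]
                start, end = int(f[1]), int(f[2])
                strand = _STRAND_CODE[f[3]]
                count = int(f[6])
                if use_multimappers:
                    count += int(f[7])
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed field: {exc}") from exc
            table.add((chrom, start, end, strand), count)
    return table


def write_sj_tab(table: JunctionTable, path: str) -> None:
    """Write a junction table in SJ.out.tab dialect (round-trips through
    :func:`read_sj_tab`)."""
    with open(path, "w") as fh:
        for key in sorted(table.counts):
            chrom, start, end, strand = key
            count = table.counts[key]
            if count > _SJ_MAX_COUNT:
                raise ValueError(f"count {count} exceeds SJ.out.tab 32-bit bound")
            fh.write(
                f"{chrom}\t{start}\t{end}\t{_CODE_STRAND[strand]}\t0\t0\t"
                f"{count}\t0\t50\n"
            )


# ---------------------------------------------------------------------------
# per-read records TSV: read_id <TAB> start-end,start-end <TAB> allele


def write_reads_tsv(reads: list[ReadRecord], path: str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            chain = ",".join(f"{k[1]}-{k[2]}" for k in r.junction_chain)
            allele = r.allele if r.allele is not None else "."
            fh.write(f"{r.read_id}\t{chain}\t{allele}\n")


def read_reads_tsv(path: str, chrom: str, strand: str) -> list[ReadRecord]:
    reads: list[ReadRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            chain = []
            if f[1]:
                for pair in f[1].split(","):
                    s, e = pair.split("-")
                    chain.append((chrom, int(s), int(e), strand))
            allele = None if f[2] in (".", "") else f[2]
            if allele not in (None, "ref", "alt"):
                raise ValueError(f"{path}:{lineno}: unknown allele {allele!r}")
            reads.append(ReadRecord(f[0], tuple(chain), allele))
    return reads


# ---------------------------------------------------------------------------
# detection


def detect_aberrant(
    table: JunctionTable, model: TranscriptModel, min_reads: int = 1
) -> list[SpliceEvent]:
    """Find non-canonical junctions and interpret them as splice events.

    Junction pairs bounding a common intronic interval are merged into a
    pseudoexon; single novel junctions into an intron stay as (possibly
    incomplete) intron-retention candidates.  Symbols are assigned before
    returning.  Zero events is a valid result.
    """
    annotated = set(model.annotated_junctions())
    lo, hi = model.span()
    left_flanks: list[SpliceEvent] = []  # 3p candidates (pseudoexon acceptors)
    right_flanks: list[SpliceEvent] = []  # 5p candidates (pseudoexon donors)
    events: list[SpliceEvent] = []
    for key in sorted(table.counts):
        chrom, start, end, strand = key
        count = table.counts[key]
        if chrom != model.chrom or count < min_reads:
            continue
        if strand not in (model.strand, "."):
            continue
        if key in annotated:
            continue
        if start - 1 <= lo or end >= hi:
            continue  # breakpoint outside the modeled span
        ev = event_from_junction(model, start, end)
        ev.support = float(count)
        ev.junctions = (key,)
        if ev.kind is EventKind.INTRON_RETENTION_3P and ev.incomplete:
            left_flanks.append(ev)
        elif ev.kind is EventKind.INTRON_RETENTION_5P and not ev.incomplete:
            right_flanks.append(ev)
            events.append(ev)  # may be consumed by a pseudoexon merge below
        elif ev.kind is EventKind.INTRON_RETENTION_5P and ev.incomplete:
            right_flanks.append(ev)
        else:
            events.append(ev)

    merged_right: set[int] = set()
    for lf in left_flanks:
        partner = None
        for i, rf in enumerate(right_flanks):
            if i in merged_right or rf.region != lf.region:
                continue
            acc, don = lf.inserted[0], rf.inserted[1]
            if acc <= don and (partner is None or don < right_flanks[partner].inserted[1]):
                partner = i
        if partner is not None:
            merged_right.add(partner)
            rf = right_flanks[partner]
            if rf in events:
                events.remove(rf)
            events.append(merge_pseudoexon(lf, rf))
        else:
            events.append(lf)  # unpaired: incomplete retention candidate
    for i, rf in enumerate(right_flanks):
        if i not in merged_right and rf.incomplete and rf not in events:
            events.append(rf)

    events.sort(key=lambda ev: (ev.anchor_position(), ev.kind.value))
    name_events(events)
    return events


# ---------------------------------------------------------------------------
# quantification


def replaced_introns(
    event: SpliceEvent,
    model: TranscriptModel,
    junctions: tuple[JunctionKey, ...] | None = None,
) -> list[JunctionKey]:
    """Annotated junctions whose splicing the event competes with: every
    annotated intron genomically overlapped by one of the event's novel
    junctions (for junction-less events, the host intron)."""
    ann = model.annotated_junctions()
    junctions = junctions if junctions is not None else event.junctions
    if not junctions:
        if event.region.kind == "intron":
            return [model.intron_junction_key(model.exon_index(event.region.number))]
        return []
    hit: list[JunctionKey] = []
    for a in ann:
        for j in junctions:
            if a[1] <= j[2] and j[1] <= a[2]:
                hit.append(a)
                break
    return hit


def event_junctions(
    event: SpliceEvent, model: TranscriptModel
) -> tuple[JunctionKey, ...]:
    """Novel junction key(s) implied by a (complete) event's breakpoints.

    Deletions produce one junction from the last kept base to the first
    kept base; pseudoexons produce their two flanking junctions; partial
    intron retentions produce the single junction at their novel boundary.
    """
    if event.incomplete:
        raise ValueError("incomplete event has no defined junction signature")

    def between(c_left: CPosition, c_right: CPosition) -> JunctionKey:
        gl = model.c_to_genomic(c_left)
        gr = model.c_to_genomic(c_right)
        lo, hi = min(gl, gr), max(gl, gr)
        return (model.chrom, lo + 2, hi, model.strand)

    if event.removed is not None:
        s, e = event.removed
        return (between(CPosition(s.anchor - 1), CPosition(e.anchor + 1)),)
    a, b = event.inserted
    intron_idx = model.exon_index(event.region.number)
    exon_l = CPosition(model.exon_c_range(intron_idx)[1])
    exon_r = CPosition(model.exon_c_range(intron_idx + 1)[0])
    if event.kind is EventKind.PSEUDOEXON:
        return (between(exon_l, a), between(b, exon_r))
    if event.kind is EventKind.INTRON_RETENTION_5P:
        return (between(b, exon_r),)
    return (between(exon_l, a),)


def quantify_event(
    event: SpliceEvent,
    table: JunctionTable,
    model: TranscriptModel,
    mode: str = "fraction",
) -> float:
    """Percent expression of one event from junction counts.

    ``a`` is the event's supporting junction count (mean of the two flanks
    for pseudoexons), ``n`` the mean count of the canonical junction(s) it
    replaces.  ``mode="fraction"`` (default) returns ``100a/(a+n)``;
    ``mode="literal"`` returns ``100a/n``.
    """
    if mode not in ("fraction", "literal"):
        raise ValueError(f"unknown mode {mode!r}")
    junctions = event.junctions or event_junctions(event, model)
    if not junctions:
        raise NoCoverage(
            "event has no junction signature; not quantifiable from a "
            "junction table (per-read records required)"
        )
    a = sum(table.get(j) for j in junctions) / len(junctions)
    canon = replaced_introns(event, model, junctions=tuple(junctions))
    n = sum(table.get(k) for k in canon) / len(canon) if canon else 0.0
    if a + n == 0:
        raise NoCoverage("no reads at the event region (a + n = 0)")
    if mode == "literal":
        if n == 0:
            raise NoCoverage("no canonical reads for literal a/n ratio")
        return 100.0 * a / n
    return 100.0 * a / (a + n)


def total_aberrant(percents: list[float]) -> float:
    """Summed aberrant expression over one variant's events."""
    return float(sum(percents))


def allele_fulllength_fraction(
    reads: list[ReadRecord],
    model: TranscriptModel,
) -> dict[str, float] | None:
    """Percent of total transcript output that is full-length with the
    variant vs the reference allele, using an exonic tag SNP.

    A read is *canonical* when every junction in its chain is annotated.
    Among allele-informative canonical reads the alt:ref split is measured
    and scaled to total output (aberrant + full-length), so the three
    quantities (aberrant %, alt full-length %, ref full-length %) are on a
    common denominator.  Returns ``None`` when no read is allele-informative
    (no exonic tag — e.g. an intronic variant), which downstream drives the
    PS3 strength downgrade.
    """
    annotated = set(model.annotated_junctions())
    total = 0
    canonical = 0
    alt = ref = 0
    for r in reads:
        total += 1
        if all(j in annotated for j in r.junction_chain):
            canonical += 1
            if r.allele == "alt":
                alt += 1
            elif r.allele == "ref":
                ref += 1
    if total == 0:
        raise NoCoverage("no reads supplied")
    if alt + ref == 0:
        return None
    alt_frac = alt / (alt + ref)
    return {
        "alt": 100.0 * canonical * alt_frac / total,
        "ref": 100.0 * canonical * (1.0 - alt_frac) / total,
    }


def compare_to_controls(
    carrier_percent: float,
    control_percents: list[float],
    min_carrier_percent: float = 0.1,
    fold_over_controls: float = 3.0,
) -> tuple[bool, str]:
    """Decide whether an event is variant-associated vs control background.

    Associated iff the carrier expression clears an absolute floor, exceeds
    every control, and is at least ``fold_over_controls`` times the control
    mean.  Returns (associated, human-readable rationale).
    """
    if not control_percents:
        raise ValueError("need at least one control sample")
    mean = sum(control_percents) / len(control_percents)
    peak = max(control_percents)
    checks = [
        (carrier_percent >= min_carrier_percent,
         f"carrier {carrier_percent:g}% >= floor {min_carrier_percent:g}%"),
        (carrier_percent > peak,
         f"carrier {carrier_percent:g}% > control max {peak:g}%"),
        (carrier_percent >= fold_over_controls * mean,
         f"carrier {carrier_percent:g}% >= {fold_over_controls:g}x control "
         f"mean {mean:g}%"),
    ]
    associated = all(ok for ok, _ in checks)
    rationale = "; ".join(
        ("PASS " if ok else "FAIL ") + msg for ok, msg in checks
    )
    return associated, rationale
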