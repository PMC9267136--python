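"""Aberrant splicing events: kinds, Δ/▼ symbols, HGVS r. descriptions.

An aberrant transcript species is either a deletion relative to the
annotated transcript (whole/partial exon skipping) or an insertion of
intronic sequence (pseudoexon inclusion, partial intron retention).  The
symbol grammar is the compact clinical shorthand:

    Δn    whole skip of exon n          ▼n    pseudoexon in intron n
    Δnp   acceptor-shift deletion       ▼np   acceptor-side retention
    Δnq   donor-shift deletion          ▼nq   donor-side retention

with letters A, B, ... appended when several events share the same
region and side, ordered by descending read support (ties 5'-first).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum

from .transcript import (
    CPosition,
    CoordinateError,
    HgvsParseError,
    RegionRef,
    TranscriptModel,
    parse_c_position,
)

__all__ = [
    "EventKind",
    "SpliceEvent",
    "FrameEffect",
    "IndeterminateLength",
    "event_from_junction",
    "event_from_r",
    "merge_pseudoexon",
    "name_events",
    "hgvs_r",
    "parse_r",
    "event_length",
    "frame_effect",
    "predict_protein_effect",
]

DELTA = "Δ"  # Δ  exon-skipping family
NABLA = "▼"  # ▼  intron-inclusion family


class EventKind(Enum):
    EXON_SKIP = "exon-skip"
    PARTIAL_EXON_DEL_ACCEPTOR = "partial-exon-del-acceptor"
    PARTIAL_EXON_DEL_DONOR = "partial-exon-del-donor"
    MULTI_EXON_DEL = "multi-exon-del"
    PSEUDOEXON = "pseudoexon"
    INTRON_RETENTION_5P = "intron-retention-5p"  # donor-side, ▼q
    INTRON_RETENTION_3P = "intron-retention-3p"  # acceptor-side, ▼p

    @property
    def is_deletion(self) -> bool:
        return self in (
            EventKind.EXON_SKIP,
            EventKind.PARTIAL_EXON_DEL_ACCEPTOR,
            EventKind.PARTIAL_EXON_DEL_DONOR,
            EventKind.MULTI_EXON_DEL,
        )


class IndeterminateLength(ValueError):
    """Event length cannot be computed without knowing the intron length."""


_SIDE_BY_KIND = {
    EventKind.EXON_SKIP: "",
    EventKind.PARTIAL_EXON_DEL_ACCEPTOR: "p",
    EventKind.PARTIAL_EXON_DEL_DONOR: "q",
    EventKind.PSEUDOEXON: "",
    EventKind.INTRON_RETENTION_5P: "q",
    EventKind.INTRON_RETENTION_3P: "p",
}


@dataclass
class SpliceEvent:
    """One aberrant transcript species.

    Exactly one of ``removed`` / ``inserted`` is set: deletions carry the
    removed c.-range (1-based inclusive, both ends exonic — a range crossing
    an exon boundary is still contiguous in c. space); insertions carry the
    inserted interval as a pair of intron-offset CPositions in transcript
    order.
    """

    kind: EventKind
    region: RegionRef
    removed: tuple[CPosition, CPosition] | None = None
    inserted: tuple[CPosition, CPosition] | None = None
    side: str | None = None  # explicit p/q annotation for MULTI_EXON_DEL
    symbol: str = ""
    support: float = 0.0
    incomplete: bool = False  # breakpoints not fully determined
    junctions: tuple[tuple[str, int, int, str], ...] = ()

    def __post_init__(self) -> None:
        if (self.removed is None) == (self.inserted is None):
            raise ValueError("exactly one of removed/inserted must be set")
        if self.kind.is_deletion and self.removed is None:
            raise ValueError(f"{self.kind.value} requires a removed range")
        if not self.kind.is_deletion and self.inserted is None:
            raise ValueError(f"{self.kind.value} requires an inserted interval")

    @property
    def side_label(self) -> str:
        if self.kind is EventKind.MULTI_EXON_DEL:
            return self.side or ""
        return _SIDE_BY_KIND[self.kind]

    @property
    def prefix(self) -> str:
        return DELTA if self.kind.is_deletion else NABLA

    def anchor_position(self) -> CPosition:
        """5'-most breakpoint, used for deterministic tie-breaking."""
        pair = self.removed if self.removed is not None else self.inserted
        return min(pair)


@dataclass(frozen=True)
class FrameEffect:
    net_length_change: int  # nucleotides; negative = deletion
    classification: str  # "in-frame" | "frameshift"

    @property
    def in_frame(self) -> bool:
        return self.classification == "in-frame"


# ---------------------------------------------------------------------------
# construction from junction evidence


def event_from_junction(
    model: TranscriptModel, donor: int, acceptor: int
) -> SpliceEvent:
    """Interpret one non-canonical junction as an aberrant event.

    ``donor``/``acceptor`` are the 1-based genomic start/end of the spliced
    interval (SJ.out.tab convention, genomic orientation: donor < acceptor).
    Raises ``ValueError("canonical junction ...")`` when the junction is an
    annotated intron.  Junctions with only one novel intronic breakpoint
    come back as intron-retention events, ``incomplete`` when the retained
    segment cannot be tied to a boundary; ``merge_pseudoexon`` upgrades a
    matching pair of such flanks to a pseudoexon.
    """
    if donor >= acceptor:
        raise ValueError("junction must satisfy donor < acceptor (genomic)")
    key = (model.chrom, donor, acceptor, model.strand)
    if key in model.annotated_junctions():
        raise ValueError(f"canonical junction {donor}-{acceptor}, not an event")
    # exonic flank bases (0-based genomic) on each transcript side
    left_g, right_g = donor - 2, acceptor  # base before / after the gap
    if model.strand == "+":
        up_g, down_g = left_g, right_g
    else:
        up_g, down_g = right_g, left_g
    up = model.genomic_to_c(up_g)
    down = model.genomic_to_c(down_g)

    if up.is_exonic and down.is_exonic:
        return _deletion_event(model, up, down)
    if up.is_exonic and not down.is_exonic:
        # annotated (or exon-internal) donor spliced to an intronic acceptor:
        # the 3' part of the intron from ``down`` onwards is retained.
        return _retention_3p(model, down)
    if not up.is_exonic and down.is_exonic:
        return _retention_5p(model, up)
    raise CoordinateError("junction with both breakpoints intronic is not "
                          "interpretable against this model")


def _deletion_event(
    model: TranscriptModel, up: CPosition, down: CPosition
) -> SpliceEvent:
    removed = (CPosition(up.anchor + 1), CPosition(down.anchor - 1))
    if removed[0] > removed[1]:
        raise ValueError("junction removes nothing — canonical adjacency")
    return _classify_deletion(model, removed)


def _classify_deletion(
    model: TranscriptModel, removed: tuple[CPosition, CPosition]
) -> SpliceEvent:
    s, e = removed
    i = model._exon_index_of_anchor(s.anchor)
    j = model._exon_index_of_anchor(e.anchor)
    ci = model.exon_c_range(i)
    cj = model.exon_c_range(j)
    region = RegionRef("exon", model.exon_number(i))
    if s.anchor == ci[0] and e.anchor == cj[1]:
        kind = EventKind.EXON_SKIP
    elif i == j:
        if s.anchor == ci[0]:
            kind = EventKind.PARTIAL_EXON_DEL_ACCEPTOR
        elif e.anchor == ci[1]:
            kind = EventKind.PARTIAL_EXON_DEL_DONOR
        else:
            # interior deletion: attribute to the nearer exon boundary
            kind = (
                EventKind.PARTIAL_EXON_DEL_DONOR
                if ci[1] - e.anchor <= s.anchor - ci[0]
                else EventKind.PARTIAL_EXON_DEL_ACCEPTOR
            )
    else:
        side = "q" if s.anchor > ci[0] else "p"
        return SpliceEvent(
            EventKind.MULTI_EXON_DEL, region, removed=removed, side=side
        )
    return SpliceEvent(kind, region, removed=removed)


# Intronic breakpoints within this many bases of an exon boundary are read
# as determined partial-intron retentions (a cryptic-site shift near the
# boundary); deeper unpaired breakpoints stay flagged incomplete, since on
# their own they cannot be told apart from a pseudoexon flank whose partner
# junction went unobserved.
RETENTION_WINDOW = 50


def _intron_index(model: TranscriptModel, pos: CPosition) -> int:
    idx = model._exon_index_of_anchor(pos.anchor)
    return idx if pos.offset > 0 else idx - 1


def _retention_3p(
    model: TranscriptModel, acceptor: CPosition, window: int = RETENTION_WINDOW
) -> SpliceEvent:
    """Retention of the intron's 3' part, from ``acceptor`` to the next exon."""
    idx = _intron_index(model, acceptor)
    L = model.intron_length(idx)
    d_acc = -acceptor.offset if acceptor.offset < 0 else L - acceptor.offset + 1
    if d_acc <= window:
        next_start = model.exon_c_range(idx + 1)[0]
        inserted = (CPosition(next_start, -d_acc), CPosition(next_start, -1))
        incomplete = False
    else:
        inserted = (acceptor, acceptor)
        incomplete = True
    return SpliceEvent(
        EventKind.INTRON_RETENTION_3P,
        RegionRef("intron", model.exon_number(idx)),
        inserted=inserted,
        incomplete=incomplete,
    )


def _retention_5p(
    model: TranscriptModel, donor: CPosition, window: int = RETENTION_WINDOW
) -> SpliceEvent:
    """Retention of the intron's 5' part, up to the novel donor position."""
    idx = _intron_index(model, donor)
    L = model.intron_length(idx)
    d_donor = donor.offset if donor.offset > 0 else L + donor.offset + 1
    if d_donor <= window:
        end_anchor = model.exon_c_range(idx)[1]
        inserted = (CPosition(end_anchor, 1), CPosition(end_anchor, d_donor))
        incomplete = False
    else:
        inserted = (donor, donor)
        incomplete = True
    return SpliceEvent(
        EventKind.INTRON_RETENTION_5P,
        RegionRef("intron", model.exon_number(idx)),
        inserted=inserted,
        incomplete=incomplete,
    )


def merge_pseudoexon(left: SpliceEvent, right: SpliceEvent) -> SpliceEvent:
    """Combine the two flanking junctions of a pseudoexon into one event.

    ``left`` is the (incomplete) 3p-retention candidate holding the
    pseudoexon's acceptor, ``right`` the 5p candidate holding its donor.
    """
    if left.kind is not EventKind.INTRON_RETENTION_3P:
        raise ValueError("left flank must be an acceptor-side candidate")
    if right.kind is not EventKind.INTRON_RETENTION_5P:
        raise ValueError("right flank must be a donor-side candidate")
    if left.region != right.region:
        raise ValueError("pseudoexon flanks must share an intron")
    acc = left.inserted[0]
    don = right.inserted[1]
    if not acc <= don:
        raise ValueError("pseudoexon acceptor must precede its donor")
    return SpliceEvent(
        EventKind.PSEUDOEXON,
        left.region,
        inserted=(acc, don),
        junctions=tuple(left.junctions) + tuple(right.junctions),
        support=(left.support + right.support) / 2.0,
    )


# ---------------------------------------------------------------------------
# symbols


def name_events(events: list[SpliceEvent]) -> list[SpliceEvent]:
    """Assign Δ/▼ symbols in place; returns the list for chaining.

    Events sharing (prefix, region number, side) receive letter suffixes in
    descending read-support order, ties broken by 5' breakpoint.  The
    ordering is total, so naming is invariant to input permutation.
    """
    groups: dict[tuple[str, int, str], list[SpliceEvent]] = {}
    for ev in events:
        groups.setdefault((ev.prefix, ev.region.number, ev.side_label), []).append(ev)
    for (prefix, number, side), members in groups.items():
        members.sort(key=lambda ev: (-ev.support, ev.anchor_position()))
        for i, ev in enumerate(members):
            base = f"{prefix}{number}{side}"
            ev.symbol = base + (chr(ord("A") + i) if len(members) > 1 else "")
    return events


def name_event(event: SpliceEvent, siblings: list[SpliceEvent]) -> str:
    """Symbol for ``event`` given previously observed events in the locus."""
    pool = [ev for ev in siblings if ev is not event] + [event]
    name_events(pool)
    return event.symbol


# ---------------------------------------------------------------------------
# HGVS r. descriptions


def hgvs_r(event: SpliceEvent, model: TranscriptModel) -> str:
    """Render the event as an HGVS-style r. description.

    Deletions: ``r.<start>_<end>del`` (collapsed for single bases).
    Insertions: ``r.<exonL>_<exonR>ins<from>_<to>`` — pseudoexon intervals
    in transcript order, intron retentions boundary-proximal base first
    (``ins1237-1_1237-10`` for a 10-nt acceptor-side retention).
    """
    if event.removed is not None:
        s, e = event.removed
        model.c_to_genomic(s), model.c_to_genomic(e)  # bound check
        if s == e:
            return f"r.{s}del"
        return f"r.{s}_{e}del"
    a, b = event.inserted
    if event.incomplete:
        a, b = event.inserted[0], "?"
    elif event.kind is EventKind.INTRON_RETENTION_3P:
        a, b = b, a  # (-1, -10): proximal first
    exon_idx = model.exon_index(event.region.number)
    flank_l = model.exon_c_range(exon_idx)[1]
    flank_r = flank_l + 1
    return f"r.{flank_l}_{flank_r}ins{a}_{b}"


_R_DEL_RE = re.compile(r"^r\.(\d+)(?:_(\d+))?del$")
_R_INS_RE = re.compile(
    r"^r\.(\d+)_(\d+)ins(\d+(?:[+-]\d+)?)_(\d+(?:[+-]\d+)?)$"
)


def parse_r(text: str, model: TranscriptModel) -> SpliceEvent:
    """Parse an r. deletion/insertion description into a SpliceEvent.

    Inverse of :func:`hgvs_r` on complete events; accepts inserted
    intervals in either order.
    """
    text = text.strip()
    m = _R_DEL_RE.match(text)
    if m:
        s = CPosition(int(m.group(1)))
        e = CPosition(int(m.group(2))) if m.group(2) else s
        if s > e:
            raise HgvsParseError(f"inverted deletion range in {text!r}")
        return _classify_deletion(model, (s, e))
    m = _R_INS_RE.match(text)
    if m:
        flank_l, flank_r = int(m.group(1)), int(m.group(2))
        if flank_r != flank_l + 1:
            raise HgvsParseError(
                f"insertion flanks must be adjacent exonic bases: {text!r}"
            )
        a = parse_c_position(m.group(3))
        b = parse_c_position(m.group(4))
        if a.is_exonic or b.is_exonic:
            raise HgvsParseError(f"inserted interval must be intronic: {text!r}")
        a, b = min(a, b), max(a, b)
        return _classify_insertion(model, flank_l, (a, b))
    raise HgvsParseError(f"unrecognized r. description: {text!r}")


def _classify_insertion(
    model: TranscriptModel, flank_l: int, inserted: tuple[CPosition, CPosition]
) -> SpliceEvent:
    a, b = inserted
    exon_idx = None
    for idx in range(model.n_exons):
        if model.exon_c_range(idx)[1] == flank_l:
            exon_idx = idx
            break
    if exon_idx is None or exon_idx == model.n_introns:
        raise CoordinateError(
            f"c.{flank_l} is not the donor-side boundary of an exon"
        )
    region = RegionRef("intron", model.exon_number(exon_idx))
    model.c_to_genomic(a), model.c_to_genomic(b)  # offset validity
    touches_donor = a.offset == 1
    touches_acceptor = b.offset == -1
    if touches_donor and not touches_acceptor:
        kind = EventKind.INTRON_RETENTION_5P
    elif touches_acceptor and not touches_donor:
        kind = EventKind.INTRON_RETENTION_3P
    elif touches_donor and touches_acceptor:
        kind = EventKind.INTRON_RETENTION_5P  # whole-intron retention
    else:
        kind = EventKind.PSEUDOEXON
    return SpliceEvent(kind, region, inserted=(a, b))


def event_from_r(
    text: str,
    model: TranscriptModel,
    support: float = 0.0,
) -> SpliceEvent:
    """Convenience: parse an r. description and attach read support."""
    ev = parse_r(text, model)
    ev.support = support
    return ev


# ---------------------------------------------------------------------------
# length / frame / protein consequences


def event_length(event: SpliceEvent, model: TranscriptModel | None = None) -> int:
    """Inclusive nucleotide length of the removed / inserted interval.

    Mixed-anchor intronic intervals (``+k`` .. ``-m``) need the intron
    length; without a model this raises :class:`IndeterminateLength`.
    """
    if event.incomplete:
        raise IndeterminateLength("event breakpoints are not fully determined")
    if event.removed is not None:
        s, e = event.removed
        return e.anchor - s.anchor + 1
    a, b = event.inserted
    if (a.offset > 0) == (b.offset > 0):
        return abs(abs(b.offset) - abs(a.offset)) + 1
    if model is None:
        raise IndeterminateLength(
            "indeterminate without intron length: "
            f"inserted interval {a}_{b} spans both intron anchors"
        )
    intron_idx = model.exon_index(event.region.number)
    L = model.intron_length(intron_idx)
    length = L - a.offset - (-b.offset) + 2
    if length < 1:
        raise CoordinateError(f"inserted interval {a}_{b} inverted for intron "
                              f"length {L}")
    return length


def frame_effect(
    event: SpliceEvent, model: TranscriptModel | None = None
) -> FrameEffect:
    """Net length change and in-frame/frameshift call (mod-3 rule)."""
    n = event_length(event, model)
    net = -n if event.removed is not None else n
    return FrameEffect(net, "in-frame" if net % 3 == 0 else "frameshift")


_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "*", "X": "Xaa",
}


def _translate(seq: str) -> str:
    from Bio.Seq import Seq

    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate())


def predict_protein_effect(
    event: SpliceEvent,
    cds_sequence: str,
    model: TranscriptModel,
    inserted_sequence: str | None = None,
) -> str:
    """Predict the protein-level consequence as an HGVS-style p. string.

    The mutant CDS is recomposed (deletion of the removed c.-range, or
    insertion of ``inserted_sequence`` at the event's exon boundary) and
    translated to the first stop.  Emitted forms: ``p.(Aaa<i>_Bbb<j>del)``,
    ``p.(Aaa<i>del)``, ``p.(Aaa<i>Bbbfs*<k>)``, ``p.(Aaa<i>*)`` and
    ``p.(=)`` when the protein is unchanged.
    """
    cds = cds_sequence.upper().replace("U", "T")
    if len(cds) != model.cds_length:
        raise ValueError(
            f"CDS length {len(cds)} does not match model length "
            f"{model.cds_length}"
        )
    if event.removed is not None:
        s, e = event.removed
        mutant = cds[: s.anchor - 1] + cds[e.anchor :]
    else:
        if inserted_sequence is None:
            raise ValueError(
                "protein prediction for insertion events needs the inserted "
                "intronic sequence"
            )
        exon_idx = model.exon_index(event.region.number)
        pos = model.exon_c_range(exon_idx)[1]
        mutant = cds[:pos] + inserted_sequence.upper().replace("U", "T") + cds[pos:]

    ref_p = _trim_at_stop(_translate(cds))
    mut_p = _trim_at_stop(_translate(mutant))
    if mut_p == ref_p:
        return "p.(=)"

    k = _common_prefix(ref_p, mut_p)
    ndel = len(ref_p) - len(mut_p)
    if (len(mutant) - len(cds)) % 3 == 0 and ndel >= 1 and mut_p[k:] == ref_p[
        k + ndel :
    ]:
        # clean in-frame deletion of one or more residues
        first = ref_p[k]
        if ndel == 1:
            return f"p.({_AA3[first]}{k + 1}del)"
        last = ref_p[k + ndel - 1]
        return f"p.({_AA3[first]}{k + 1}_{_AA3[last]}{k + ndel}del)"

    ref_aa = ref_p[k] if k < len(ref_p) else "*"
    mut_aa = mut_p[k] if k < len(mut_p) else "*"
    if mut_aa == "*":
        return f"p.({_AA3[ref_aa]}{k + 1}*)"
    # frameshift: stop offset counts the first changed residue as 1
    stop_off = len(mut_p) - k + 1  # mut_p excludes the stop itself
    full_mut = _translate(mutant)
    if "*" not in full_mut:
        return f"p.({_AA3[ref_aa]}{k + 1}{_AA3[mut_aa]}fs*?)"
    return f"p.({_AA3[ref_aa]}{k + 1}{_AA3[mut_aa]}fs*{stop_off})"


def _trim_at_stop(protein: str) -> str:
    i = protein.find("*")
    return protein if i < 0 else protein[:i]


def _common_prefix(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n
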