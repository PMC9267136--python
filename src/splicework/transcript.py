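"""Transcript models and exact HGVS c.-coordinate arithmetic.

A :class:`TranscriptModel` holds the exon structure of a single (coding)
transcript.  All genomic intervals are 0-based half-open internally; HGVS
rendering is 1-based inclusive.  c. positions may carry an intronic offset
(``c.1408+743`` is the 743rd base of the intron following the exon whose
last base is c.1408; ``c.5763-1056`` counts backwards from the acceptor).

The model is deliberately sequence-free: coordinate arithmetic, region
lookup and splice-site window classification need only exon boundaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "CPosition",
    "RegionRef",
    "TranscriptModel",
    "CoordinateError",
    "HgvsParseError",
    "parse_c_position",
    "variant_c_position",
    "SITE_CONSENSUS_DONOR",
    "SITE_CONSENSUS_ACCEPTOR",
    "SITE_DEEP_INTRONIC",
    "SITE_DEEP_EXONIC",
]


class CoordinateError(ValueError):
    """A position cannot be resolved on the given transcript model."""


class HgvsParseError(ValueError):
    """Malformed HGVS position / description string."""


# Variant-site classes (the donor/acceptor consensus windows follow the
# common clinical definition: donor = last 3 exonic + first 8 intronic nt,
# acceptor = last 12 intronic + first 2 exonic nt).
SITE_CONSENSUS_DONOR = "5'ss"
SITE_CONSENSUS_ACCEPTOR = "3'ss"
SITE_DEEP_INTRONIC = "DI"
SITE_DEEP_EXONIC = "DE"

DONOR_EXONIC_WINDOW = 3
DONOR_INTRONIC_WINDOW = 8
ACCEPTOR_INTRONIC_WINDOW = 12
ACCEPTOR_EXONIC_WINDOW = 2


@dataclass(frozen=True, order=True)
class CPosition:
    """A CDS-anchored HGVS position: exonic anchor plus intronic offset.

    ``offset == 0`` means the position is exonic.  A positive offset counts
    into the intron downstream of the anchor's donor site; a negative offset
    counts backwards from the acceptor of the intron upstream of the anchor.
    Tuple ordering of ``(anchor, offset)`` coincides with transcript order.
    """

    anchor: int
    offset: int = 0

    def __post_init__(self) -> None:
        if self.anchor < 1:
            raise HgvsParseError(
                f"anchor must be >= 1 (UTR positions unsupported): {self.anchor}"
            )

    def __str__(self) -> str:
        if self.offset == 0:
            return str(self.anchor)
        return f"{self.anchor}{self.offset:+d}"

    @property
    def is_exonic(self) -> bool:
        return self.offset == 0


_C_POS_RE = re.compile(r"^(\d+)(?:([+-])(\d+))?$")


def parse_c_position(text: str) -> CPosition:
    """Parse ``"172"``, ``"1408+743"`` or ``"5763-1056"`` into a CPosition.

    UTR-anchored positions (``-12``, ``*45``) are rejected: nothing in this
    workflow needs them and silently mis-anchoring them would be worse.
    """
    token = text.strip()
    m = _C_POS_RE.match(token)
    if m is None:
        raise HgvsParseError(f"malformed c. position: {token!r}")
    anchor = int(m.group(1))
    offset = 0
    if m.group(2) is not None:
        offset = int(m.group(3))
        if m.group(2) == "-":
            offset = -offset
        if offset == 0:
            raise HgvsParseError(f"zero intronic offset in {token!r}")
    return CPosition(anchor, offset)


_VARIANT_POS_RE = re.compile(r"c\.(\d+(?:[+-]\d+)?)")


def variant_c_position(variant: str) -> CPosition:
    """Extract the (first) c. position from a variant name.

    ``"APC:c.1408+743_1408+745delinsACG"`` -> CPosition(1408, +743).
    """
    m = _VARIANT_POS_RE.search(variant)
    if m is None:
        raise HgvsParseError(f"no c. position found in {variant!r}")
    return parse_c_position(m.group(1))


@dataclass(frozen=True)
class RegionRef:
    """Reference to exon *n* or intron *n* in the model's numbering scheme."""

    kind: str  # "exon" | "intron"
    number: int

    def __post_init__(self) -> None:
        if self.kind not in ("exon", "intron"):
            raise ValueError(f"region kind must be exon/intron, got {self.kind!r}")

    def __str__(self) -> str:
        return f"{self.kind} {self.number}"


class TranscriptModel:
    """Exon structure of one transcript plus c./genomic coordinate maps.

    Parameters
    ----------
    transcript_id, gene : str
        Identifiers carried through to reports.
    chrom : str
        Chromosome / contig name used in junction keys.
    strand : str
        ``"+"`` or ``"-"``.
    exons : sequence of (start, end)
        Genomic half-open intervals in *transcript* order (descending
        genomic coordinates on the minus strand).
    first_exon_number : int
        Number assigned to the first modeled exon.  Supports LRG-style
        numbering where the first coding exon is not "exon 1".
    """

    def __init__(
        self,
        transcript_id: str,
        gene: str,
        chrom: str,
        strand: str,
        exons: Sequence[tuple[int, int]],
        first_exon_number: int = 1,
    ) -> None:
        if strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {strand!r}")
        if not exons:
            raise ValueError("model needs at least one exon")
        self.transcript_id = transcript_id
        self.gene = gene
        self.chrom = chrom
        self.strand = strand
        self.exons = tuple((int(s), int(e)) for s, e in exons)
        self.first_exon_number = int(first_exon_number)
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"empty/inverted exon interval ({s}, {e})")
        # transcript-order and intron-length sanity
        for i in range(len(self.exons) - 1):
            gap = self._intron_span(i)
            if gap[1] <= gap[0]:
                raise ValueError(
                    f"exons {i} and {i + 1} overlap or touch (intron length < 1)"
                )
        sizes = [e - s for s, e in self.exons]
        self._c_ends = []
        acc = 0
        for size in sizes:
            acc += size
            self._c_ends.append(acc)
        self.cds_length = acc

    # -- basic structure ---------------------------------------------------

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    def exon_number(self, index: int) -> int:
        """Displayed number of the exon at 0-based transcript index."""
        return self.first_exon_number + index

    def exon_index(self, number: int) -> int:
        idx = number - self.first_exon_number
        if not 0 <= idx < self.n_exons:
            raise CoordinateError(f"no exon numbered {number} in {self.transcript_id}")
        return idx

    def exon_c_range(self, index: int) -> tuple[int, int]:
        """1-based inclusive c. range of the exon at transcript index."""
        start = 1 if index == 0 else self._c_ends[index - 1] + 1
        return start, self._c_ends[index]

    def _intron_span(self, index: int) -> tuple[int, int]:
        """Genomic half-open span of the intron after exon ``index``."""
        a, b = self.exons[index], self.exons[index + 1]
        if self.strand == "+":
            return a[1], b[0]
        return b[1], a[0]

    def intron_length(self, index: int) -> int:
        s, e = self._intron_span(index)
        return e - s

    def intron_length_by_number(self, number: int) -> int:
        return self.intron_length(self.exon_index(number))

    # -- coordinate maps ---------------------------------------------------

    def _exon_base(self, index: int, within: int) -> int:
        """Genomic (0-based) coordinate of the ``within``-th base (0-based,
        transcript direction) of exon ``index``."""
        s, e = self.exons[index]
        if self.strand == "+":
            return s + within
        return e - 1 - within

    def c_to_genomic(self, pos: CPosition) -> int:
        """Map a c. position to its 0-based genomic coordinate."""
        if pos.anchor > self.cds_length:
            raise CoordinateError(
                f"c.{pos} beyond transcript length {self.cds_length}"
            )
        idx = self._exon_index_of_anchor(pos.anchor)
        c_start, c_end = self.exon_c_range(idx)
        g_anchor = self._exon_base(idx, pos.anchor - c_start)
        if pos.offset == 0:
            return g_anchor
        if pos.offset > 0:
            if pos.anchor != c_end or idx == self.n_introns:
                raise CoordinateError(
                    f"c.{pos}: +offset requires the last base of a non-terminal exon"
                )
            if pos.offset > self.intron_length(idx):
                raise CoordinateError(
                    f"c.{pos}: offset exceeds intron length {self.intron_length(idx)}"
                )
            step = 1 if self.strand == "+" else -1
            return g_anchor + step * pos.offset
        # negative offset: counts back from the acceptor of the upstream intron
        if pos.anchor != c_start or idx == 0:
            raise CoordinateError(
                f"c.{pos}: -offset requires the first base of a non-initial exon"
            )
        if -pos.offset > self.intron_length(idx - 1):
            raise CoordinateError(
                f"c.{pos}: offset exceeds intron length {self.intron_length(idx - 1)}"
            )
        step = 1 if self.strand == "+" else -1
        return g_anchor + step * pos.offset

    def genomic_to_c(self, g: int) -> CPosition:
        """Map a 0-based genomic coordinate inside the model span to a
        CPosition.  Intronic bases are expressed relative to the nearer
        splice site (HGVS half-intron convention; ties go to the donor)."""
        for idx, (s, e) in enumerate(self.exons):
            if s <= g < e:
                c_start, _ = self.exon_c_range(idx)
                within = (g - s) if self.strand == "+" else (e - 1 - g)
                return CPosition(c_start + within)
        for idx in range(self.n_introns):
            s, e = self._intron_span(idx)
            if not s <= g < e:
                continue
            if self.strand == "+":
                d_donor = g - s + 1  # 1 = first intronic base
                d_acc = e - g
            else:
                d_donor = e - g
                d_acc = g - s + 1
            if d_donor <= d_acc:
                return CPosition(self.exon_c_range(idx)[1], d_donor)
            return CPosition(self.exon_c_range(idx + 1)[0], -d_acc)
        raise CoordinateError(f"genomic {g} outside {self.transcript_id} span")

    def _exon_index_of_anchor(self, anchor: int) -> int:
        for idx, c_end in enumerate(self._c_ends):
            if anchor <= c_end:
                return idx
        raise CoordinateError(f"anchor c.{anchor} beyond transcript")

    # -- region / site classification -------------------------------------

    def region_of(self, pos: CPosition) -> RegionRef:
        """Exon or intron containing the position, in model numbering.

        Positions with a positive offset belong to the intron following the
        anchor's exon; negative offsets to the intron preceding it.
        """
        idx = self._exon_index_of_anchor(pos.anchor)
        if pos.offset == 0:
            return RegionRef("exon", self.exon_number(idx))
        self.c_to_genomic(pos)  # validates offset vs intron length
        if pos.offset > 0:
            return RegionRef("intron", self.exon_number(idx))
        return RegionRef("intron", self.exon_number(idx - 1))

    def variant_site_class(self, pos: CPosition) -> str:
        """Classify a variant position into 5'ss / 3'ss / DI / DE.

        Consensus windows: donor = last 3 exonic + first 8 intronic bases;
        acceptor = last 12 intronic + first 2 exonic bases.
        """
        self.c_to_genomic(pos)  # validity check
        if pos.offset > 0:
            return (
                SITE_CONSENSUS_DONOR
                if pos.offset <= DONOR_INTRONIC_WINDOW
                else SITE_DEEP_INTRONIC
            )
        if pos.offset < 0:
            return (
                SITE_CONSENSUS_ACCEPTOR
                if -pos.offset <= ACCEPTOR_INTRONIC_WINDOW
                else SITE_DEEP_INTRONIC
            )
        idx = self._exon_index_of_anchor(pos.anchor)
        c_start, c_end = self.exon_c_range(idx)
        if idx < self.n_introns and c_end - pos.anchor < DONOR_EXONIC_WINDOW:
            return SITE_CONSENSUS_DONOR
        if idx > 0 and pos.anchor - c_start < ACCEPTOR_EXONIC_WINDOW:
            return SITE_CONSENSUS_ACCEPTOR
        return SITE_DEEP_EXONIC

    # -- junctions ---------------------------------------------------------

    def intron_junction_key(self, index: int) -> tuple[str, int, int, str]:
        """Junction key (chrom, 1-based intron start, 1-based intron end,
        strand) of the annotated intron after exon ``index``.  Matches the
        STAR SJ.out.tab coordinate convention."""
        s, e = self._intron_span(index)
        return (self.chrom, s + 1, e, self.strand)

    def annotated_junctions(self) -> tuple[tuple[str, int, int, str], ...]:
        return tuple(self.intron_junction_key(i) for i in range(self.n_introns))

    def span(self) -> tuple[int, int]:
        """Genomic half-open span covered by the model."""
        lo = min(s for s, _ in self.exons)
        hi = max(e for _, e in self.exons)
        return lo, hi

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_exon_sizes(
        cls,
        transcript_id: str,
        gene: str,
        chrom: str,
        strand: str,
        exon_sizes: Sequence[int],
        intron_sizes: Sequence[int],
        genomic_start: int = 10_000,
        first_exon_number: int = 1,
    ) -> "TranscriptModel":
        """Build a model from exon/intron lengths (transcript order).

        ``genomic_start`` anchors the genomically-leftmost base.
        """
        if len(intron_sizes) != len(exon_sizes) - 1:
            raise ValueError("need exactly n_exons - 1 intron sizes")
        # lay out left-to-right in genomic order
        g_exons = list(exon_sizes)
        g_introns = list(intron_sizes)
        if strand == "-":
            g_exons.reverse()
            g_introns.reverse()
        intervals = []
        pos = genomic_start
        for i, size in enumerate(g_exons):
            intervals.append((pos, pos + size))
            pos += size
            if i < len(g_introns):
                pos += g_introns[i]
        if strand == "-":
            intervals.reverse()
        return cls(transcript_id, gene, chrom, strand, intervals, first_exon_number)

    @classmethod
    def from_dict(cls, spec: dict) -> "TranscriptModel":
        """Build from an inline (YAML) definition.

        Accepts either explicit ``exons: [[start, end], ...]`` (genomic,
        0-based half-open, transcript order) or ``exon_sizes`` +
        ``intron_sizes`` (+ optional ``genomic_start``).
        """
        common = dict(
            transcript_id=spec.get("id") or spec["transcript_id"],
            gene=spec.get("gene", ""),
            chrom=spec.get("chrom", "chr1"),
            strand=spec.get("strand", "+"),
            first_exon_number=spec.get("first_exon_number", 1),
        )
        if "exons" in spec:
            return cls(exons=[tuple(x) for x in spec["exons"]], **common)
        return cls.from_exon_sizes(
            exon_sizes=spec["exon_sizes"],
            intron_sizes=spec["intron_sizes"],
            genomic_start=spec.get("genomic_start", 10_000),
            **common,
        )

    @classmethod
    def from_gtf(
        cls,
        path: str,
        transcript_id: str,
        gene: str | None = None,
        first_exon_number: int = 1,
    ) -> "TranscriptModel":
        """Read exon features for one transcript from a GTF file."""
        import gffutils

        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="merge",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        exons = []
        strand = None
        chrom = None
        gene_name = gene
        for feat in db.features_of_type("exon"):
            ids = feat.attributes.get("transcript_id", [])
            if transcript_id not in ids:
                continue
            exons.append((feat.start - 1, feat.end))  # GTF is 1-based inclusive
            strand = feat.strand
            chrom = feat.seqid
            if gene_name is None:
                gene_name = (feat.attributes.get("gene_name") or [""])[0]
        if not exons:
            raise ValueError(f"transcript {transcript_id!r} not found in {path}")
        exons.sort()
        if strand == "-":
            exons.reverse()
        return cls(transcript_id, gene_name or "", chrom, strand, exons,
                   first_exon_number)

    @classmethod
    def from_bed12(
        cls, path: str, name: str | None = None, first_exon_number: int = 1
    ) -> "TranscriptModel":
        """Read one transcript from a BED12 file (first or named record)."""
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                if len(f) < 12:
                    raise ValueError(f"not a BED12 record: {line[:60]!r}")
                if name is not None and f[3] != name:
                    continue
                start = int(f[1])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
                if f[5] == "-":
                    exons.reverse()
                return cls(f[3], f[3], f[0], f[5], exons, first_exon_number)
        raise ValueError(f"record {name!r} not found in {path}")
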