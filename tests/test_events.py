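"""Event nomenclature, r. descriptions, lengths, frame and protein effects."""

import itertools
import re

import numpy as np
import pytest

from splicework.events import (
    EventKind,
    IndeterminateLength,
    SpliceEvent,
    event_from_junction,
    event_from_r,
    event_length,
    frame_effect,
    hgvs_r,
    name_events,
    parse_r,
    predict_protein_effect,
)
from splicework.transcript import CPosition, RegionRef, TranscriptModel


class TestNaming:
    def test_letter_suffixes_by_support_then_coordinate(self, models):
        m = models["RAD51C"]
        evs = [
            event_from_r("r.1027_1032del", m, support=10.5),
            event_from_r("r.1027_1078del", m, support=4.9),
            event_from_r("r.1027_1081del", m, support=0.04),
        ]
        name_events(evs)
        assert [e.symbol for e in evs] == ["Δ9pA", "Δ9pB", "Δ9pC"]

    def test_naming_invariant_under_permutation(self, models):
        m = models["ATM"]
        base = [
            ("r.5762_5763ins5762+985_5763-1055", 20.8),
            ("r.5762_5763ins5762+1002_5763-1055", 1.6),
            ("r.171_185del", 41.4),
            ("r.171_195del", 1.3),
        ]
        reference = None
        for perm in itertools.permutations(base):
            evs = [event_from_r(r, m, support=s) for r, s in perm]
            name_events(evs)
            symbols = {hgvs_r(e, m): e.symbol for e in evs}
            if reference is None:
                reference = symbols
            assert symbols == reference
        assert reference["r.5762_5763ins5762+985_5763-1055"] == "▼38A"
        assert reference["r.171_195del"] == "Δ3qB"

    def test_sole_events_get_no_letter(self, models):
        ev = event_from_r("r.3557_3646del", models["MSH6"], support=6.8)
        name_events([ev])
        assert ev.symbol == "Δ7"

    def test_skip_and_partial_deletion_are_separate_series(self, models):
        m = models["LZTR1"]
        evs = [
            event_from_r("r.1831_1942del", m, support=36.0),
            event_from_r("r.1786_1942del", m, support=2.0),
        ]
        name_events(evs)
        assert {e.symbol for e in evs} == {"Δ16q", "Δ16"}


class TestHgvsR:
    @pytest.mark.parametrize(
        "gene,text",
        [
            ("LZTR1", "r.1831_1942del"),
            ("FH", "r.1236_1237ins1237-1_1237-10"),
            ("APC", "r.1408_1409ins1408+647_1408+744"),
            ("ATM", "r.5762_5763ins5762+985_5763-1055"),
            ("TP53", "r.74_75ins74+1_74+21"),
        ],
    )
    def test_parse_render_roundtrip_on_reference_descriptions(
        self, models, gene, text
    ):
        m = models[gene]
        assert hgvs_r(parse_r(text, m), m) == text

    def test_single_base_deletion_collapses(self, models):
        m = models["ATM"]
        ev = SpliceEvent(
            EventKind.PARTIAL_EXON_DEL_DONOR,
            RegionRef("exon", 3),
            removed=(CPosition(100), CPosition(100)),
        )
        assert hgvs_r(ev, m) == "r.100del"
        parsed = parse_r("r.100del", m)
        assert parsed.removed == (CPosition(100), CPosition(100))

    @pytest.mark.parametrize("seed", range(8))
    def test_roundtrip_on_randomized_events(self, models, seed):
        """hgvs_r and parse_r are mutual inverses over the event grammar."""
        rng = np.random.default_rng(seed)
        m = models["ATM"]
        for _ in range(40):
            ev = _random_event(rng, m)
            text = hgvs_r(ev, m)
            back = parse_r(text, m)
            assert (back.removed, back.inserted) == (ev.removed, ev.inserted)
            assert hgvs_r(back, m) == text

    def test_unparseable_rejected(self, models):
        from splicework.transcript import HgvsParseError

        with pytest.raises(HgvsParseError):
            parse_r("r.10_5del", models["ATM"])
        with pytest.raises(HgvsParseError):
            parse_r("r.banana", models["ATM"])


def _random_event(rng, m: TranscriptModel) -> SpliceEvent:
    if rng.random() < 0.5:
        a = int(rng.integers(1, m.cds_length - 1))
        b = int(rng.integers(a, min(m.cds_length, a + 200)))
        from splicework.events import _classify_deletion

        return _classify_deletion(m, (CPosition(a), CPosition(b)))
    intron_idx = int(rng.integers(0, m.n_introns))
    L = m.intron_length(intron_idx)
    end_anchor = m.exon_c_range(intron_idx)[1]
    next_anchor = end_anchor + 1
    mode = rng.integers(0, 3)
    if mode == 0:  # donor-side retention
        k = int(rng.integers(1, L))
        ins = (CPosition(end_anchor, 1), CPosition(end_anchor, k))
        kind = EventKind.INTRON_RETENTION_5P
    elif mode == 1:  # acceptor-side retention
        k = int(rng.integers(1, L))
        ins = (CPosition(next_anchor, -k), CPosition(next_anchor, -1))
        kind = EventKind.INTRON_RETENTION_3P
    else:  # pseudoexon strictly inside the intron
        half = max(2, L // 2)
        a = int(rng.integers(2, half + 1))
        b = int(rng.integers(2, half + 1))
        ins = (CPosition(end_anchor, a), CPosition(next_anchor, -b))
        kind = EventKind.PSEUDOEXON
    return SpliceEvent(kind, RegionRef("intron", m.exon_number(intron_idx)),
                       inserted=ins)


class TestEventFromJunction:
    def test_canonical_junction_is_an_error(self, models):
        m = models["MSH6"]
        chrom, s, e, strand = m.intron_junction_key(5)
        with pytest.raises(ValueError, match="canonical"):
            event_from_junction(m, s, e)

    def test_exon_skip_from_annotated_flanks(self, models):
        m = models["MSH6"]
        _, s6, _, _ = m.intron_junction_key(5)  # intron before exon 7
        _, _, e7, _ = m.intron_junction_key(6)  # intron after exon 7
        ev = event_from_junction(m, s6, e7)
        assert ev.kind is EventKind.EXON_SKIP
        assert ev.removed == (CPosition(3557), CPosition(3646))

    def test_partial_exon_deletion_from_cryptic_donor(self, models):
        m = models["LZTR1"]
        g_donor = m.c_to_genomic(CPosition(1830))  # novel donor after c.1830
        _, _, e16, _ = m.intron_junction_key(15)  # wrong intron on purpose?
        chrom, s16, e16, _ = m.intron_junction_key(15)
        ev = event_from_junction(m, g_donor + 2, e16)
        assert ev.kind is EventKind.PARTIAL_EXON_DEL_DONOR
        assert ev.removed == (CPosition(1831), CPosition(1942))

    def test_boundary_near_junction_is_complete_retention(self, models):
        m = models["TP53"]
        ev = event_from_r("r.74_75ins74+1_74+21", m)
        from splicework.junctions import event_junctions

        (key,) = event_junctions(ev, m)
        detected = event_from_junction(m, key[1], key[2])
        assert detected.kind is EventKind.INTRON_RETENTION_5P
        assert not detected.incomplete
        assert detected.inserted == ev.inserted


class TestLengthAndFrame:
    @pytest.mark.parametrize(
        "gene,text,length",
        [
            ("LZTR1", "r.1831_1942del", 112),
            ("FH", "r.1236_1237ins1237-1_1237-10", 10),
            ("TP53", "r.74_75ins74+1_74+21", 21),
            ("RAD51C", "r.1027_1032del", 6),
            ("APC", "r.1408_1409ins1408+647_1408+744", 98),
            ("APC", "r.1408_1409ins1408+602_1408+744", 143),
        ],
    )
    def test_lengths_forced_by_descriptions(self, models, gene, text, length):
        m = models[gene]
        assert event_length(parse_r(text, m), m) == length

    def test_mixed_anchor_interval_needs_intron_length(self, models):
        m = models["ATM"]
        ev = parse_r("r.5762_5763ins5762+985_5763-1055", m)
        with pytest.raises(IndeterminateLength):
            event_length(ev, None)
        assert event_length(ev, m) == 137

    def test_frame_classification_follows_mod3(self, models):
        m = models["MSH6"]
        fe = frame_effect(parse_r("r.3557_3646del", m), m)
        assert fe.net_length_change == -90 and fe.in_frame
        fe = frame_effect(parse_r("r.1831_1942del", models["LZTR1"]),
                          models["LZTR1"])
        assert fe.net_length_change == -112
        assert fe.classification == "frameshift"

    def test_incomplete_event_has_indeterminate_length(self, models):
        m = models["APC"]
        ev = SpliceEvent(
            EventKind.INTRON_RETENTION_3P,
            RegionRef("intron", 10),
            inserted=(CPosition(1408, 647), CPosition(1408, 647)),
            incomplete=True,
        )
        with pytest.raises(IndeterminateLength):
            event_length(ev, m)


class TestProteinEffect:
    # single-exon toy model: 10 codons incl. terminal stop
    CDS = "ATGGCTGAATTTGGGCCCAAACGTATGTAA"

    @pytest.fixture
    def toy(self):
        return TranscriptModel("toy-cds", "TOY", "chrT", "+",
                               [(0, len(self.CDS))])

    def _deletion(self, s, e):
        from splicework.events import _classify_deletion

        return lambda m: _classify_deletion(m, (CPosition(s), CPosition(e)))

    def test_inframe_single_codon_deletion(self, toy):
        ev = self._deletion(4, 6)(toy)  # removes codon 2 (GCT, Ala)
        assert predict_protein_effect(ev, self.CDS, toy) == "p.(Ala2del)"

    def test_frameshift_matches_direct_translation_oracle(self):
        from Bio.Seq import Seq

        cds = "ATGGCAATAAGGCATTGA"  # shifted frame hits a stop
        toy = TranscriptModel("toy-fs", "TOY", "chrT", "+", [(0, len(cds))])
        ev = self._deletion(4, 4)(toy)  # 1-nt deletion
        got = predict_protein_effect(ev, cds, toy)
        mutant = cds[:3] + cds[4:]
        usable = len(mutant) - len(mutant) % 3
        mut_p = str(Seq(mutant[:usable]).translate())
        ref_p = str(Seq(cds).translate())
        k = next(i for i, (a, b) in enumerate(zip(ref_p, mut_p)) if a != b)
        stop = mut_p.index("*")
        expected_offset = stop - k + 1
        m = re.fullmatch(r"p\.\((\w{3})(\d+)(\w{3})fs\*(\d+)\)", got)
        assert m is not None, got
        assert int(m.group(2)) == k + 1
        assert int(m.group(4)) == expected_offset

    def test_deletion_creating_immediate_stop(self):
        cds = "ATGCATAAGGAGTAG"
        toy = TranscriptModel("toy2", "TOY", "chrT", "+", [(0, len(cds))])
        ev = self._deletion(4, 5)(toy)  # mutant codon 2 becomes TAA
        assert predict_protein_effect(ev, cds, toy) == "p.(His2*)"

    def test_length_mismatch_rejected(self, toy):
        ev = self._deletion(4, 6)(toy)
        with pytest.raises(ValueError, match="length"):
            predict_protein_effect(ev, self.CDS + "A", toy)
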