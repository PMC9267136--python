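"""Junction I/O, aberrant-event detection and quantification."""

import numpy as np
import pytest

from splicework.events import event_from_r
from splicework.junctions import (
    JunctionTable,
    NoCoverage,
    ReadRecord,
    allele_fulllength_fraction,
    compare_to_controls,
    detect_aberrant,
    event_junctions,
    quantify_event,
    read_reads_tsv,
    read_sj_tab,
    total_aberrant,
    write_reads_tsv,
    write_sj_tab,
)


class TestSjTabIO:
    def test_field_mapping(self, tmp_path):
        p = tmp_path / "a.SJ.out.tab"
        p.write_text("chr1\t300\t400\t1\t1\t1\t50\t3\t30\n")
        t = read_sj_tab(str(p))
        assert t.counts == {("chr1", 300, 400, "+"): 50}

    def test_multimappers_optional(self, tmp_path):
        p = tmp_path / "a.tab"
        p.write_text("chr1\t300\t400\t2\t1\t1\t50\t3\t30\n")
        assert read_sj_tab(str(p), use_multimappers=True).counts == {
            ("chr1", 300, 400, "-"): 53
        }

    def test_undetermined_strand_kept(self, tmp_path):
        p = tmp_path / "a.tab"
        p.write_text("chr1\t300\t400\t0\t0\t0\t7\t0\t10\n")
        assert ("chr1", 300, 400, ".") in read_sj_tab(str(p)).counts

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.tab"
        p.write_text("")
        assert read_sj_tab(str(p)).counts == {}

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.tab"
        p.write_text("chr1\t300\t400\t1\t1\t1\t50\t3\t30\nchr1\t300\n")
        with pytest.raises(ValueError, match=":2:"):
            read_sj_tab(str(p))

    @pytest.mark.parametrize("seed", range(5))
    def test_write_read_identity(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        t = JunctionTable("x")
        for _ in range(rng.integers(0, 30)):
            key = ("chr%d" % rng.integers(1, 4), int(rng.integers(1, 10_000)),
                   int(rng.integers(10_000, 20_000)),
                   "+-."[rng.integers(0, 3)])
            t.add(key, int(rng.integers(0, 10_000)))
        path = tmp_path / "t.tab"
        write_sj_tab(t, str(path))
        assert read_sj_tab(str(path)) == t

    def test_count_beyond_format_bound_rejected(self, tmp_path):
        t = JunctionTable("x", {("chr1", 1, 2, "+"): 2**31})
        with pytest.raises(ValueError, match="32-bit"):
            write_sj_tab(t, str(tmp_path / "t.tab"))


class TestReadsTsvIO:
    def test_roundtrip(self, tmp_path):
        reads = [
            ReadRecord("r1", (("chrX", 10, 20, "+"), ("chrX", 40, 60, "+")), "alt"),
            ReadRecord("r2", (), "ref"),
            ReadRecord("r3", (("chrX", 10, 20, "+"),), None),
        ]
        p = tmp_path / "reads.tsv"
        write_reads_tsv(reads, str(p))
        assert read_reads_tsv(str(p), "chrX", "+") == reads


class TestDetection:
    def test_annotated_only_table_yields_nothing(self, models):
        m = models["MSH6"]
        t = JunctionTable("c", {k: 100 for k in m.annotated_junctions()})
        assert detect_aberrant(t, m) == []

    def test_cryptic_donor_plus_annotated_acceptor(self, models):
        m = models["LZTR1"]
        truth = event_from_r("r.1831_1942del", m)
        t = JunctionTable("c", {k: 100 for k in m.annotated_junctions()})
        t.add(event_junctions(truth, m)[0], 36)
        (ev,) = detect_aberrant(t, m)
        assert ev.symbol == "Δ16q"
        assert ev.removed == truth.removed

    def test_two_novel_junctions_merge_into_pseudoexon(self, models):
        m = models["APC"]
        truth = event_from_r("r.1408_1409ins1408+647_1408+744", m)
        t = JunctionTable("c", {k: 100 for k in m.annotated_junctions()})
        for key in event_junctions(truth, m):
            t.add(key, 27)
        (ev,) = detect_aberrant(t, m)
        assert ev.kind.value == "pseudoexon"
        from splicework.events import event_length

        assert event_length(ev, m) == 98

    def test_unpaired_deep_junction_is_incomplete_candidate(self, models):
        m = models["APC"]
        truth = event_from_r("r.1408_1409ins1408+647_1408+744", m)
        left, _ = event_junctions(truth, m)
        t = JunctionTable("c", {k: 100 for k in m.annotated_junctions()})
        t.add(left, 10)
        (ev,) = detect_aberrant(t, m)
        assert ev.incomplete
        # breakpoints unknown, but junction support still quantifies
        assert quantify_event(ev, t, m) == pytest.approx(100 * 10 / 110)


class TestQuantification:
    def _table(self, m, aberrant_key, a, n):
        t = JunctionTable("c", {k: n for k in m.annotated_junctions()})
        if a:
            t.add(aberrant_key, a)
        return t

    def test_fraction_formula(self, models):
        m = models["LZTR1"]
        ev = event_from_r("r.1831_1942del", m)
        key = event_junctions(ev, m)[0]
        assert quantify_event(ev, self._table(m, key, 36, 64), m) == 36.0
        assert quantify_event(ev, self._table(m, key, 0, 64), m) == 0.0
        assert quantify_event(
            ev, self._table(m, key, 36, 64), m, mode="literal"
        ) == pytest.approx(56.25)

    def test_scale_invariance(self, models):
        m = models["LZTR1"]
        ev = event_from_r("r.1831_1942del", m)
        key = event_junctions(ev, m)[0]
        p1 = quantify_event(ev, self._table(m, key, 17, 83), m)
        p2 = quantify_event(ev, self._table(m, key, 17 * 7, 83 * 7), m)
        assert p1 == pytest.approx(p2)

    def test_no_coverage_signalled(self, models):
        m = models["LZTR1"]
        ev = event_from_r("r.1831_1942del", m)
        with pytest.raises(NoCoverage):
            quantify_event(ev, JunctionTable("c"), m)

    def test_total_aberrant(self):
        assert total_aberrant([20.8, 1.6]) == pytest.approx(22.4)
        assert total_aberrant([27.0, 0.3]) == pytest.approx(27.3)
        assert total_aberrant([]) == 0.0


class TestAlleleFractions:
    def test_tag_snp_proportions(self, models):
        m = models["ATM"]
        novel = ("chr11", 1, 2, "+")  # any non-annotated junction
        ann = m.annotated_junctions()
        reads = (
            [ReadRecord(f"a{i}", (novel,), None) for i in range(414)]
            + [ReadRecord(f"m{i}", ann, "alt") for i in range(80)]
            + [ReadRecord(f"w{i}", ann, "ref") for i in range(506)]
        )
        split = allele_fulllength_fraction(reads, m)
        assert split["alt"] == pytest.approx(8.0)
        assert split["ref"] == pytest.approx(50.6)

    def test_no_alt_fulllength_supports_complete_impairment(self, models):
        m = models["LZTR1"]
        ann = m.annotated_junctions()
        novel = ("chr22", 1, 2, "+")
        reads = [ReadRecord(f"a{i}", (novel,), None) for i in range(38)] + [
            ReadRecord(f"w{i}", ann, "ref") for i in range(62)
        ]
        assert allele_fulllength_fraction(reads, m)["alt"] == 0.0

    def test_balanced_alleles_with_no_aberration(self, models):
        m = models["ATM"]
        ann = m.annotated_junctions()
        reads = [ReadRecord(f"m{i}", ann, "alt") for i in range(43)] + [
            ReadRecord(f"w{i}", ann, "ref") for i in range(57)
        ]
        split = allele_fulllength_fraction(reads, m)
        assert split == {"alt": pytest.approx(43.0), "ref": pytest.approx(57.0)}

    def test_intronic_variant_has_no_tag(self, models):
        m = models["FH"]
        reads = [ReadRecord("r1", m.annotated_junctions(), None)]
        assert allele_fulllength_fraction(reads, m) is None


class TestControlComparison:
    @pytest.mark.parametrize(
        "carrier,controls,expected",
        [
            (3.0, [0.3, 0.4, 0.6, 0.9, 1.3], True),
            (10.5, [0.35, 0.45, 0.0, 0.0, 0.0], True),
            (0.5, [0.6, 0.6, 0.6, 0.6, 0.6], False),
            (0.05, [0.0] * 5, False),  # below the absolute floor
            (1.1, [0.0] * 5, True),
        ],
    )
    def test_association_rule(self, carrier, controls, expected):
        associated, why = compare_to_controls(carrier, controls)
        assert associated is expected
        assert "carrier" in why

    def test_requires_controls(self):
        with pytest.raises(ValueError):
            compare_to_controls(1.0, [])
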