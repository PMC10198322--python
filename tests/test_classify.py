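"""Score-band classification, repeat tract detection, annotation pipeline."""

import re

import numpy as np
import pytest

from quadscan import (
    ProjectionModel,
    annotate_sequence,
    classify,
    find_dinucleotide_repeats,
    make_repeat_oligo,
    normalize_sequence,
    qs_score,
)
from quadscan.classify import MotifCall, refine_call, tract_calls

EPS = 1e-9


class TestClassify:
    @pytest.mark.parametrize(
        "qs, label",
        [
            (2.12, "ZG4_prone"),
            (2.0 + EPS, "ZG4_prone"),
            (2.0, "G4_candidate"),
            (1.2 + EPS, "G4_candidate"),
            (1.2, "tetrahelix_band"),
            (1.11, "tetrahelix_band"),
            (1.1, "tetrahelix_band"),
            (0.7, "tetrahelix_band"),
            (0.7 - EPS, "none"),
            (0.69, "none"),
            (0.0, "none"),
            (-1.2, "none"),
            (-1.2 - EPS, "imotif_candidate"),
            (-2.5, "imotif_candidate"),
        ],
    )
    def test_band_edges(self, qs, label):
        assert classify(qs) == label

    def test_total_function(self):
        for qs in np.linspace(-4, 4, 400):
            assert classify(float(qs)) in (
                "ZG4_prone",
                "G4_candidate",
                "tetrahelix_band",
                "imotif_candidate",
                "none",
            )


class TestRepeatFinder:
    def test_pure_repeat(self):
        tracts = find_dinucleotide_repeats("GT" * 6, min_repeats=6)
        assert len(tracts) == 1
        t = tracts[0]
        assert (t.unit, t.start, t.end, t.count, t.strand) == ("GT", 0, 12, 6, "+")
        assert not t.half_unit

    def test_no_tract_in_tetramer_repeat(self):
        assert find_dinucleotide_repeats("ACGT" * 3, min_repeats=6) == []

    def test_embedded_tract_offsets(self):
        rng = np.random.default_rng(11)
        left = "".join(rng.choice(list("ACGT"), 19)) + "C"
        right = "C" + "".join(rng.choice(list("ACGT"), 19))
        # C at both junctions so the tract cannot extend by chance
        seq = left + "GA" * 9 + right
        tracts = [
            t for t in find_dinucleotide_repeats(seq, min_repeats=8) if t.unit == "GA"
        ]
        assert len(tracts) == 1
        t = tracts[0]
        assert (t.start, t.end, t.count) == (20, 38, 9)

    def test_phase_and_half_unit(self):
        tracts = find_dinucleotide_repeats("TGTGTGTGTGTGT", min_repeats=6)
        assert len(tracts) == 1
        t = tracts[0]
        assert (t.unit, t.count, t.half_unit) == ("GT", 6, True)
        assert t.end - t.start == 2 * t.count

    def test_complement_strand(self):
        tracts = find_dinucleotide_repeats("CA" * 8, min_repeats=6)
        assert len(tracts) == 1
        assert (tracts[0].unit, tracts[0].strand) == ("GT", "-")

    def test_degenerate_unit_rejected(self):
        with pytest.raises(ValueError):
            find_dinucleotide_repeats("GGGG", units=("GG",))

    def test_palindromic_unit_scanned_once(self):
        tracts = find_dinucleotide_repeats(
            "AT" * 8, min_repeats=6, units=("AT",)
        )
        assert len(tracts) == 1  # complement is the same alternation

    def test_regex_oracle_on_random_sequences(self):
        """Agree with a direct regex enumeration on 1,000 random sequences."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = int(rng.integers(0, 80))
            seq = "".join(rng.choice(list("ACGT"), n))
            got = {
                (t.start, t.end, t.count, t.strand)
                for t in find_dinucleotide_repeats(seq, min_repeats=3, units=("GT",))
            }
            expected = set()
            for a, b, strand in (("G", "T", "+"), ("C", "A", "-")):
                pat = re.compile(f"{a}(?:{b}{a})*{b}?|{b}(?:{a}{b})*{a}?")
                for m in pat.finditer(seq):
                    count = (m.end() - m.start()) // 2
                    if count >= 3:
                        expected.add((m.start(), m.start() + 2 * count, count, strand))
            assert got == expected


class TestRefinementAndPipeline:
    def test_refine_recovers_tract_score_inside_window_call(self, model30):
        """A 16-nt tract diluted by a 25-nt window scores Z-G4 at its core."""
        rec = normalize_sequence("C" * 0 + "T" * 5 + "GT" * 8 + "A" * 4, "x")
        call = MotifCall("x", 0, rec.n, "+", 1.4, "G4_candidate")
        refined = refine_call(rec, call, model30)
        assert refined.qs > 2.0
        assert refined.label == "ZG4_prone"
        assert refined.core_end - refined.core_start >= 12

    def test_minus_strand_refinement(self, model30):
        rec = normalize_sequence("A" * 5 + "CA" * 8 + "T" * 5, "x")
        call = MotifCall("x", 0, rec.n, "-", -1.4, "imotif_candidate")
        refined = refine_call(rec, call, model30)
        assert refined.qs < -2.0
        assert refined.label == "imotif_candidate"

    def test_tract_calls_skip_unclassifiable(self, model30):
        rec = make_repeat_oligo("GA", 6)  # 0.6875: below every band
        tracts = find_dinucleotide_repeats(rec, min_repeats=6)
        assert tract_calls(rec, tracts, model30) == []

    def test_tract_calls_label_tetrahelix(self, model30):
        rec = make_repeat_oligo("GA", 9)
        calls = tract_calls(rec, find_dinucleotide_repeats(rec), model30)
        assert [c.label for c in calls] == ["tetrahelix_band"]

    def test_annotate_combines_routes(self):
        """Tract route finds the short Z-G4 repeat; calls are disjoint."""
        rec = normalize_sequence("AC" * 2 + "GT" * 8 + "TTAACC" * 10, "x")
        calls = annotate_sequence(rec)
        zg4 = [c for c in calls if c.label == "ZG4_prone"]
        assert len(zg4) == 1
        assert zg4[0].overlaps(4, 20)
        by_strand = {}
        for c in calls:
            by_strand.setdefault(c.strand, []).append(c)
        for group in by_strand.values():
            group.sort(key=lambda c: c.start)
            for a, b in zip(group, group[1:]):
                assert a.end <= b.start

    def test_reference_repeat_oligos_land_in_their_bands(self, model30):
        for count, expected in [(6, "ZG4_prone"), (9, "ZG4_prone")]:
            rec = make_repeat_oligo("GT", count)
            assert classify(qs_score(rec, model30)) == expected
        for count, expected in [(9, "tetrahelix_band"), (27, "tetrahelix_band")]:
            rec = make_repeat_oligo("GA", count)
            assert classify(qs_score(rec, model30)) == expected
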