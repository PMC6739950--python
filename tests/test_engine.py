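import random

import numpy as np
import pytest

from karyoconvert import (
    CNDelta,
    GenomicInterval,
    accumulate,
    build_profile,
    classify,
    clone_baseline,
    convert_one,
    event_deltas,
    parse_karyotype,
    parse_term,
)


def clone_of(karyotype):
    return parse_karyotype(karyotype).clones[0]


def deltas_of(term, hg19, karyotype="46,XY"):
    (ab,) = parse_term(term)
    ds, warns = event_deltas(ab, hg19, clone_of(karyotype))
    return [(d.interval.chrom, d.interval.start, d.interval.end, d.delta)
            for d in ds], warns


class TestEventDeltas:
    def test_whole_arm_derivative_loses_unretained_arms(self, hg19):
        ds, _ = deltas_of("der(1;19)(q10;p10)", hg19)
        assert ds == [
            ("chr1", 0, 125000000, -1),
            ("chr19", 26500000, 59128983, -1),
        ]

    def test_supernumerary_derivative_gains_both_pieces(self, hg19):
        ds, _ = deltas_of("+der(10)t(10;21)(p13;q21)", hg19)
        assert sorted(ds) == [
            ("chr10", 12200000, 135534747, 1),
            ("chr21", 16400000, 48129895, 1),
        ]

    def test_balanced_translocation_produces_nothing(self, hg19):
        ds, warns = deltas_of("t(9;22)(q34;q11)", hg19)
        assert ds == [] and warns == []

    def test_balanced_inversion_produces_nothing(self, hg19):
        ds, _ = deltas_of("inv(16)(p13q22)", hg19)
        assert ds == []

    def test_interstitial_deletion_spans_both_breakpoint_bands(self, hg19):
        # oracle: min start of Xq21.31, max end of Xq27.2 from the table
        lo = hg19.resolve_band("chrX", "q21.31").start
        hi = hg19.resolve_band("chrX", "q27.2").end
        ds, _ = deltas_of("del(X)(q21.31q27.2)", hg19)
        assert ds == [("chrX", lo, hi, -1)]
        assert (lo, hi) == (86200000, 142100000)

    def test_terminal_deletion_runs_to_telomere(self, hg19):
        ds, _ = deltas_of("del(5)(q13)", hg19)
        b = hg19.resolve_band("chr5", "q13")
        assert ds == [("chr5", b.start, hg19.chrom_length("chr5"), -1)]
        ds, _ = deltas_of("del(5)(p13)", hg19)
        b = hg19.resolve_band("chr5", "p13")
        assert ds == [("chr5", 0, b.end, -1)]

    def test_duplication_and_triplication(self, hg19):
        lo = hg19.resolve_band("chr1", "q21").start
        hi = hg19.resolve_band("chr1", "q32").end
        assert deltas_of("dup(1)(q21q32)", hg19)[0] == [("chr1", lo, hi, 1)]
        assert deltas_of("trp(1)(q21q32)", hg19)[0] == [("chr1", lo, hi, 2)]

    def test_isochromosome_replacing_a_homolog(self, hg19):
        ds, _ = deltas_of("i(17q)", hg19)
        assert sorted(ds) == [
            ("chr17", 0, 24000000, -1),        # p arm lost
            ("chr17", 24000000, 81195210, 1),  # q arm gained
        ]

    def test_supernumerary_isochromosome_gains_two_arm_copies(self, hg19):
        ds, _ = deltas_of("+i(17q)", hg19)
        assert ds == [("chr17", 24000000, 81195210, 2)]

    def test_iso_conserves_material_at_band_level(self, hg19):
        # i(17q) without "+": arm coverage +1 on q exactly balances -1 on p
        ds, _ = deltas_of("i(17q)", hg19)
        assert sum(d for (_, _, _, d) in ds) == 0

    def test_unbalanced_derivative_loses_distal_base_gains_donor(self, hg19):
        ds, _ = deltas_of("der(9)t(9;22)(p21;q11)", hg19)
        b9 = hg19.resolve_band("chr9", "p21")
        b22 = hg19.resolve_band("chr22", "q11")
        assert sorted(ds) == sorted(
            [
                ("chr9", 0, b9.start, -1),       # distal p material lost
                ("chr22", b22.start, hg19.chrom_length("chr22"), 1),
            ]
        )

    def test_unbalanced_derivative_at_a_telomeric_band_loses_nothing(self, hg19):
        # 9q34 reaches the telomere: the whole base chromosome is retained
        ds, _ = deltas_of("der(9)t(9;22)(q34;q11)", hg19)
        b22 = hg19.resolve_band("chr22", "q11")
        assert ds == [("chr22", b22.start, hg19.chrom_length("chr22"), 1)]

    def test_three_way_derivative_assembles_sequential_pieces(self, hg19):
        ds, _ = deltas_of("+der(1)t(1;3)(p32;q21)t(3;7)(q28;q11)", hg19)
        b1 = hg19.resolve_band("chr1", "p32")
        e3 = hg19.resolve_band("chr3", "q21")
        x3 = hg19.resolve_band("chr3", "q28")
        b7 = hg19.resolve_band("chr7", "q11")
        assert sorted(ds) == sorted(
            [
                ("chr1", b1.start, hg19.chrom_length("chr1"), 1),
                ("chr3", e3.start, x3.end, 1),
                ("chr7", b7.start, hg19.chrom_length("chr7"), 1),
            ]
        )

    def test_add_loses_distal_material_only(self, hg19):
        ds, _ = deltas_of("add(9)(p21)", hg19)
        b = hg19.resolve_band("chr9", "p21")
        assert ds == [("chr9", 0, b.start, -1)]

    def test_ring_loses_both_telomeric_caps(self, hg19):
        ds, _ = deltas_of("r(7)(p15q35)", hg19)
        b1 = hg19.resolve_band("chr7", "p15")
        b2 = hg19.resolve_band("chr7", "q35")
        assert sorted(ds) == sorted(
            [
                ("chr7", 0, b1.start, -1),
                ("chr7", b2.end, hg19.chrom_length("chr7"), -1),
            ]
        )

    def test_bare_ring_and_marker_warn_and_contribute_nothing(self, hg19):
        for term in ["+r", "+mar", "dmin", "hsr"]:
            ds, warns = deltas_of(term, hg19)
            assert ds == []
            assert warns

    def test_unresolvable_band_skips_with_warning(self, hg19):
        ds, warns = deltas_of("del(5)(q99)", hg19)
        assert ds == []
        assert any("del(5)(q99)" in w.term for w in warns)


class TestCloneBaseline:
    def test_structural_x_aberration_implies_second_x(self, hg19):
        clone = clone_of("46,X,del(X)(q21.31q27.2)")
        assert clone_baseline(clone, hg19)["chrX"] == 2

    def test_male_sex_chromosomes(self, hg19):
        base = clone_baseline(clone_of("46,XY,del(5)(q13)"), hg19)
        assert base["chrX"] == 1 and base["chrY"] == 1
        assert base["chr5"] == 2

    def test_ploidy_marker_scales_autosomes(self, hg19):
        clone = clone_of("69<3n>,XXX,+8")
        assert clone_baseline(clone, hg19)["chr8"] == 3

    def test_supernumerary_structural_does_not_raise_baseline(self, hg19):
        clone = clone_of("47,XX,+der(X)t(X;1)(q21;q21)")
        assert clone_baseline(clone, hg19)["chrX"] == 2


class TestAccumulate:
    def test_cancellation(self):
        ds = [
            CNDelta(GenomicInterval("chr1", 0, 100), 1),
            CNDelta(GenomicInterval("chr1", 0, 100), -1),
        ]
        assert accumulate(ds) == []

    def test_overlap_stacks(self):
        ds = [
            CNDelta(GenomicInterval("chr1", 0, 60), -1),
            CNDelta(GenomicInterval("chr1", 40, 100), -1),
        ]
        segs = [(s.start, s.end, s.delta) for s in accumulate(ds)]
        assert segs == [(0, 40, -1), (40, 60, -2), (60, 100, -1)]

    def test_adjacent_equal_deltas_merge(self):
        ds = [
            CNDelta(GenomicInterval("chr1", 0, 50), 1),
            CNDelta(GenomicInterval("chr1", 50, 100), 1),
        ]
        segs = [(s.start, s.end, s.delta) for s in accumulate(ds)]
        assert segs == [(0, 100, 1)]

    def test_matches_per_base_counting_on_random_sets(self):
        # oracle: integer array accumulation on toy chromosomes <= 1000 bp
        rng = random.Random(42)
        for _ in range(200):
            length = rng.randint(10, 1000)
            deltas = []
            for _ in range(rng.randint(1, 8)):
                a = rng.randrange(0, length)
                b = rng.randrange(a + 1, length + 1)
                deltas.append(
                    CNDelta(GenomicInterval("chr1", a, b), rng.choice([-2, -1, 1, 2]))
                )
            arr = np.zeros(length, dtype=int)
            for d in deltas:
                arr[d.interval.start : d.interval.end] += d.delta
            expected = []
            pos = 0
            while pos < length:
                if arr[pos] == 0:
                    pos += 1
                    continue
                end = pos
                while end < length and arr[end] == arr[pos]:
                    end += 1
                expected.append(("chr1", pos, end, int(arr[pos])))
                pos = end
            got = [(s.chrom, s.start, s.end, s.delta) for s in accumulate(deltas)]
            assert got == expected


class TestClassify:
    @pytest.mark.parametrize(
        "delta,baseline,label,zygosity",
        [
            (1, 2, "Gain", "not_applicable"),
            (2, 2, "Gain", "not_applicable"),
            (-1, 2, "Loss", "hemizygous"),
            (-2, 2, "Loss", "homozygous"),
            (-3, 2, "Loss", "homozygous"),   # clamped at zero copies
            (-1, 1, "Loss", "homozygous"),
            (1, 1, "Gain", "not_applicable"),
        ],
    )
    def test_labels(self, delta, baseline, label, zygosity):
        c = classify(delta, baseline)
        assert (c.label, c.zygosity) == (label, zygosity)


class TestProfiles:
    @pytest.mark.parametrize("karyotype", ["46,XX", "46,XY"])
    def test_normal_karyotypes_produce_no_output(self, hg19, karyotype):
        res = convert_one(karyotype, hg19)
        assert res.rows == []

    def test_dup_and_del_with_same_breakpoints_cancel(self, hg19):
        res = convert_one("46,XX,dup(1)(q21q32),del(1)(q21q32)", hg19)
        assert res.rows == []

    def test_sex_field_alone_never_generates_deltas(self, hg19):
        # a lone X sex field is not compared against a female reference
        res = convert_one("45,X", hg19)
        assert res.rows == []

    def test_over_subtraction_clamps_with_warning(self, hg19):
        clone = clone_of("43,XY,-5,-5,-5")
        prof = build_profile(clone, hg19)
        (seg,) = prof.segments
        assert seg.delta == -3
        assert classify(seg.delta, prof.baseline["chr5"]).zygosity == "homozygous"
        assert any("clamped" in w.message for w in prof.warnings)

    def test_segments_stay_inside_bounds_and_disjoint(self, hg19):
        res = convert_one(
            "48,XX,+8,del(8)(q22),dup(8)(p11p21),i(17q),+der(3)t(3;5)(q21;q31)",
            hg19,
        )
        by_chrom = {}
        for r in res.rows:
            assert 0 <= r.start < r.end <= hg19.chrom_length(r.chrom)
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        for ivs in by_chrom.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 <= s2
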