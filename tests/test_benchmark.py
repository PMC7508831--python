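"""Exclusion-rule fixtures, repeat detectors vs oracles, benchmark
assembly invariants, and liftover."""

import numpy as np
import pytest

from oracles import homopolymer_oracle, tandem_oracle

from diplobench.align import DiploidCallset
from diplobench.benchmark import (
    BenchmarkConfig,
    LiftoverSpec,
    build_benchmark,
    dense_exclusions,
    detect_homopolymers,
    detect_tandem_repeats,
    liftover_regions,
    liftover_variants,
    lowconf_regions,
    sv_exclusions,
)
from diplobench.intervals import GenomicInterval, IntervalSet
from diplobench.variants import SmallVariant


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def snv(pos, chrom="locus", gt=(1, 0)):
    return SmallVariant(chrom, pos, "A", ("G",), gt)


def callset(variants, dip=((0, 100_000),), chrom="locus"):
    return DiploidCallset(
        variants=list(variants),
        dip_regions=IntervalSet.from_tuples(
            [(chrom, s, e) for s, e in dip]
        ),
    )


def spans(iset):
    return [(iv.start, iv.end) for iv in iset]


class TestHomopolymers:
    # flanks with no 2-periodicity, so they cannot chain into
    # imperfect homopolymers themselves
    LEFT = "ACGT" * 25   # ends in T
    RIGHT = "CGTA" * 25  # starts with C

    def test_eleven_base_run_padded_five(self):
        seq = self.LEFT + "A" * 11 + self.RIGHT
        p = 100
        assert spans(detect_homopolymers(seq)) == [(p - 5, p + 11 + 5)]

    def test_ten_base_run_not_flagged(self):
        seq = self.LEFT + "C" * 10 + self.RIGHT[1:]
        assert detect_homopolymers(seq).is_empty()

    def test_imperfect_run_with_single_interruption_flagged(self):
        seq = self.LEFT + "AAAAATAAAAA" + self.RIGHT
        p = 100
        assert spans(detect_homopolymers(seq)) == [(p - 5, p + 11 + 5)]

    def test_double_interruption_breaks_run(self):
        seq = self.LEFT + "AAAAATTAAAAA" + self.RIGHT
        assert detect_homopolymers(seq).is_empty()

    def test_matches_regex_oracle_on_random_sequences(self, rng):
        for _ in range(10):
            # AT-rich alphabet makes long runs common
            seq = "".join(
                np.array(list("AATT GC".replace(" ", "")))[
                    rng.integers(0, 6, 10_000)
                ]
            )
            got = spans(detect_homopolymers(seq))
            assert got == homopolymer_oracle(seq)


class TestTandemRepeats:
    def test_dinucleotide_array_detected(self):
        seq = "GTTGCATGCA" + "AC" * 6 + "GATCCTGGAC"
        assert spans(detect_tandem_repeats(seq)) == [(10, 22)]

    def test_no_array_without_two_copies_spanning_min(self):
        assert detect_tandem_repeats("ACGTACGA").is_empty()

    def test_planted_trinucleotide_array_detected_exactly(self, rng):
        left = random_seq(rng, 500)
        right = random_seq(rng, 500)
        seq = left + "AGC" * 8 + right
        got = detect_tandem_repeats(seq)
        oracle = tandem_oracle(seq)
        assert spans(got) == oracle
        assert any(s <= 500 and e >= 524 for s, e in spans(got))

    def test_matches_period_scan_oracle(self, rng):
        for _ in range(5):
            seq = "".join(
                np.array(list("AC"))[rng.integers(0, 2, 2000)]
            )  # two-letter alphabet is repeat-dense
            assert spans(detect_tandem_repeats(seq)) == tandem_oracle(seq)


class TestLowconf:
    def af(self, pos, fraction):
        return SmallVariant("locus", pos, "A", ("G",), (1, 0),
                            allele_fraction=fraction)

    def test_five_midfraction_variants_form_one_region(self):
        vs = [self.af(p, 0.4) for p in (1000, 3000, 5000, 7000, 9000)]
        assert spans(lowconf_regions(vs)) == [(950, 9050)]

    def test_high_fraction_variant_ignored(self):
        assert lowconf_regions([self.af(5000, 0.9)]).is_empty()

    def test_af_boundaries_inclusive(self):
        vs = [self.af(p, f) for p, f in ((1000, 0.25), (2000, 0.75))]
        assert spans(lowconf_regions(vs)) == [(950, 2050)]

    def test_distant_variants_split_then_size_filtered(self):
        vs = [self.af(1000, 0.5), self.af(25_000, 0.5)]
        # two singleton clusters, each 100 bp after padding: both dropped
        assert lowconf_regions(vs).is_empty()

    def test_matches_brute_force_clustering(self, rng):
        cfg = BenchmarkConfig()
        pos = sorted(int(p) for p in rng.integers(0, 200_000, 60))
        vs = [self.af(p, 0.5) for p in pos]
        got = spans(lowconf_regions(vs))
        # oracle: split where gap > lc_cluster, pad, filter by size
        clusters, cur = [], [pos[0]]
        for p in pos[1:]:
            if p - cur[-1] <= cfg.lc_cluster:
                cur.append(p)
            else:
                clusters.append(cur)
                cur = [p]
        clusters.append(cur)
        expect = []
        for c in clusters:
            s, e = max(0, c[0] - cfg.lc_pad), c[-1] + cfg.lc_pad
            if e - s >= cfg.lc_min_size:
                expect.append((s, e))
        assert got == expect


class TestSvExclusions:
    def deletion(self, pos, size):
        return SmallVariant("locus", pos, "A" * (size + 1), ("A",), (1, 0))

    def test_sixty_bp_deletion_padded(self):
        cs = callset([self.deletion(5000, 60)])
        assert spans(sv_exclusions(cs, IntervalSet())) == [(4950, 5111)]

    def test_overlapping_tandem_repeat_expands_region(self):
        cs = callset([self.deletion(5000, 60)])
        trs = IntervalSet.from_tuples([("locus", 4990, 5100)])
        assert spans(sv_exclusions(cs, trs)) == [(4940, 5150)]

    def test_49bp_indel_not_structural(self):
        cs = callset([self.deletion(5000, 48)])  # max allele len 49
        assert sv_exclusions(cs, IntervalSet()).is_empty()

    def test_nearby_svs_merge_within_1kb(self):
        cs = callset([self.deletion(5000, 60), self.deletion(6000, 60)])
        got = spans(sv_exclusions(cs, IntervalSet()))
        assert len(got) == 1


class TestDenseExclusions:
    def test_21_consecutive_snvs_excluded_with_pad(self):
        cs = callset([snv(1000 + i) for i in range(21)])
        assert spans(dense_exclusions(cs)) == [(990, 1031)]

    def test_11_isolated_snvs_fail_stage_two(self):
        cs = callset([snv(1000 + i) for i in range(11)])
        assert dense_exclusions(cs).is_empty()

    def test_9_clustered_snvs_fail_stage_one(self):
        cs = callset([snv(1000 + i) for i in range(9)])
        assert dense_exclusions(cs).is_empty()

    def test_two_stage1_clusters_combine_across_1kb(self):
        cs = callset(
            [snv(1000 + i) for i in range(11)]
            + [snv(1500 + i) for i in range(11)]
        )
        got = spans(dense_exclusions(cs))
        assert got == [(990, 1521)]

    def test_or_reading_flag(self):
        cs = callset([snv(1000 + i) for i in range(11)])
        cfg = BenchmarkConfig(dense_two_stage_and=False)
        assert spans(dense_exclusions(cs, cfg)) == [(990, 1021)]


class TestBuildBenchmark:
    def empty(self):
        return IntervalSet()

    def test_no_exclusions_keeps_dip_regions(self):
        cs = callset([], dip=((0, 10_000),))
        regions = build_benchmark(
            cs, self.empty(), self.empty(), self.empty(), self.empty()
        )
        assert regions.included == cs.dip_regions
        assert regions.audit["included_bp"] == 10_000

    def test_exclusion_splits_interval(self):
        cs = callset([], dip=((0, 10_000),))
        excl = IntervalSet.from_tuples([("locus", 4000, 5000)])
        regions = build_benchmark(
            cs, excl, self.empty(), self.empty(), self.empty()
        )
        assert spans(regions.included) == [(0, 4000), (5000, 10_000)]
        assert regions.audit["lowconf_bp"] == 1000

    def test_included_disjoint_from_every_exclusion(self):
        cs = callset([snv(1000 + i) for i in range(25)], dip=((0, 50_000),))
        sv = IntervalSet.from_tuples([("locus", 20_000, 20_500)])
        hp = IntervalSet.from_tuples([("locus", 30_000, 30_020)])
        regions = build_benchmark(
            cs, self.empty(), sv, dense_exclusions(cs), hp
        )
        for excl in regions.exclusions.values():
            assert regions.included.intersect(excl).is_empty()

    def test_partially_covered_repeat_trimmed_entirely(self):
        cs = callset([], dip=((0, 10_000),))
        hp = IntervalSet.from_tuples([("locus", 4000, 4020)])
        # repeat straddles the boundary created by an exclusion
        trim = IntervalSet.from_tuples([("locus", 3990, 4010)])
        regions = build_benchmark(
            cs, self.empty(), self.empty(), self.empty(), hp,
            repeats_for_trim=trim,
        )
        # after the homopolymer cut, [3990,4010) is only partially
        # inside: it must be removed outright
        assert not regions.included.covers_point("locus", 3995)
        for iv in trim:
            assert (
                regions.included.contains_interval(iv)
                or regions.included.intersect(
                    IntervalSet([iv])
                ).is_empty()
            )

    def test_adding_variants_never_grows_benchmark(self):
        base_vars = [snv(1000 + i) for i in range(25)]
        dip = ((0, 50_000),)
        extra = base_vars + [
            SmallVariant("locus", 30_000, "A" * 61, ("A",), (1, 0))
        ]
        trs = IntervalSet()

        def build(vs):
            cs = callset(vs, dip=dip)
            return build_benchmark(
                cs, self.empty(), sv_exclusions(cs, trs),
                dense_exclusions(cs), self.empty(),
            )

        before = build(base_vars).included
        after = build(extra).included
        assert after.subtract(before).is_empty()


class TestLiftover:
    def test_vcf_pos_shift(self):
        v = SmallVariant("6", 28_477_797, "A", ("G",), (1, 0))
        (lifted,), dropped = liftover_variants([v])
        # 0-based 28477797 is VCF POS 28477798; +32223 -> POS 28510021
        assert lifted.chrom == "chr6"
        assert lifted.pos + 1 == 28_510_021
        assert not dropped

    def test_known_discrepant_site_dropped(self):
        # the single base differing between source and target assemblies
        v = SmallVariant("6", 28_719_765 - 32_223 - 1, "T", ("C",), (1, 1))
        lifted, dropped = liftover_variants([v])
        assert lifted == [] and len(dropped) == 1

    def test_bed_uniform_shift(self):
        got = liftover_regions(
            IntervalSet.from_tuples([("6", 100, 200)])
        )
        assert spans(got) == [(32_323, 32_423)]

    def test_roundtrip_restores_input(self):
        vs = [
            SmallVariant("6", 1000, "A", ("G",), (1, 0)),
            SmallVariant("6", 28_719_765 - 32_223 - 1, "T", ("C",), (1, 1)),
        ]
        lifted, dropped = liftover_variants(vs)
        back_spec = LiftoverSpec(
            offset=-32_223, drop_sites=(), chrom_rename=(("chr6", "6"),)
        )
        restored, _ = liftover_variants(lifted + dropped, back_spec)
        assert sorted(restored, key=lambda v: v.pos) == vs

    def test_negative_coordinates_rejected(self):
        v = SmallVariant("6", 10, "A", ("G",), (1, 0))
        with pytest.raises(ValueError):
            liftover_variants([v], LiftoverSpec(offset=-1000))
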