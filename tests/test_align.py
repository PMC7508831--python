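"""Minimizer anchoring, O(ND) alignment, divergence track, variant
extraction and diploid merge."""

import numpy as np
import pytest

from oracles import dp_indel_distance

from diplobench.align import (
    AlignConfig,
    BlockAlignment,
    anchor_and_chain,
    build_divergence_track,
    extract_variants,
    merge_diploid,
    ond_align,
    piecewise_align,
    reconstruct_haplotig,
    script_d,
)
from diplobench.intervals import IntervalSet
from diplobench.simulate import SimConfig, simulate_truth
from diplobench.variants import SmallVariant, apply_variants


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def apply_script(a, b, script):
    """Replay an edit script: consumes a via match/del, b via match/ins."""
    out = []
    i = j = 0
    for op, ln in script:
        if op == "match":
            assert a[i : i + ln] == b[j : j + ln]
            out.append(a[i : i + ln])
            i += ln
            j += ln
        elif op == "del":
            i += ln
        else:
            out.append(b[j : j + ln])
            j += ln
    assert i == len(a) and j == len(b)
    return "".join(out)


class TestOndAlign:
    @pytest.mark.parametrize(
        "a,b,d",
        [
            ("GCAT", "GCAT", 0),
            ("ACGT", "AGT", 1),
            ("ABCABBA", "CBABAC", 5),  # the classic worked example
            ("", "ACGT", 4),
            ("ACGT", "", 4),
        ],
    )
    def test_known_distances(self, a, b, d):
        res = ond_align(a, b, 100)
        assert res.aligned and res.D == d
        assert apply_script(a, b, res.script) == b

    def test_matches_quadratic_dp_oracle(self, rng):
        for _ in range(200):
            n, m = rng.integers(0, 200, size=2)
            a = random_seq(rng, n)
            b = random_seq(rng, m)
            res = ond_align(a, b, n + m + 1)
            assert res.D == dp_indel_distance(a, b)
            assert apply_script(a, b, res.script) == b

    def test_d_max_exceeded_reports_unaligned(self):
        res = ond_align("A" * 50, "C" * 50, 10)
        assert not res.aligned

    def test_divergence_definition(self):
        res = ond_align("AAAA", "AATAA", 10)
        assert res.D == 1 and res.divergence == 1 / 5

    def test_negative_budget_rejected(self):
        with pytest.raises(ValueError):
            ond_align("A", "A", -1)


class TestAnchorChain:
    def test_identity_chain_covers_sequence(self, rng):
        cfg = AlignConfig()
        seq = random_seq(rng, 5000)
        chain = anchor_and_chain(seq, seq, cfg)
        assert chain.score > 0
        assert all(q == t for q, t, _ in chain.anchors)
        first_q = chain.anchors[0][0]
        last_q = chain.anchors[-1][0] + chain.anchors[-1][2]
        assert last_q - first_q >= len(seq) - cfg.minimizer_k - cfg.minimizer_w

    def test_insertion_shifts_diagonal_by_its_length(self, rng):
        cfg = AlignConfig()
        target = random_seq(rng, 4000)
        query = target[:2000] + random_seq(rng, 100) + target[2000:]
        chain = anchor_and_chain(query, target, cfg)
        offsets = {q - t for q, t, _ in chain.anchors}
        assert offsets == {0, 100}

    def test_unrelated_sequences_produce_no_usable_chain(self, rng):
        cfg = AlignConfig()
        for _ in range(20):
            a, b = random_seq(rng, 10_000), random_seq(rng, 10_000)
            chain = anchor_and_chain(a, b, cfg)
            assert chain.score < cfg.min_chain_anchors

    def test_colinearity_invariant(self, rng):
        target = random_seq(rng, 6000)
        query = target[:3000] + "TT" + target[3000:]
        chain = anchor_and_chain(query, target)
        qs = [q for q, _, _ in chain.anchors]
        ts = [t for _, t, _ in chain.anchors]
        assert qs == sorted(qs) and ts == sorted(ts)
        assert len(set(ts)) == len(ts)


class TestPiecewiseAlign:
    def test_identity_alignment_is_flat(self, rng):
        ref = random_seq(rng, 30_000)
        blocks, track = piecewise_align(ref, ref)
        assert len(blocks) == 1
        assert all(w.aligned and w.est_difference == 0 for w in track.windows)

    def test_planted_divergence_shows_in_track(self, rng):
        """2% SNV divergence in a 20 kb segment reads out at 1-3% in the
        windows there and ~0 elsewhere."""
        ref = random_seq(rng, 100_000)
        q = list(ref)
        n_mut = 0
        for i in range(40_000, 60_000):
            if rng.random() < 0.02:
                q[i] = "ACGT"[("ACGT".index(q[i]) + 1) % 4]
                n_mut += 1
        blocks, track = piecewise_align("".join(q), ref)
        inside = [
            w.est_difference
            for w in track.windows
            if 41_000 <= w.interval.start < 59_000
        ]
        outside = [
            w.est_difference
            for w in track.windows
            if w.interval.end <= 39_000 or w.interval.start >= 61_000
        ]
        # each substitution costs one del + one ins in the edit script:
        # est_difference doubles the SNV rate
        assert 0.02 <= float(np.mean(inside)) <= 0.06
        assert float(np.mean(outside)) < 0.005

    def test_hyperdivergent_segment_flagged_unaligned(self, rng):
        """A 30%-divergent 50 kb segment becomes an alignment gap, not a
        forced alignment."""
        ref = random_seq(rng, 150_000)
        q = list(ref)
        for i in range(50_000, 100_000):
            if rng.random() < 0.30:
                q[i] = "ACGT"[("ACGT".index(q[i]) + 1) % 4]
        blocks, track = piecewise_align("".join(q), ref)
        gap = track.unaligned_regions()
        middle = IntervalSet.from_tuples([("locus", 52_000, 98_000)])
        assert gap.intersect(middle).total_bp() >= 0.9 * middle.total_bp()
        flank = IntervalSet.from_tuples(
            [("locus", 1_000, 48_000), ("locus", 102_000, 149_000)]
        )
        assert gap.intersect(flank).total_bp() == 0

    def test_reverse_complement_haplotig_recovers_alignment(self, rng):
        from diplobench.kmers import reverse_complement

        ref = random_seq(rng, 20_000)
        blocks, track = piecewise_align(reverse_complement(ref), ref)
        assert sum(w.aligned for w in track.windows) >= 18


class TestExtractVariants:
    def make_blocks(self, ref, hap):
        blocks, _ = piecewise_align(hap, ref)
        return blocks

    def test_single_mismatch_becomes_snv(self, rng):
        ref = random_seq(rng, 3000)
        q = list(ref)
        q[1500] = "ACGT"[("ACGT".index(q[1500]) + 1) % 4]
        hap = "".join(q)
        variants, covered = extract_variants(
            self.make_blocks(ref, hap), ref, hap
        )
        assert len(variants) == 1
        v = variants[0]
        assert (v.pos, v.ref, v.alt) == (1500, ref[1500], hap[1500])
        assert v.is_snv

    def test_deletion_left_aligned_with_context_base(self, rng):
        # plant an unambiguous context then a deletable repeat
        core = random_seq(rng, 1000) + "GGTACACACGG" + random_seq(rng, 1000)
        ref = core
        # delete the "AC" at the right edge of the repeat: canonical
        # representation anchors at the repeat start
        cut = ref.index("GGTACACACGG") + 6
        hap = ref[:cut] + ref[cut + 2 :]
        variants, _ = extract_variants(self.make_blocks(ref, hap), ref, hap)
        assert len(variants) == 1
        v = variants[0]
        anchor = ref.index("GGTACACACGG") + 2
        assert (v.pos, v.ref, v.alt) == (anchor, "TAC", "T")

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_roundtrip_identity_on_simulated_loci(self, seed):
        """apply(extract(align)) reproduces the haplotig exactly over
        covered intervals."""
        cfg = SimConfig(seed=seed, locus_length=120_000)
        truth = simulate_truth(cfg)
        for h in (1, 2):
            hap = truth.hap(h)
            blocks, _ = piecewise_align(hap, truth.reference)
            variants, covered = extract_variants(blocks, truth.reference, hap)
            for blk in blocks:
                if not blk.aligned:
                    continue
                q0, q1 = blk.query_interval
                assert (
                    reconstruct_haplotig(truth.reference, variants, blk)
                    == hap[q0:q1]
                )

    def test_covered_equals_aligned_blocks(self, rng):
        ref = random_seq(rng, 10_000)
        blocks = self.make_blocks(ref, ref)
        _, covered = extract_variants(blocks, ref, ref)
        assert covered.total_bp() == sum(
            t1 - t0 for blk in blocks for t0, t1 in [blk.target_interval]
        )


class TestMergeDiploid:
    def cov(self, *tuples):
        return IntervalSet.from_tuples([("locus", s, e) for s, e in tuples])

    def test_hap1_only_variant_is_1_0(self):
        v = SmallVariant("locus", 100, "A", ("G",), (1, 1))
        cs = merge_diploid(([v], self.cov((0, 1000))), ([], self.cov((0, 1000))))
        assert cs.variants[0].genotype == (1, 0)
        assert cs.variants[0].gt_string() == "1|0"

    def test_same_variant_on_both_is_hom(self):
        v = SmallVariant("locus", 100, "A", ("G",), (1, 1))
        cs = merge_diploid(([v], self.cov((0, 1000))), ([v], self.cov((0, 1000))))
        assert cs.variants[0].genotype == (1, 1)

    def test_different_alts_make_multiallelic(self, tmp_path):
        a = SmallVariant("locus", 100, "A", ("G",), (1, 1))
        b = SmallVariant("locus", 100, "A", ("T",), (1, 1))
        cs = merge_diploid(([a], self.cov((0, 1000))), ([b], self.cov((0, 1000))))
        (v,) = cs.variants
        assert v.alts == ("G", "T") and v.genotype == (1, 2)
        # survives a VCF round trip
        from diplobench.io import read_vcf, write_vcf

        path = tmp_path / "m.vcf"
        write_vcf(path, cs.variants, {"locus": 1000})
        (back,) = read_vcf(path)
        assert back.alts == ("G", "T") and back.genotype == (1, 2)

    def test_dip_regions_are_intersection(self):
        cs = merge_diploid(
            ([], self.cov((0, 500), (600, 1000))),
            ([], self.cov((200, 800))),
        )
        assert [(iv.start, iv.end) for iv in cs.dip_regions] == [
            (200, 500), (600, 800),
        ]

    def test_inconsistent_ref_rejected(self):
        a = SmallVariant("locus", 100, "A", ("G",), (1, 1))
        b = SmallVariant("locus", 100, "C", ("T",), (1, 1))
        with pytest.raises(ValueError):
            merge_diploid(([a], self.cov((0, 1000))), ([b], self.cov((0, 1000))))


class TestDivergenceTrack:
    def test_windows_tile_target(self):
        blocks = [
            BlockAlignment((0, 5000), (0, 5000), [("match", 5000)], 0, 0.0)
        ]
        track = build_divergence_track(blocks, 5500, window=1000)
        spans = [(w.interval.start, w.interval.end) for w in track.windows]
        assert spans == [(0, 1000), (1000, 2000), (2000, 3000),
                         (3000, 4000), (4000, 5000), (5000, 5500)]
        assert [w.aligned for w in track.windows] == [True] * 5 + [False]
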