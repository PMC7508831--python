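"""Rule-based benchmark-region construction.

Starting from the diploid callset's confidently-covered territory
(dip regions), the builder removes: read-back low-confidence clusters,
structural-variant neighbourhoods (expanded over overlapping tandem
repeats), hyper-dense variant clusters, long perfect/imperfect
homopolymers, and an externally supplied hyper-divergent annotation.
Finally any repeat interval only partially inside the remaining
territory is removed outright, so no repeat straddles a benchmark
boundary.  Variant records are never dropped from the callset — only
the evaluable regions shrink — and every rule logs the bp it removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .align import DiploidCallset
from .intervals import GenomicInterval, IntervalSet
from .variants import SmallVariant

logger = logging.getLogger(__name__)


@dataclass
class BenchmarkConfig:
    sv_min_size: int = 50
    sv_pad: int = 50
    sv_merge: int = 1_000
    dense_win1: int = 10
    dense_n1: int = 10
    dense_win2: int = 1_000
    dense_n2: int = 20
    dense_pad: int = 10
    hp_min_len: int = 11  # flag runs strictly longer than 10 bp
    hp_pad: int = 5
    af_low: float = 0.25
    af_high: float = 0.75
    lc_cluster: int = 10_000
    lc_pad: int = 50
    lc_min_size: int = 300
    tr_max_period: int = 6
    tr_min_span: int = 10
    # dense rule ambiguity: require both stages (AND) by default; the OR
    # reading excludes any stage-1 cluster of >dense_n1 variants outright
    dense_two_stage_and: bool = True

    def __post_init__(self) -> None:
        if self.af_low >= self.af_high:
            raise ValueError("af_low must be < af_high")


@dataclass
class LiftoverSpec:
    """Whole-locus coordinate shift between assemblies whose sequence is
    identical up to an offset and a handful of dropped sites."""

    offset: int = 32_223
    drop_sites: Tuple[Tuple[str, int], ...] = (("chr6", 28_719_765),)  # 1-based
    chrom_rename: Tuple[Tuple[str, str], ...] = (("6", "chr6"),)


@dataclass
class BenchmarkRegions:
    included: IntervalSet
    exclusions: Dict[str, IntervalSet]
    audit: Dict[str, int]


# ------------------------------------------------------------- detectors

def detect_homopolymers(
    reference: str,
    chrom: str = "locus",
    cfg: BenchmarkConfig | None = None,
) -> IntervalSet:
    """Perfect and imperfect homopolymers longer than 10 bp, padded.

    An imperfect homopolymer is a run of one base interrupted by
    isolated single non-matching bases, each flanked by at least one
    matching base on both sides.  Qualifying spans are padded by
    ``hp_pad`` on each side and merged.
    """
    cfg = cfg or BenchmarkConfig()
    n = len(reference)
    out: List[GenomicInterval] = []
    # maximal perfect runs, then greedy extension across single-base breaks
    runs: List[Tuple[int, int, str]] = []
    i = 0
    while i < n:
        j = i
        while j < n and reference[j] == reference[i]:
            j += 1
        runs.append((i, j, reference[i]))
        i = j
    ri = 0
    while ri < len(runs):
        s, e, base = runs[ri]
        rj = ri
        # absorb [1-base interruption][run of same base] repeatedly
        while (
            rj + 2 < len(runs)
            and runs[rj + 1][1] - runs[rj + 1][0] == 1
            and runs[rj + 2][2] == base
        ):
            rj += 2
            e = runs[rj][1]
        if e - s >= cfg.hp_min_len:
            out.append(
                GenomicInterval(
                    chrom, max(0, s - cfg.hp_pad), min(n, e + cfg.hp_pad)
                )
            )
        ri += 1
    return IntervalSet(out)


def detect_tandem_repeats(
    reference: str,
    chrom: str = "locus",
    max_period: int = 6,
    min_span: int = 10,
) -> IntervalSet:
    """Maximal perfect tandem arrays: unit length <= ``max_period``,
    at least two full copies, total span >= ``min_span``."""
    if max_period < 1:
        raise ValueError("max_period must be >= 1")
    n = len(reference)
    out: List[GenomicInterval] = []
    for p in range(1, max_period + 1):
        i = 0
        while i + p < n:
            if reference[i] != reference[i + p]:
                i += 1
                continue
            j = i
            while j + p < n and reference[j] == reference[j + p]:
                j += 1
            span = (j + p) - i  # array is [i, j+p)
            if span >= max(min_span, 2 * p):
                out.append(GenomicInterval(chrom, i, j + p))
            i = j + 1
    return IntervalSet(out)


# ------------------------------------------------------------- rule stages

def lowconf_regions(
    readback_variants: Sequence[SmallVariant],
    chrom: str = "locus",
    cfg: BenchmarkConfig | None = None,
) -> IntervalSet:
    """Low-confidence assembly regions from read-back variant calls.

    Variants with allele fraction in [af_low, af_high] (neither clearly
    absent nor clearly homozygous, i.e. reads disagree with the contig)
    are single-linkage clustered within ``lc_cluster`` bp; each cluster
    span is extended by ``lc_pad`` per side and kept if the extended
    region reaches ``lc_min_size``.
    """
    cfg = cfg or BenchmarkConfig()
    pos = sorted(
        v.pos
        for v in readback_variants
        if v.allele_fraction is not None
        and cfg.af_low <= v.allele_fraction <= cfg.af_high
    )
    out: List[GenomicInterval] = []
    i = 0
    while i < len(pos):
        j = i
        while j + 1 < len(pos) and pos[j + 1] - pos[j] <= cfg.lc_cluster:
            j += 1
        start = max(0, pos[i] - cfg.lc_pad)
        end = pos[j] + cfg.lc_pad
        if end - start >= cfg.lc_min_size:
            out.append(GenomicInterval(chrom, start, end))
        i = j + 1
    return IntervalSet(out)


def sv_exclusions(
    callset: DiploidCallset,
    tandem_repeats: IntervalSet,
    cfg: BenchmarkConfig | None = None,
) -> IntervalSet:
    """Structural-variant exclusion regions.

    Each variant with an allele >= ``sv_min_size`` is expanded over any
    overlapping tandem-repeat intervals, padded by ``sv_pad``, and the
    results merged when within ``sv_merge`` bp of each other.
    """
    cfg = cfg or BenchmarkConfig()
    regions: List[GenomicInterval] = []
    for v in callset.variants:
        if not v.is_sv(cfg.sv_min_size):
            continue
        start, end = v.pos, max(v.end, v.pos + 1)
        span = GenomicInterval(v.chrom, start, end)
        for tr in tandem_repeats.overlapping(span):
            start = min(start, tr.start)
            end = max(end, tr.end)
        regions.append(
            GenomicInterval(
                v.chrom, max(0, start - cfg.sv_pad), end + cfg.sv_pad
            )
        )
    return IntervalSet(regions).merge(cfg.sv_merge)


def dense_exclusions(
    callset: DiploidCallset,
    cfg: BenchmarkConfig | None = None,
) -> IntervalSet:
    """Hyper-dense variant clusters, excluded as likely mis-assembled or
    better described as structural events.

    Stage 1 single-linkage clusters variants within ``dense_win1`` bp
    and keeps clusters with more than ``dense_n1`` variants; stage 2
    merges kept clusters within ``dense_win2`` bp and (in the default
    AND reading) retains merged regions whose total variant count
    exceeds ``dense_n2``.  Surviving regions get ``dense_pad``.
    """
    cfg = cfg or BenchmarkConfig()
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for v in callset.variants:
        by_chrom.setdefault(v.chrom, []).append((v.pos, v.end))
    out: List[GenomicInterval] = []
    for chrom, spans in by_chrom.items():
        spans.sort()
        # stage 1
        clusters: List[Tuple[int, int, int]] = []  # (start, end, count)
        i = 0
        while i < len(spans):
            j = i
            end = spans[i][1]
            while j + 1 < len(spans) and spans[j + 1][0] - end <= cfg.dense_win1:
                j += 1
                end = max(end, spans[j][1])
            clusters.append((spans[i][0], end, j - i + 1))
            i = j + 1
        stage1 = [c for c in clusters if c[2] > cfg.dense_n1]
        if not cfg.dense_two_stage_and:
            out.extend(
                GenomicInterval(
                    chrom, max(0, s - cfg.dense_pad), e + cfg.dense_pad
                )
                for s, e, _ in stage1
            )
            continue
        # stage 2: merge kept clusters, sum counts
        i = 0
        while i < len(stage1):
            j = i
            s, e, cnt = stage1[i]
            while (
                j + 1 < len(stage1)
                and stage1[j + 1][0] - e <= cfg.dense_win2
            ):
                j += 1
                e = max(e, stage1[j][1])
                cnt += stage1[j][2]
            if cnt > cfg.dense_n2:
                out.append(
                    GenomicInterval(
                        chrom, max(0, s - cfg.dense_pad), e + cfg.dense_pad
                    )
                )
            i = j + 1
    return IntervalSet(out)


# --------------------------------------------------------------- assembly

def build_benchmark(
    callset: DiploidCallset,
    lowconf: IntervalSet,
    sv_excl: IntervalSet,
    dense_excl: IntervalSet,
    homopolymers: IntervalSet,
    divergent_annotation: IntervalSet | None = None,
    repeats_for_trim: IntervalSet | None = None,
    locus: IntervalSet | None = None,
) -> BenchmarkRegions:
    """Apply every exclusion rule to the dip regions and trim partially
    covered repeats.

    The audit reports both raw bp per rule and the bp each rule newly
    removed in application order (rules overlap, so raw counts sum to
    more than the total removed).  When the full ``locus`` extent is
    given, territory outside the dip regions is reported as the
    ``not_dip`` exclusion.
    """
    divergent = divergent_annotation or IntervalSet()
    trim_track = repeats_for_trim if repeats_for_trim is not None else homopolymers

    rules: List[Tuple[str, IntervalSet]] = [
        ("lowconf", lowconf),
        ("sv", sv_excl),
        ("dense", dense_excl),
        ("homopolymer", homopolymers),
        ("divergent", divergent),
    ]
    included = callset.dip_regions
    audit: Dict[str, int] = {"dip_bp": included.total_bp()}
    exclusions: Dict[str, IntervalSet] = {}
    if locus is not None:
        exclusions["not_dip"] = locus.subtract(callset.dip_regions)
        audit["not_dip_bp"] = exclusions["not_dip"].total_bp()
    for name, excl in rules:
        before = included.total_bp()
        clipped = excl.intersect(callset.dip_regions)
        included = included.subtract(excl)
        removed_new = before - included.total_bp()
        exclusions[name] = clipped
        audit[f"{name}_bp"] = clipped.total_bp()
        audit[f"{name}_bp_new"] = removed_new
        logger.info(
            "exclusion rule %-12s removed %8d bp (%d bp new)",
            name, clipped.total_bp(), removed_new,
        )

    # final pass: drop any repeat only partially inside the benchmark
    partial: List[GenomicInterval] = []
    for iv in trim_track:
        if included.overlapping(iv) and not included.contains_interval(iv):
            partial.append(iv)
    trim_set = IntervalSet(partial)
    before = included.total_bp()
    included = included.subtract(trim_set)
    exclusions["partial_repeat_trim"] = trim_set.intersect(
        callset.dip_regions
    )
    audit["partial_repeat_trim_bp"] = exclusions[
        "partial_repeat_trim"
    ].total_bp()
    audit["partial_repeat_trim_bp_new"] = before - included.total_bp()
    logger.info(
        "partial-repeat trim removed %d bp new",
        audit["partial_repeat_trim_bp_new"],
    )

    audit["included_bp"] = included.total_bp()
    audit["excluded_bp"] = audit["dip_bp"] - audit["included_bp"]
    return BenchmarkRegions(
        included=included, exclusions=exclusions, audit=audit
    )


# --------------------------------------------------------------- liftover

def liftover_variants(
    variants: Sequence[SmallVariant], spec: LiftoverSpec | None = None
) -> Tuple[List[SmallVariant], List[SmallVariant]]:
    """Shift VCF coordinates by a constant offset, renaming chromosomes
    and dropping listed sites.  Returns (lifted, dropped)."""
    spec = spec or LiftoverSpec()
    rename = dict(spec.chrom_rename)
    drop = set(spec.drop_sites)
    lifted: List[SmallVariant] = []
    dropped: List[SmallVariant] = []
    for v in variants:
        chrom = rename.get(v.chrom, v.chrom)
        pos = v.pos + spec.offset
        if pos < 0:
            raise ValueError(f"liftover yields negative position for {v}")
        shifted = SmallVariant(
            chrom, pos, v.ref, v.alts, v.genotype, v.phased,
            v.allele_fraction, v.filter,
        )
        if (chrom, pos + 1) in drop:  # drop sites are 1-based
            dropped.append(shifted)
        else:
            lifted.append(shifted)
    return lifted, dropped


def liftover_regions(
    regions: IntervalSet, spec: LiftoverSpec | None = None
) -> IntervalSet:
    spec = spec or LiftoverSpec()
    rename = dict(spec.chrom_rename)
    out = []
    for iv in regions:
        start = iv.start + spec.offset
        if start < 0:
            raise ValueError(f"liftover yields negative start for {iv}")
        out.append(
            GenomicInterval(
                rename.get(iv.chrom, iv.chrom), start, iv.end + spec.offset
            )
        )
    return IntervalSet(out)


# ------------------------------------------------------------- comparison

def compare_to_truth(
    truth_variants: Sequence[SmallVariant],
    called_variants: Sequence[SmallVariant],
    regions: IntervalSet,
    sv_min_size: int = 50,
) -> Dict[str, List[SmallVariant]]:
    """Record-level FP/FN of a callset against truth, restricted to
    small variants whose REF span lies fully inside ``regions``.

    Matching is on (chrom, pos, ref, alts, genotype) with phased
    orientation fixed (haplotig 1 = haplotype 1).
    """

    def keyed(vs: Sequence[SmallVariant]) -> Dict[tuple, SmallVariant]:
        out = {}
        for v in vs:
            if v.is_sv(sv_min_size):
                continue
            if not regions.contains_interval(
                GenomicInterval(v.chrom, v.pos, max(v.end, v.pos + 1))
            ):
                continue
            out[(v.chrom, v.pos, v.ref, v.alts, v.genotype)] = v
        return out

    t = keyed(truth_variants)
    q = keyed(called_variants)
    fn = [t[k] for k in sorted(set(t) - set(q))]
    fp = [q[k] for k in sorted(set(q) - set(t))]
    tp = [t[k] for k in sorted(set(t) & set(q))]
    return {"tp": tp, "fp": fp, "fn": fn}
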