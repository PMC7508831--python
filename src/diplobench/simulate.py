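"""Synthetic diploid loci with known truth.

Generates a reference locus carrying the structural features that make
assembly-based benchmarking of a hyperpolymorphic region hard — a
near-identical two-copy segmental duplication with copy-specific
variants, a hyper-divergent segment, a run of homozygosity, and long
homopolymers — plus two haplotype sequences derived from planted phased
variants, and HiFi-like long reads (~99% accurate, with
homopolymer-length-dependent 1-bp indel errors).

Everything is deterministic given ``SimConfig.seed``; each stage draws
from its own RNG stream derived from the master seed, so stages can be
re-run independently.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .intervals import GenomicInterval, IntervalSet
from .variants import SmallVariant, apply_variants, normalize_variant

BASES = "ACGT"


class ConfigurationError(ValueError):
    """Raised when planted features cannot fit the locus geometry."""


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent RNG stream for a named pipeline stage."""
    return np.random.default_rng([seed, zlib.crc32(stage.encode())])


# ------------------------------------------------------------------- configs

@dataclass
class SegDupConfig:
    copy_length: int = 10_000
    copy_divergence: float = 0.02
    spacer: int = 2_000
    # Plant >=1 copy-distinguishing SNV per read-length window so the
    # k-mer separation problem is information-theoretically solvable;
    # disable to exercise the failure mode (identical copies).
    ensure_distinguishable: bool = True


@dataclass
class DivergentConfig:
    length: int = 20_000
    divergence: float = 0.30


@dataclass
class SimConfig:
    """Desk-scale defaults: a 200 kb locus with the same feature mix
    (relative density of SNVs/indels/SVs, segdup, divergent segment,
    homozygous run) as the ~5 Mb target region, so whole-pipeline runs
    complete in seconds rather than hours."""

    locus_length: int = 200_000
    chrom: str = "locus"
    snv_rate: float = 2e-3  # ~1 het/kb each hap; hyperpolymorphic territory
    small_indel_rate: float = 2e-4
    max_small_indel: int = 10
    sv_count: int = 2
    sv_size_range: Tuple[int, int] = (60, 400)
    segdup: SegDupConfig = field(default_factory=SegDupConfig)
    divergent_region: DivergentConfig = field(default_factory=DivergentConfig)
    homozygous_run_length: int = 20_000
    n_homopolymers: int = 12
    homopolymer_length_range: Tuple[int, int] = (12, 18)
    read_length_mean: int = 10_000
    read_length_sd: int = 1_500
    coverage: float = 15.0  # per haplotype
    hifi_mismatch_rate: float = 1e-3
    hifi_indel_rate: float = 2e-4
    homopolymer_indel_multiplier: float = 2.0
    homopolymer_run_cap: int = 10
    hom_fraction: float = 1.0 / 3.0
    min_variant_spacing: int = 20
    seed: int = 0

    def validate(self) -> None:
        for name in ("snv_rate", "small_indel_rate", "hifi_mismatch_rate",
                     "hifi_indel_rate", "hom_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.divergent_region.divergence <= 1.0:
            raise ConfigurationError("divergence outside [0, 1]")
        if self.coverage <= 0:
            raise ConfigurationError("coverage must be > 0")
        if self.segdup.copy_length >= self.locus_length / 4:
            raise ConfigurationError(
                "segdup copy_length must be < locus_length / 4"
            )
        if self._layout() is None:
            raise ConfigurationError(
                "planted features do not fit inside the locus"
            )

    def _layout(self) -> Optional[Dict[str, Tuple[int, int]]]:
        """Fixed left-to-right feature placement; None if infeasible."""
        L = self.locus_length
        sd = self.segdup
        feats: Dict[str, Tuple[int, int]] = {}
        pos = int(0.10 * L)
        if sd.copy_length > 0:
            feats["segdup_copy1"] = (pos, pos + sd.copy_length)
            pos += sd.copy_length + sd.spacer
            feats["segdup_copy2"] = (pos, pos + sd.copy_length)
            pos += sd.copy_length
        pos = max(pos + int(0.02 * L), int(0.45 * L))
        dv = self.divergent_region
        if dv.length > 0:
            feats["divergent"] = (pos, pos + dv.length)
            pos += dv.length
        pos = max(pos + int(0.02 * L), int(0.70 * L))
        if self.homozygous_run_length > 0:
            feats["roh"] = (pos, pos + self.homozygous_run_length)
            pos += self.homozygous_run_length
        if pos > L - int(0.02 * L):
            return None
        return feats


def mhc_like_config(seed: int = 0) -> SimConfig:
    """Full-scale preset mirroring the target region: ~5 Mb locus, 30 kb
    two-copy segmental duplication, ~110 kb hyper-divergent segment,
    15 kb HiFi-like reads at 18x per haplotype."""
    return SimConfig(
        locus_length=5_000_000,
        segdup=SegDupConfig(copy_length=30_000, spacer=5_000),
        divergent_region=DivergentConfig(length=110_000, divergence=0.30),
        homozygous_run_length=200_000,
        n_homopolymers=200,
        read_length_mean=15_000,
        read_length_sd=2_000,
        coverage=18.0,
        seed=seed,
    )


# ------------------------------------------------------------------- outputs

@dataclass
class SimulatedRead:
    read_id: str
    sequence: str
    true_haplotype: int  # 1 or 2
    start: int  # on the source haplotype, 0-based
    end: int  # half-open, pre-error coordinates
    # injected indel errors as (pre-error fragment offset, +1 ins / -1 del);
    # this is the read's truth alignment to its source haplotype
    indel_edits: Tuple[Tuple[int, int], ...] = ()


@dataclass
class SimulatedReadSet:
    reads: List[SimulatedRead]

    def __iter__(self):
        return iter(self.reads)

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class TruthDiploid:
    chrom: str
    reference: str
    hap1: str
    hap2: str
    truth_variants: List[SmallVariant]
    annotations: Dict[str, IntervalSet]

    def het_snvs(self) -> List[Tuple[int, str, str, int]]:
        """Phased het SNV markers: (pos, ref, alt, phase_bit).

        phase_bit 0 means the ALT allele sits on haplotype 1."""
        out = []
        for v in self.truth_variants:
            if v.is_snv and v.is_het and len(v.alts) == 1:
                bit = 0 if v.genotype[0] == 1 else 1
                out.append((v.pos, v.ref, v.alt, bit))
        return out

    def truth_phase(self) -> List[int]:
        return [bit for _, _, _, bit in self.het_snvs()]

    def hap(self, h: int) -> str:
        return self.hap1 if h == 1 else self.hap2


class CoordMap:
    """Monotone map between reference and one haplotype's coordinates,
    built from the truth variants.  Positions inside a variant span clamp
    to the span start."""

    def __init__(self, truth: TruthDiploid, hap: int) -> None:
        ref_starts: List[int] = []
        hap_starts: List[int] = []
        seg_lens: List[int] = []
        cr = ch = 0
        for v in sorted(truth.truth_variants, key=lambda v: v.pos):
            seg = v.pos - cr
            ref_starts.append(cr)
            hap_starts.append(ch)
            seg_lens.append(seg)
            allele = v.allele(v.genotype[hap - 1])
            cr = v.end
            ch += seg + len(allele)
        ref_starts.append(cr)
        hap_starts.append(ch)
        seg_lens.append(len(truth.reference) - cr)
        self._ref = np.array(ref_starts)
        self._hap = np.array(hap_starts)
        self._len = np.array(seg_lens)

    def to_hap(self, ref_pos: int) -> int:
        i = int(np.searchsorted(self._ref, ref_pos, side="right")) - 1
        off = min(ref_pos - self._ref[i], self._len[i])
        return int(self._hap[i] + off)

    def to_ref(self, hap_pos: int) -> int:
        i = int(np.searchsorted(self._hap, hap_pos, side="right")) - 1
        off = min(hap_pos - self._hap[i], self._len[i])
        return int(self._ref[i] + off)


# ------------------------------------------------------------------- helpers

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=n)])


def _mutate_seq(
    rng: np.random.Generator, seq: str, rate: float
) -> Tuple[str, List[int]]:
    """Substitute bases at ``rate``; return new seq and mutated offsets."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode(), hits.tolist()


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in BASES if b != base]
    return choices[rng.integers(0, 3)]


def homopolymer_run_lengths(seq: str) -> np.ndarray:
    """Per-base length of the homopolymer run containing that base."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    if len(arr) == 0:
        return np.zeros(0, dtype=np.int64)
    change = np.nonzero(arr[1:] != arr[:-1])[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(arr)]))
    lens = ends - starts
    return np.repeat(lens, lens)


# ------------------------------------------------------------ truth building

def simulate_truth(config: SimConfig) -> TruthDiploid:
    """Build the reference locus, plant phased variants, derive haplotypes.

    The truth invariant — applying haplotype-h alleles of the truth
    variants to the reference reproduces haplotype h exactly — holds by
    construction since the haplotypes are produced by
    :func:`apply_variants`.
    """
    config.validate()
    rng = stage_rng(config.seed, "truth")
    L = config.locus_length
    layout = config._layout()
    assert layout is not None

    ref = list(_random_seq(rng, L))

    # segmental duplication: copy2 = copy1 mutated at copy_divergence,
    # optionally guaranteeing distinguishing SNVs at read-length spacing
    if "segdup_copy1" in layout:
        c1s, c1e = layout["segdup_copy1"]
        c2s, c2e = layout["segdup_copy2"]
        copy1 = "".join(ref[c1s:c1e])
        copy2, _ = _mutate_seq(rng, copy1, config.segdup.copy_divergence)
        copy2 = list(copy2)
        if config.segdup.ensure_distinguishable:
            window = max(1, config.read_length_mean // 2)
            for off in range(window // 2, len(copy2), window):
                copy2[off] = _other_base(rng, copy1[off])
        ref[c2s:c2e] = copy2

    # long homopolymers (HiFi error hotspots), kept clear of other features
    feature_ivs = [
        GenomicInterval(config.chrom, s, e) for s, e in layout.values()
    ]
    hp_ivs: List[GenomicInterval] = []
    lo, hi = config.homopolymer_length_range
    attempts = 0
    while len(hp_ivs) < config.n_homopolymers and attempts < 50 * max(
        1, config.n_homopolymers
    ):
        attempts += 1
        hp_len = int(rng.integers(lo, hi + 1))
        p = int(rng.integers(100, L - hp_len - 100))
        iv = GenomicInterval(config.chrom, p, p + hp_len)
        if any(iv.overlaps(f) for f in feature_ivs) or any(
            iv.overlaps(h) for h in
            [GenomicInterval(config.chrom, x.start - 30, x.end + 30)
             for x in hp_ivs]
        ):
            continue
        base = BASES[rng.integers(0, 4)]
        ref[p : p + hp_len] = base * hp_len
        # break accidental run extension at the edges
        if ref[p - 1] == base:
            ref[p - 1] = _other_base(rng, base)
        if p + hp_len < L and ref[p + hp_len] == base:
            ref[p + hp_len] = _other_base(rng, base)
        hp_ivs.append(iv)

    reference = "".join(ref)

    # ---- candidate variant positions -----------------------------------
    div_iv = layout.get("divergent")
    roh_iv = layout.get("roh")
    rate = np.full(L, config.snv_rate)
    if div_iv is not None:
        dv = config.divergent_region.divergence
        # per-hap divergence d needs total planted rate 1.5d when 1/3 of
        # sites are homozygous and hets split evenly between haplotypes
        denom = config.hom_fraction + (1 - config.hom_fraction) / 2
        rate[div_iv[0] : div_iv[1]] = min(1.0, dv / max(denom, 1e-9))
    snv_pos = np.nonzero(rng.random(L) < rate)[0]
    indel_pos = np.nonzero(rng.random(L) < config.small_indel_rate)[0]

    sv_specs: List[Tuple[int, int, str]] = []  # (pos, size, kind)
    placed = 0
    guard = 0
    while placed < config.sv_count and guard < 200:
        guard += 1
        size = int(rng.integers(*config.sv_size_range))
        p = int(rng.integers(1000, L - size - 1000))
        iv = GenomicInterval(config.chrom, p, p + size + 1)
        if any(iv.overlaps(f) for f in feature_ivs):
            continue
        kind = "DEL" if rng.random() < 0.5 else "INS"
        sv_specs.append((p, size, kind))
        placed += 1

    # mask: no small variants near locus ends, homopolymers, or SV spans
    forbidden = IntervalSet(
        [GenomicInterval(config.chrom, 0, 60),
         GenomicInterval(config.chrom, L - 60, L)]
        + [GenomicInterval(config.chrom, h.start - 25, h.end + 25)
           for h in hp_ivs]
        + [GenomicInterval(config.chrom, p - 60, p + sz + 60)
           for p, sz, _ in sv_specs]
    )

    candidates: List[Tuple[int, str, int]] = []  # (pos, kind, size)
    for p in snv_pos:
        candidates.append((int(p), "SNV", 1))
    for p in indel_pos:
        size = int(rng.integers(1, config.max_small_indel + 1))
        kind = "DELS" if rng.random() < 0.5 else "INSS"
        candidates.append((int(p), kind, size))
    for p, size, kind in sv_specs:
        candidates.append((p, "DEL" if kind == "DEL" else "INS", size))
    candidates.sort()

    variants: List[SmallVariant] = []
    last_end = 0
    for pos, kind, size in candidates:
        # dense SNVs are the whole point of the divergent segment: let
        # them sit adjacent there; elsewhere keep variants separated so
        # normalized representations stay unambiguous
        in_div = div_iv is not None and div_iv[0] <= pos < div_iv[1]
        spacing = 0 if (kind == "SNV" and in_div) else config.min_variant_spacing
        if pos < last_end + spacing:
            continue
        span = 1 if kind in ("SNV", "INS", "INSS") else size + 1
        if pos + span + spacing > L:
            continue
        iv = GenomicInterval(config.chrom, pos, pos + span)
        is_sv = kind in ("DEL", "INS")
        if not is_sv and not forbidden.intersect(IntervalSet([iv])).is_empty():
            continue
        in_roh = roh_iv is not None and roh_iv[0] <= pos < roh_iv[1]
        if in_roh or rng.random() < config.hom_fraction:
            gt = (1, 1)
        else:
            gt = (1, 0) if rng.random() < 0.5 else (0, 1)
        if kind == "SNV":
            refb = reference[pos]
            altb = _other_base(rng, refb)
            v = SmallVariant(config.chrom, pos, refb, (altb,), gt)
        elif kind in ("INS", "INSS"):
            ins = _random_seq(rng, size)
            npos, nref, nalt = normalize_variant(
                config.chrom, pos, reference[pos], reference[pos] + ins,
                reference, left_bound=last_end + 1,
            )
            v = SmallVariant(config.chrom, npos, nref, (nalt,), gt)
        else:  # deletion
            npos, nref, nalt = normalize_variant(
                config.chrom, pos, reference[pos : pos + size + 1],
                reference[pos], reference, left_bound=last_end + 1,
            )
            v = SmallVariant(config.chrom, npos, nref, (nalt,), gt)
        variants.append(v)
        last_end = v.end

    hap1 = apply_variants(reference, variants, 1)
    hap2 = apply_variants(reference, variants, 2)

    annotations = {
        name: IntervalSet([GenomicInterval(config.chrom, s, e)])
        for name, (s, e) in layout.items()
    }
    annotations["homopolymer"] = IntervalSet(hp_ivs)

    return TruthDiploid(
        chrom=config.chrom,
        reference=reference,
        hap1=hap1,
        hap2=hap2,
        truth_variants=variants,
        annotations=annotations,
    )


# ------------------------------------------------------------- read drawing

def simulate_reads(
    truth: TruthDiploid, config: SimConfig
) -> SimulatedReadSet:
    """Draw HiFi-like reads from both haplotypes.

    Substitution errors are per-base Bernoulli; 1-bp indel errors occur
    at a rate scaled linearly (capped) with the surrounding homopolymer
    run length, mimicking the dominant HiFi error mode.
    """
    rng = stage_rng(config.seed, "reads")
    reads: List[SimulatedRead] = []
    if config.coverage <= 0:
        import warnings

        warnings.warn("coverage is 0; returning an empty read set")
        return SimulatedReadSet(reads)
    for hap in (1, 2):
        seq = truth.hap(hap)
        Lh = len(seq)
        runs = homopolymer_run_lengths(seq)
        extra = np.minimum(runs - 1, config.homopolymer_run_cap)
        p_indel = config.hifi_indel_rate * (
            1.0 + config.homopolymer_indel_multiplier * extra
        )
        n_reads = int(round(config.coverage * Lh / config.read_length_mean))
        for i in range(n_reads):
            rl = int(
                np.clip(
                    rng.normal(config.read_length_mean, config.read_length_sd),
                    min(500, Lh), Lh,
                )
            )
            start = int(rng.integers(0, Lh - rl + 1))
            end = start + rl
            frag = seq[start:end]
            frag, edits = _inject_errors(
                rng, frag, p_indel[start:end],
                config.hifi_mismatch_rate,
            )
            reads.append(
                SimulatedRead(f"r{hap}_{i}", frag, hap, start, end, edits)
            )
    return SimulatedReadSet(reads)


def _inject_errors(
    rng: np.random.Generator,
    frag: str,
    p_indel: np.ndarray,
    mismatch_rate: float,
) -> Tuple[str, Tuple[Tuple[int, int], ...]]:
    n = len(frag)
    sub_hits = np.nonzero(rng.random(n) < mismatch_rate)[0]
    indel_hits = np.nonzero(rng.random(n) < p_indel)[0]
    if len(sub_hits) == 0 and len(indel_hits) == 0:
        return frag, ()
    subs = {int(i): _other_base(rng, frag[i]) for i in sub_hits}
    # indel: duplicate or drop the base (the HiFi homopolymer error mode)
    indels = {
        int(i): ("ins" if rng.random() < 0.5 else "del") for i in indel_hits
    }
    out: List[str] = []
    edits: List[Tuple[int, int]] = []
    for i, base in enumerate(frag):
        b = subs.get(i, base)
        action = indels.get(i)
        if action == "del":
            edits.append((i, -1))
            continue
        out.append(b)
        if action == "ins":
            out.append(b)
            edits.append((i, +1))
    return "".join(out), tuple(edits)


# ----------------------------------------------------- truth-side utilities

def observe_alleles(
    truth: TruthDiploid,
    readset: SimulatedReadSet,
    sites: Sequence[Tuple[int, str, str]],
) -> Dict[str, List[Tuple[int, str]]]:
    """Per-read base observations at marker sites (reference positions).

    Sites are projected through the truth coordinate map onto each
    read's source haplotype, then through the read's own truth alignment
    (its injected indel errors), emulating allele extraction from a
    read-to-haplotype alignment.  Sites whose base was deleted by a
    sequencing error yield no observation; substitution errors at the
    site itself report the erroneous base.
    """
    site_pos = [p for p, _, _ in sites]
    maps = {h: CoordMap(truth, h) for h in (1, 2)}
    hap_pos = {
        h: np.array([maps[h].to_hap(p) for p in site_pos]) for h in (1, 2)
    }
    out: Dict[str, List[Tuple[int, str]]] = {}
    for read in readset:
        out[read.read_id] = []
        hp = hap_pos[read.true_haplotype]
        lo = int(np.searchsorted(hp, read.start, side="left"))
        hi = int(np.searchsorted(hp, read.end, side="left"))
        if lo == hi:
            continue
        edit_pos = [i for i, _ in read.indel_edits]
        deltas = np.cumsum([d for _, d in read.indel_edits]) if edit_pos else None
        deleted = {i for i, d in read.indel_edits if d < 0}
        obs: List[Tuple[int, str]] = []
        for j in range(lo, hi):
            off = int(hp[j]) - read.start  # pre-error fragment offset
            if off in deleted:
                continue
            shift = 0
            if deltas is not None:
                k = int(np.searchsorted(edit_pos, off, side="left"))
                if k:
                    shift = int(deltas[k - 1])
            pos_in_read = off + shift
            if 0 <= pos_in_read < len(read.sequence):
                obs.append((site_pos[j], read.sequence[pos_in_read]))
        out[read.read_id] = obs
    return out


def simulate_segdup_read_pool(
    seed: int,
    copy_length: int = 5_000,
    n_distinguishing_snvs: int = 3,
    read_length: int = 2_000,
    depth: float = 20.0,
) -> Tuple[List[Tuple[str, str]], Dict[str, int]]:
    """Error-free reads from two near-identical repeat copies.

    Copy 2 differs from copy 1 only at ``n_distinguishing_snvs`` evenly
    spread positions, so every read covers at least one distinguishing
    site when ``read_length`` exceeds the inter-SNV spacing.  Returns
    (read pool, truth copy label per read id) — the canonical test bed
    for k-mer based repeat separation.
    """
    rng = stage_rng(seed, "segdup_pool")
    copy1 = _random_seq(rng, copy_length)
    copy2 = list(copy1)
    step = copy_length // (n_distinguishing_snvs + 1)
    for j in range(1, n_distinguishing_snvs + 1):
        p = j * step
        copy2[p] = _other_base(rng, copy1[p])
    copy2 = "".join(copy2)
    # each copy is embedded in its own unique flanking sequence, as in a
    # genome; read coverage over the copies is then uniform and junction
    # k-mers are genuinely copy-specific
    flank = read_length
    regions = [
        _random_seq(rng, flank) + copy1 + _random_seq(rng, flank),
        _random_seq(rng, flank) + copy2 + _random_seq(rng, flank),
    ]
    reads: List[Tuple[str, str]] = []
    labels: Dict[str, int] = {}
    for copy_no, seq in enumerate(regions, start=1):
        n_reads = int(round(depth * len(seq) / read_length))
        # stratified-jittered starts: coverage stays within +-1 of the
        # nominal depth, so k-mer counts respect the depth-derived bands
        stride = (len(seq) - read_length) / max(n_reads - 1, 1)
        for i in range(n_reads):
            jitter = rng.uniform(0, stride)
            start = min(int(i * stride + jitter), len(seq) - read_length)
            rid = f"c{copy_no}_{i}"
            reads.append((rid, seq[start : start + read_length]))
            labels[rid] = copy_no
    return reads, labels


def read_reference_intervals(
    truth: TruthDiploid, readset: SimulatedReadSet
) -> Dict[str, GenomicInterval]:
    """Project each read's source span onto reference coordinates."""
    maps = {h: CoordMap(truth, h) for h in (1, 2)}
    out: Dict[str, GenomicInterval] = {}
    for read in readset:
        m = maps[read.true_haplotype]
        s, e = m.to_ref(read.start), m.to_ref(read.end)
        if e > s:
            out[read.read_id] = GenomicInterval(truth.chrom, s, e)
    return out
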