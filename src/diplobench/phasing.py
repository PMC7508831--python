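"""Haplotype partitioning: confident-HET selection, read haplotagging,
untagged-read coverage, and switch/Hamming phasing evaluation.

Reads are assigned to haplotypes by simple majority vote over the
phased heterozygous marker SNVs they cover: ties (including reads that
cover no marker) are left untagged.  This deterministic H1/H2/untagged
split is the three-way semantics used when binning long reads for
per-haplotype assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

from .intervals import GenomicInterval, IntervalSet

GenotypeKey = Tuple[str, int, str, str]  # (chrom, pos0, ref, alt)


@dataclass(frozen=True)
class HetSite:
    """A phased heterozygous SNV marker.

    ``phase`` 0 places the ALT allele on haplotype 1, 1 on haplotype 2;
    ``None`` means not yet phased."""

    chrom: str
    pos: int
    ref: str
    alt: str
    phase: int | None = None
    block_id: int = 0


@dataclass
class PhasedHetSet:
    sites: List[HetSite]

    def __post_init__(self) -> None:
        self.sites = sorted(self.sites, key=lambda s: (s.chrom, s.pos))
        for s in self.sites:
            if len(s.ref) != 1 or len(s.alt) != 1:
                raise ValueError(f"non-SNV marker at {s.chrom}:{s.pos}")

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    def phase_bits(self) -> List[int]:
        bits = [s.phase for s in self.sites]
        if any(b is None for b in bits):
            raise ValueError("phase bits unset")
        return bits  # type: ignore[return-value]

    def with_phase(self, bits: Sequence[int]) -> "PhasedHetSet":
        if len(bits) != len(self.sites):
            raise ValueError("phase vector length mismatch")
        return PhasedHetSet(
            [
                HetSite(s.chrom, s.pos, s.ref, s.alt, int(b), s.block_id)
                for s, b in zip(self.sites, bits)
            ]
        )

    def flipped(self) -> "PhasedHetSet":
        return self.with_phase([1 - b for b in self.phase_bits()])


@dataclass
class ReadTag:
    read_id: str
    assignment: str  # "H1", "H2" or "untagged"
    h1_support: int
    h2_support: int


@dataclass
class ReadTagging:
    tags: List[ReadTag]

    def by_assignment(self) -> Dict[str, List[str]]:
        out: Dict[str, List[str]] = {"H1": [], "H2": [], "untagged": []}
        for t in self.tags:
            out[t.assignment].append(t.read_id)
        return out

    def counts(self) -> Dict[str, int]:
        return {k: len(v) for k, v in self.by_assignment().items()}


@dataclass
class PhasingMetrics:
    n_hets: int
    switch_errors: int
    switch_rate: float
    hamming_errors: int
    hamming_rate: float
    switch_rate_defined: bool = True

    def as_dict(self) -> Dict[str, float]:
        return {
            "n_hets": self.n_hets,
            "switch_errors": self.switch_errors,
            "switch_rate": self.switch_rate,
            "hamming_errors": self.hamming_errors,
            "hamming_rate": self.hamming_rate,
        }


# ------------------------------------------------------------- het selection

def select_confident_hets(
    callsets: Sequence[Mapping[GenotypeKey, Tuple[int, int]]],
) -> Tuple[PhasedHetSet, Dict[str, int]]:
    """Keep biallelic SNVs concordantly heterozygous in every callset.

    Mirrors the confident-HET strategy of intersecting independent
    genotype callsets and retaining only sites all of them deem
    heterozygous.  Returns the (unphased) marker set and drop counts by
    reason.
    """
    if len(callsets) < 2:
        raise ValueError("need at least 2 genotype callsets")
    dropped = {"non_snv": 0, "missing": 0, "discordant_genotype": 0}
    keys = set(callsets[0])
    for cs in callsets[1:]:
        keys |= set(cs)
    kept: List[HetSite] = []
    for key in sorted(keys):
        chrom, pos, ref, alt = key
        if len(ref) != 1 or len(alt) != 1:
            dropped["non_snv"] += 1
            continue
        if not all(key in cs for cs in callsets):
            dropped["missing"] += 1
            continue
        gts = [cs[key] for cs in callsets]
        if not all(sorted(g) == [0, 1] for g in gts):
            dropped["discordant_genotype"] += 1
            continue
        kept.append(HetSite(chrom, pos, ref, alt, phase=None))
    return PhasedHetSet(kept), dropped


# ---------------------------------------------------------------- haplotag

def haplotag_reads(
    observations: Mapping[str, Sequence[Tuple[int, str]]],
    hets: PhasedHetSet,
) -> ReadTagging:
    """Majority-vote read-to-haplotype assignment.

    ``observations`` maps read id -> [(reference pos, observed base)].
    Bases matching neither REF nor ALT at a marker are ignored.  A read
    is H1 iff its H1 support strictly exceeds H2 support (and vice
    versa); ties — including reads covering no marker — are untagged.
    """
    site_index: Dict[int, HetSite] = {s.pos: s for s in hets}
    tags: List[ReadTag] = []
    for read_id in sorted(observations):
        h1 = h2 = 0
        for pos, base in observations[read_id]:
            site = site_index.get(pos)
            if site is None or site.phase is None:
                continue
            if base == site.alt:
                alt_on = 1 if site.phase == 0 else 2
            elif base == site.ref:
                alt_on = 2 if site.phase == 0 else 1
            else:
                continue  # sequencing error / third allele
            if alt_on == 1:
                h1 += 1
            else:
                h2 += 1
        if h1 > h2:
            assignment = "H1"
        elif h2 > h1:
            assignment = "H2"
        else:
            assignment = "untagged"
        tags.append(ReadTag(read_id, assignment, h1, h2))
    return ReadTagging(tags)


# ------------------------------------------------------- untagged coverage

def untagged_depth_regions(
    read_intervals: Iterable[GenomicInterval],
    depth_threshold: int = 10,
) -> IntervalSet:
    """Maximal regions where untagged-read depth strictly exceeds the
    threshold (the ">10 reads" convention)."""
    events: Dict[str, List[Tuple[int, int]]] = {}
    for iv in read_intervals:
        events.setdefault(iv.chrom, []).append((iv.start, +1))
        events[iv.chrom].append((iv.end, -1))
    out: List[GenomicInterval] = []
    for chrom, evs in events.items():
        evs.sort()
        depth = 0
        region_start: int | None = None
        i = 0
        while i < len(evs):
            pos = evs[i][0]
            while i < len(evs) and evs[i][0] == pos:
                depth += evs[i][1]
                i += 1
            if depth > depth_threshold and region_start is None:
                region_start = pos
            elif depth <= depth_threshold and region_start is not None:
                if pos > region_start:
                    out.append(GenomicInterval(chrom, region_start, pos))
                region_start = None
    return IntervalSet(out)


# ------------------------------------------------------- phasing evaluation

def phasing_error(
    truth: PhasedHetSet, test: PhasedHetSet
) -> PhasingMetrics:
    """Switch and Hamming error of ``test`` phasing against ``truth``.

    With x_i the XOR of truth and test bits in genomic order, switch
    errors count the sign changes of x (each switch flips all downstream
    relative phases) and Hamming errors count min(sum x, n - sum x),
    i.e. wrong-site count minimized over global haplotype orientation —
    so a globally flipped but otherwise perfect phasing scores 0/0.
    """
    t_keys = [(s.chrom, s.pos, s.ref, s.alt) for s in truth]
    q_keys = [(s.chrom, s.pos, s.ref, s.alt) for s in test]
    if t_keys != q_keys:
        raise ValueError("truth and test phasings cover different sites")
    x = [
        a ^ b for a, b in zip(truth.phase_bits(), test.phase_bits())
    ]
    n = len(x)
    if n == 0:
        return PhasingMetrics(0, 0, 0.0, 0, 0.0, switch_rate_defined=False)
    switches = sum(1 for i in range(n - 1) if x[i] != x[i + 1])
    if n < 2:
        switch_rate = 0.0
        defined = False
    else:
        switch_rate = switches / (n - 1)
        defined = True
    ham = min(sum(x), n - sum(x))
    return PhasingMetrics(
        n_hets=n,
        switch_errors=switches,
        switch_rate=switch_rate,
        hamming_errors=ham,
        hamming_rate=ham / n,
        switch_rate_defined=defined,
    )


def phasing_error_multiblock(
    truth: PhasedHetSet, test: PhasedHetSet
) -> PhasingMetrics:
    """Per-block metrics aggregated by site-weighted mean (single-block
    inputs reduce to :func:`phasing_error`)."""
    blocks = sorted({s.block_id for s in truth})
    per_block: List[PhasingMetrics] = []
    for b in blocks:
        t = PhasedHetSet([s for s in truth if s.block_id == b])
        q_sites = [s for s in test if s.block_id == b]
        per_block.append(phasing_error(t, PhasedHetSet(q_sites)))
    n = sum(m.n_hets for m in per_block)
    if n == 0:
        return PhasingMetrics(0, 0, 0.0, 0, 0.0, switch_rate_defined=False)
    sw = sum(m.switch_errors for m in per_block)
    ham = sum(m.hamming_errors for m in per_block)
    sw_denom = sum(max(m.n_hets - 1, 0) for m in per_block)
    return PhasingMetrics(
        n_hets=n,
        switch_errors=sw,
        switch_rate=sw / sw_denom if sw_denom else 0.0,
        hamming_errors=ham,
        hamming_rate=ham / n,
        switch_rate_defined=sw_denom > 0,
    )
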