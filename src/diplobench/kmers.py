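"""K-mer based repeat resolution for near-identical segmental duplications.

Reads drawn from two copies of a segmental duplication cannot be told
apart by a tolerant overlapper, but copy-specific k-mers (k = 32 by
default) can: k-mers seen at roughly single-copy depth are
haplotype/repeat-specific, k-mers seen at multi-copy depth are shared,
and rare k-mers are sequencing errors.  Grouping reads that share
specific k-mers separates the copies before any assembly graph is
built.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_K = 32


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmers(seq: str, k: int) -> List[str]:
    """All k-mers of ``seq`` in canonical (strand-insensitive) form:
    the lexicographic minimum of the k-mer and its reverse complement."""
    n = len(seq)
    if n < k:
        return []
    rc = reverse_complement(seq)
    out = []
    for i in range(n - k + 1):
        fwd = seq[i : i + k]
        rev = rc[n - k - i : n - i]
        out.append(fwd if fwd <= rev else rev)
    return out


@dataclass
class KmerSpectrum:
    k: int
    counts: Counter
    total_reads: int

    def __post_init__(self) -> None:
        # k >= 11 is the practical floor for repeat-specific signal in
        # genomic read pools; smaller k is permitted for enumeration and
        # testing but will not separate anything real
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")


@dataclass
class KmerClassification:
    """Occurrence-count bands: ``erroneous`` below t_err, ``specific`` in
    [t_err, t_high] (about one copy's worth of depth), ``shared`` above
    (multiple repeat copies / both haplotypes)."""

    labels: Dict[str, str]
    t_err: int
    t_high: int

    def specific(self) -> Set[str]:
        return {km for km, lab in self.labels.items() if lab == "specific"}

    def fraction(self, label: str) -> float:
        if not self.labels:
            return 0.0
        return sum(
            1 for lab in self.labels.values() if lab == label
        ) / len(self.labels)


@dataclass
class ReadPartition:
    groups: List[Set[str]]
    ungrouped: Set[str]

    def group_of(self) -> Dict[str, int]:
        out = {}
        for gi, grp in enumerate(self.groups):
            for rid in grp:
                out[rid] = gi
        return out


ReadLike = Tuple[str, str]  # (read_id, sequence)


def _as_pairs(reads: Iterable) -> List[ReadLike]:
    pairs: List[ReadLike] = []
    for r in reads:
        if isinstance(r, tuple):
            pairs.append(r)
        else:  # SimulatedRead or any object with read_id/sequence
            pairs.append((r.read_id, r.sequence))
    return pairs


def count_kmers(reads: Iterable, k: int = DEFAULT_K) -> KmerSpectrum:
    """Count canonical k-mer occurrences across a read pool.

    Reads shorter than ``k`` are skipped with a warning.
    """
    pairs = _as_pairs(reads)
    if not pairs:
        raise ValueError("empty read set")
    counts: Counter = Counter()
    skipped = 0
    for _, seq in pairs:
        if len(seq) < k:
            skipped += 1
            continue
        counts.update(canonical_kmers(seq, k))
    if skipped:
        import warnings

        warnings.warn(f"skipped {skipped} reads shorter than k={k}")
    return KmerSpectrum(k=k, counts=counts, total_reads=len(pairs))


def classify_kmers(
    spectrum: KmerSpectrum,
    expected_depth: float,
    t_err: int | None = None,
    t_high: int | None = None,
) -> KmerClassification:
    """Band the spectrum by occurrence count.

    Default thresholds derive from the expected per-copy read depth:
    ``t_err = max(2, round(depth / 4))`` separates the error band,
    ``t_high = round(1.5 * depth)`` separates single-copy from
    multi-copy counts.  Both are exposed for tuning.
    """
    if expected_depth <= 0:
        raise ValueError("expected_depth must be > 0")
    if t_err is None:
        t_err = max(2, round(expected_depth / 4))
    if t_high is None:
        t_high = round(1.5 * expected_depth)
    labels: Dict[str, str] = {}
    for km, c in spectrum.counts.items():
        if c < t_err:
            labels[km] = "erroneous"
        elif c <= t_high:
            labels[km] = "specific"
        else:
            labels[km] = "shared"
    return KmerClassification(labels=labels, t_err=t_err, t_high=t_high)


def partition_reads(
    reads: Iterable,
    classification: KmerClassification,
    k: int = DEFAULT_K,
    min_shared: int = 3,
) -> ReadPartition:
    """Group reads connected by shared specific k-mers.

    Two reads are linked when they share at least ``min_shared``
    specific k-mers; groups are connected components of size >= 2.
    Reads without specific k-mers (or in singleton components) are
    ungrouped, to be assembled with every group.
    """
    pairs = _as_pairs(reads)
    specific = classification.specific()
    read_ids = [rid for rid, _ in pairs]

    km_to_reads: Dict[str, List[int]] = {}
    has_specific: Set[int] = set()
    for idx, (rid, seq) in enumerate(pairs):
        seen = set(canonical_kmers(seq, k)) & specific
        if seen:
            has_specific.add(idx)
        for km in seen:
            km_to_reads.setdefault(km, []).append(idx)

    pair_counts: Counter = Counter()
    for idxs in km_to_reads.values():
        for i in range(len(idxs)):
            for j in range(i + 1, len(idxs)):
                pair_counts[(idxs[i], idxs[j])] += 1

    parent = list(range(len(pairs)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (i, j), c in pair_counts.items():
        if c >= min_shared:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj

    comps: Dict[int, Set[str]] = {}
    for idx in has_specific:
        comps.setdefault(find(idx), set()).add(read_ids[idx])

    groups = sorted(
        (grp for grp in comps.values() if len(grp) >= 2),
        key=lambda g: sorted(g)[0],
    )
    grouped = set().union(*groups) if groups else set()
    ungrouped = set(read_ids) - grouped
    return ReadPartition(groups=groups, ungrouped=ungrouped)
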