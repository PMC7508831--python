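"""Independent brute-force oracles used to validate the fast paths.

Each oracle deliberately uses a different mechanism from the
implementation it checks: per-base boolean masks for interval algebra,
quadratic dynamic programming for indel edit distance, regex scanning
for homopolymers, naive dictionaries for k-mer counts.
"""

from __future__ import annotations

import re
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np


# ------------------------------------------------------ interval mask oracle

def mask_from_intervals(
    intervals: Iterable[Tuple[int, int]], size: int
) -> np.ndarray:
    mask = np.zeros(size, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    return mask


def intervals_from_mask(mask: np.ndarray) -> List[Tuple[int, int]]:
    out = []
    in_run = False
    start = 0
    for i, v in enumerate(mask):
        if v and not in_run:
            start, in_run = i, True
        elif not v and in_run:
            out.append((start, i))
            in_run = False
    if in_run:
        out.append((start, len(mask)))
    return out


def merge_oracle(
    intervals: Sequence[Tuple[int, int]], gap: int, size: int
) -> List[Tuple[int, int]]:
    """Pairwise-distance merge: union closure of 'within gap' relation."""
    ivs = [list(iv) for iv in sorted(intervals)]
    changed = True
    while changed:
        changed = False
        for i in range(len(ivs)):
            for j in range(i + 1, len(ivs)):
                a, b = ivs[i], ivs[j]
                if a is None or b is None:
                    continue
                dist = max(b[0] - a[1], a[0] - b[1], 0)
                if dist <= gap:
                    ivs[i] = [min(a[0], b[0]), max(a[1], b[1])]
                    ivs[j] = None
                    changed = True
        ivs = [iv for iv in ivs if iv is not None]
    return sorted((s, e) for s, e in ivs)


def subtract_oracle(
    a: Sequence[Tuple[int, int]], b: Sequence[Tuple[int, int]], size: int
) -> List[Tuple[int, int]]:
    return intervals_from_mask(
        mask_from_intervals(a, size) & ~mask_from_intervals(b, size)
    )


def total_bp_oracle(
    intervals: Sequence[Tuple[int, int]], size: int
) -> int:
    return int(mask_from_intervals(intervals, size).sum())


# ---------------------------------------------------------- indel DP oracle

def dp_indel_distance(a: str, b: str) -> int:
    """Quadratic DP insert/delete edit distance (no substitutions):
    D = len(a) + len(b) - 2 * LCS(a, b)."""
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        ai = a[i - 1]
        for j in range(1, m + 1):
            if ai == b[j - 1]:
                cur[j] = prev[j - 1]
            else:
                cur[j] = min(prev[j], cur[j - 1]) + 1
        prev = cur
    return prev[m]


# ------------------------------------------------------- homopolymer oracle

def homopolymer_oracle(
    seq: str, min_len: int = 11, pad: int = 5
) -> List[Tuple[int, int]]:
    """Regex scan for perfect/imperfect (single-base-interrupted)
    homopolymer spans of at least ``min_len``, padded and merged."""
    raw: List[Tuple[int, int]] = []
    for base in "ACGT":
        pattern = rf"{base}+(?:[^{base}]{base}+)*"
        for m in re.finditer(pattern, seq):
            if m.end() - m.start() >= min_len:
                raw.append(
                    (max(0, m.start() - pad), min(len(seq), m.end() + pad))
                )
    # merge overlapping/touching
    raw.sort()
    merged: List[Tuple[int, int]] = []
    for s, e in raw:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


# ------------------------------------------------------ tandem repeat oracle

def tandem_oracle(
    seq: str, max_period: int = 6, min_span: int = 10
) -> List[Tuple[int, int]]:
    """Exhaustive per-position period scan for perfect tandem arrays."""
    n = len(seq)
    mask = np.zeros(n, dtype=bool)
    for p in range(1, max_period + 1):
        for i in range(n):
            j = i
            while j + p < n and seq[j] == seq[j + p]:
                j += 1
            span = j + p - i
            if j > i and span >= max(min_span, 2 * p):
                mask[i : j + p] = True
    # note: the oracle returns the covered positions, not array bounds
    return intervals_from_mask(mask)


# ----------------------------------------------------------- k-mer oracles

def naive_kmer_counts(reads: Sequence[Tuple[str, str]], k: int) -> Dict[str, int]:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    counts: Dict[str, int] = {}
    for _, seq in reads:
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            rc = "".join(comp[c] for c in reversed(km))
            canon = min(km, rc)
            counts[canon] = counts.get(canon, 0) + 1
    return counts


# --------------------------------------------------------- pileup oracle

def depth_regions_oracle(
    intervals: Sequence[Tuple[int, int]], threshold: int, size: int
) -> List[Tuple[int, int]]:
    depth = np.zeros(size, dtype=int)
    for s, e in intervals:
        depth[s:e] += 1
    return intervals_from_mask(depth > threshold)
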