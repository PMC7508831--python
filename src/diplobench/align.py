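"""Haplotig-to-reference alignment and diploid variant extraction.

The alignment strategy mirrors how assembly-based callers treat a
multi-megabase haplotig: sparse exact anchors (window minimizers that
are unique in both sequences) are chained colinearly, the inter-anchor
gaps are closed with Myers' greedy O(ND) shortest-edit-script algorithm
(insertions/deletions only), and gaps whose edit cost implies local
divergence above ``max_block_divergence`` are declared alignment gaps
instead of being forced — highly diverged segments (like a hyper-
divergent HLA-DRB-class region) therefore show up as unaligned windows
in the divergence track rather than as implausible variant piles.

Edit scripts are written target-relative: ``del`` consumes reference
(target) bases, ``ins`` consumes haplotig (query) bases, ``match``
consumes both.  Substitutions are recovered afterwards by pairing
adjacent del/ins runs during variant extraction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .intervals import GenomicInterval, IntervalSet
from .kmers import reverse_complement
from .variants import SmallVariant, normalize_variant

Op = Tuple[str, int]  # ("match" | "ins" | "del", run length)


@dataclass
class AlignConfig:
    minimizer_k: int = 15
    minimizer_w: int = 10
    max_anchor_gap: int = 200_000
    band_init: int = 10_000
    divergence_window: int = 1_000
    max_block_divergence: float = 0.05
    # absolute slack (in indel-edit units) added to the per-gap
    # divergence budget so short gaps holding a single variant pass
    gap_slack: int = 20
    # gaps larger than this on both sides get a k-mer identity prefilter
    # before any O(ND) work
    prefilter_min_gap: int = 5_000
    prefilter_min_kmer_frac: float = 0.2
    min_chain_anchors: int = 3

    def __post_init__(self) -> None:
        if self.max_anchor_gap <= self.band_init:
            raise ValueError("max_anchor_gap must exceed band_init")


@dataclass
class AnchorChain:
    """Colinear chain of exact anchor matches (query pos, target pos, len)."""

    anchors: List[Tuple[int, int, int]]
    score: int = 0
    strand: int = 1  # +1 forward, -1 reverse-complemented query

    def __post_init__(self) -> None:
        if self.score == 0:
            self.score = len(self.anchors)


@dataclass
class BlockAlignment:
    query_interval: Tuple[int, int]
    target_interval: Tuple[int, int]
    script: List[Op]
    D: int
    divergence: float
    aligned: bool = True


@dataclass
class DivergenceWindow:
    interval: GenomicInterval
    est_difference: float
    aligned: bool


@dataclass
class DivergenceTrack:
    windows: List[DivergenceWindow]

    def unaligned_regions(self) -> IntervalSet:
        return IntervalSet(
            w.interval for w in self.windows if not w.aligned
        )


@dataclass
class DiploidCallset:
    variants: List[SmallVariant]
    dip_regions: IntervalSet


# ------------------------------------------------------------- minimizers

def window_minimizers(seq: str, k: int, w: int) -> List[Tuple[int, str]]:
    """Leftmost-minimum minimizers of every window of ``w`` k-mers."""
    n = len(seq)
    if n < k:
        return []
    kmers = [seq[i : i + k] for i in range(n - k + 1)]
    if len(kmers) <= w:
        m = min(range(len(kmers)), key=lambda i: (kmers[i], i))
        return [(m, kmers[m])]
    out: List[Tuple[int, str]] = []
    dq: List[int] = []  # indices, kmers increasing
    for i, km in enumerate(kmers):
        while dq and kmers[dq[-1]] > km:
            dq.pop()
        dq.append(i)
        if dq[0] <= i - w:
            dq.pop(0)
        if i >= w - 1:
            if not out or out[-1][0] != dq[0]:
                out.append((dq[0], kmers[dq[0]]))
    return out


def anchor_and_chain(
    query: str, target: str, cfg: AlignConfig | None = None
) -> AnchorChain:
    """Unique-minimizer anchors chained by longest colinear chain.

    Only k-mers occurring exactly once in *both* sequences become
    anchors, which keeps near-identical segmental-duplication copies
    from cross-anchoring.  Chains are split later at
    ``max_anchor_gap``.
    """
    cfg = cfg or AlignConfig()
    k, w = cfg.minimizer_k, cfg.minimizer_w
    if len(query) < k or len(target) < k:
        return AnchorChain([], score=0)

    q_counts: Counter = Counter(
        query[i : i + k] for i in range(len(query) - k + 1)
    )
    t_counts: Counter = Counter(
        target[i : i + k] for i in range(len(target) - k + 1)
    )
    t_pos = {
        km: i
        for i, km in window_minimizers(target, k, w)
        if q_counts.get(km) == 1 and t_counts[km] == 1
    }
    anchors = [
        (qp, t_pos[km], k)
        for qp, km in window_minimizers(query, k, w)
        if km in t_pos
    ]
    anchors.sort()
    if not anchors:
        return AnchorChain([], score=0)

    # longest strictly-colinear chain = LIS over target positions
    import bisect

    tails: List[int] = []  # target pos of smallest tail per length
    tails_idx: List[int] = []
    prev = [-1] * len(anchors)
    for i, (_, tp, _) in enumerate(anchors):
        j = bisect.bisect_left(tails, tp)
        if j == len(tails):
            tails.append(tp)
            tails_idx.append(i)
        else:
            tails[j] = tp
            tails_idx[j] = i
        prev[i] = tails_idx[j - 1] if j > 0 else -1
    chain: List[Tuple[int, int, int]] = []
    i = tails_idx[-1]
    while i >= 0:
        chain.append(anchors[i])
        i = prev[i]
    chain.reverse()
    return AnchorChain(chain, score=len(chain))


def _dedup_overlaps(
    anchors: List[Tuple[int, int, int]]
) -> List[Tuple[int, int, int]]:
    """Trim anchors so consecutive matches never overlap in either
    coordinate (shifting start keeps them exact-match substrings)."""
    out: List[Tuple[int, int, int]] = []
    cur_q = cur_t = -1
    for q, t, ln in anchors:
        delta = max(cur_q - q, cur_t - t, 0)
        q, t, ln = q + delta, t + delta, ln - delta
        if ln <= 0:
            continue
        out.append((q, t, ln))
        cur_q, cur_t = q + ln, t + ln
    return out


# ----------------------------------------------------------------- O(ND)

def _lcp(a: str, x: int, b: str, y: int) -> int:
    """Length of the longest common prefix of a[x:] and b[y:]."""
    la, lb = len(a), len(b)
    t = 0
    size = 4096
    while size >= 1:
        while x + size <= la and y + size <= lb and a[x : x + size] == b[
            y : y + size
        ]:
            x += size
            y += size
            t += size
        size >>= 1
    return t


def _myers(a: str, b: str, d_max: int) -> Optional[List[Op]]:
    """Greedy furthest-reaching O(ND) shortest indel edit script a -> b.

    Returns run-length ops ('match' consumes both, 'del' consumes a,
    'ins' consumes b) or None if the minimal D would exceed ``d_max``.
    """
    n, m = len(a), len(b)
    d_max = min(d_max, n + m)
    # trivial fast paths
    pre = _lcp(a, 0, b, 0)
    if pre == n and pre == m:
        return [("match", n)] if n else []
    vs: List[np.ndarray] = []
    v = np.zeros(3, dtype=np.int64)  # index by k + d; v[k=1] = 0 sentinel
    v[1 + 1] = 0
    found = False
    for d in range(d_max + 1):
        newv = np.zeros(2 * d + 1, dtype=np.int64)
        for k in range(-d, d + 1, 2):
            if d == 0:
                x = 0
            elif k == -d or (
                k != d and v[(k - 1) + (d - 1)] < v[(k + 1) + (d - 1)]
            ):
                x = int(v[(k + 1) + (d - 1)])  # down: insertion
            else:
                x = int(v[(k - 1) + (d - 1)]) + 1  # right: deletion
            y = x - k
            if 0 <= x <= n and 0 <= y <= m:
                x += (snake := _lcp(a, x, b, y))
                y += snake
            newv[k + d] = x
            if x >= n and y >= m:
                found = True
                break
        vs.append(newv)
        v = newv
        if found:
            break
    if not found:
        return None

    # traceback
    ops_rev: List[Tuple[str, int]] = []
    x, y = n, m
    for d in range(len(vs) - 1, 0, -1):
        vprev = vs[d - 1]
        k = x - y
        if k == -d or (
            k != d and vprev[(k - 1) + (d - 1)] < vprev[(k + 1) + (d - 1)]
        ):
            pk = k + 1
            step = "ins"
        else:
            pk = k - 1
            step = "del"
        px = int(vprev[pk + (d - 1)])
        py = px - pk
        mx = px + (1 if step == "del" else 0)
        my = py + (1 if step == "ins" else 0)
        snake = x - mx
        if snake:
            ops_rev.append(("match", snake))
        ops_rev.append((step, 1))
        x, y = px, py
    if x:  # leading snake at d=0
        ops_rev.append(("match", x))
    ops = _merge_runs(list(reversed(ops_rev)))
    return ops


def _merge_runs(ops: List[Op]) -> List[Op]:
    out: List[Op] = []
    for op, ln in ops:
        if ln <= 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + ln)
        else:
            out.append((op, ln))
    return out


def script_d(ops: Sequence[Op]) -> int:
    return sum(ln for op, ln in ops if op != "match")


def ond_align(a: str, b: str, d_max: int) -> BlockAlignment:
    """Myers O(ND) alignment of two sequences (a = target, b = query).

    If the minimal indel-edit distance would exceed ``d_max`` the block
    is returned flagged unaligned instead of raising.
    """
    if d_max < 0:
        raise ValueError("d_max must be >= 0")
    ops = _myers(a, b, d_max)
    if ops is None:
        return BlockAlignment(
            (0, len(b)), (0, len(a)), [], D=d_max + 1,
            divergence=1.0, aligned=False,
        )
    d = script_d(ops)
    denom = max(len(a), len(b), 1)
    return BlockAlignment(
        (0, len(b)), (0, len(a)), ops, D=d, divergence=d / denom,
    )


# --------------------------------------------------------- piecewise align

def _kmer_identity_fraction(q: str, t: str, k: int = 15) -> float:
    if len(q) < k or len(t) < k:
        return 0.0
    t_set = {t[i : i + k] for i in range(0, len(t) - k + 1)}
    hits = total = 0
    for i in range(0, len(q) - k + 1, max(1, k // 3)):
        total += 1
        if q[i : i + k] in t_set:
            hits += 1
    return hits / total if total else 0.0


def _align_gap(
    qseg: str, tseg: str, cfg: AlignConfig
) -> Optional[List[Op]]:
    """Close one inter-anchor gap; None means 'declare an alignment gap'."""
    qn, tn = len(qseg), len(tseg)
    if qn == 0 and tn == 0:
        return []
    if tn == 0:
        return [("ins", qn)]
    if qn == 0:
        return [("del", tn)]
    if min(qn, tn) > cfg.prefilter_min_gap:
        if (
            _kmer_identity_fraction(qseg, tseg)
            < cfg.prefilter_min_kmer_frac
        ):
            return None
    budget = (
        abs(qn - tn)
        + 2 * int(cfg.max_block_divergence * min(qn, tn))
        + cfg.gap_slack
    )
    d_limit = min(cfg.band_init, budget)
    ops = _myers(tseg, qseg, d_limit)
    if ops is None:
        return None
    excess = script_d(ops) - abs(qn - tn)
    if excess > 2 * cfg.max_block_divergence * min(qn, tn) + cfg.gap_slack:
        return None
    return ops


def piecewise_align(
    haplotig: str,
    reference: str,
    cfg: AlignConfig | None = None,
    chrom: str = "locus",
) -> Tuple[List[BlockAlignment], DivergenceTrack]:
    """Anchor, chain and locally align a haplotig against the reference.

    Returns aligned blocks (with target-relative edit scripts) and the
    windowed divergence track over the reference; reference regions
    with no surviving block appear as unaligned (white-gap) windows.
    The reverse-complemented haplotig is tried if forward chaining finds
    too few anchors.
    """
    cfg = cfg or AlignConfig()
    chain = anchor_and_chain(haplotig, reference, cfg)
    query = haplotig
    if chain.score < cfg.min_chain_anchors:
        rc = reverse_complement(haplotig)
        chain_rc = anchor_and_chain(rc, reference, cfg)
        if chain_rc.score > chain.score:
            chain = AnchorChain(chain_rc.anchors, chain_rc.score, strand=-1)
            query = rc
    blocks: List[BlockAlignment] = []
    if chain.score >= cfg.min_chain_anchors:
        anchors = _dedup_overlaps(chain.anchors)
        blocks = _blocks_from_anchors(query, reference, anchors, cfg)
    track = build_divergence_track(
        blocks, len(reference), chrom, cfg.divergence_window
    )
    return blocks, track


def _blocks_from_anchors(
    query: str,
    target: str,
    anchors: List[Tuple[int, int, int]],
    cfg: AlignConfig,
) -> List[BlockAlignment]:
    blocks: List[BlockAlignment] = []
    cur_ops: List[Op] = []
    cur_q0 = cur_t0 = cur_q = cur_t = None

    def flush() -> None:
        nonlocal cur_ops, cur_q0, cur_t0, cur_q, cur_t
        if cur_q0 is not None and cur_q > cur_q0:
            ops = _merge_runs(cur_ops)
            d = script_d(ops)
            denom = max(cur_q - cur_q0, cur_t - cur_t0, 1)
            div = d / denom
            if div <= cfg.max_block_divergence:
                blocks.append(
                    BlockAlignment(
                        (cur_q0, cur_q), (cur_t0, cur_t), ops, d, div
                    )
                )
        cur_ops = []
        cur_q0 = cur_t0 = cur_q = cur_t = None

    for q, t, ln in anchors:
        if cur_q is None:
            cur_q0, cur_t0 = q, t
            cur_q, cur_t = q + ln, t + ln
            cur_ops = [("match", ln)]
            continue
        qgap, tgap = q - cur_q, t - cur_t
        if qgap > cfg.max_anchor_gap or tgap > cfg.max_anchor_gap:
            flush()
            cur_q0, cur_t0 = q, t
            cur_q, cur_t = q + ln, t + ln
            cur_ops = [("match", ln)]
            continue
        gap_ops = _align_gap(
            query[cur_q : q], target[cur_t : t], cfg
        )
        if gap_ops is None:
            flush()
            cur_q0, cur_t0 = q, t
            cur_q, cur_t = q + ln, t + ln
            cur_ops = [("match", ln)]
            continue
        cur_ops.extend(gap_ops)
        cur_ops.append(("match", ln))
        cur_q, cur_t = q + ln, t + ln
    flush()
    return blocks


def build_divergence_track(
    blocks: Sequence[BlockAlignment],
    target_len: int,
    chrom: str = "locus",
    window: int = 1_000,
) -> DivergenceTrack:
    """Aggregate per-base edit load into tiling windows on the target.

    A window is aligned when at least half its bases are covered by
    aligned blocks; its est_difference is edited bases over covered
    bases (insertions charged to their anchor position), clipped to 1.
    """
    edited = np.zeros(target_len, dtype=np.float64)
    covered = np.zeros(target_len, dtype=bool)
    for blk in blocks:
        if not blk.aligned:
            continue
        t0, t1 = blk.target_interval
        covered[t0:t1] = True
        t = t0
        for op, ln in blk.script:
            if op == "match":
                t += ln
            elif op == "del":
                edited[t : t + ln] += 1
                t += ln
            else:  # ins
                edited[min(t, target_len - 1)] += ln
    windows: List[DivergenceWindow] = []
    for s in range(0, target_len, window):
        e = min(s + window, target_len)
        cov = int(covered[s:e].sum())
        if cov * 2 >= (e - s):
            est = float(min(1.0, edited[s:e].sum() / max(cov, 1)))
            windows.append(
                DivergenceWindow(GenomicInterval(chrom, s, e), est, True)
            )
        else:
            windows.append(
                DivergenceWindow(GenomicInterval(chrom, s, e), 0.0, False)
            )
    return DivergenceTrack(windows)


# ------------------------------------------------------ variant extraction

def extract_variants(
    blocks: Sequence[BlockAlignment],
    reference: str,
    haplotig: str,
    chrom: str = "locus",
    join_gap: int = 10,
) -> Tuple[List[SmallVariant], IntervalSet]:
    """Turn per-block edit scripts into normalized variant records.

    Del/ins runs separated by matches shorter than ``join_gap`` are
    treated as one replacement event; each event is trimmed
    (suffix-then-prefix), equal-length remainders become per-base SNVs,
    pure length differences become left-aligned indels with one base of
    left context, and mixed events are decomposed as indel-then-SNVs.
    Applying the returned variants to the reference reconstructs the
    haplotig exactly over the covered intervals.
    """
    variants: List[SmallVariant] = []
    covered: List[GenomicInterval] = []
    for blk in blocks:
        if not blk.aligned:
            continue
        q0, _ = blk.query_interval
        t0, t1 = blk.target_interval
        covered.append(GenomicInterval(chrom, t0, t1))
        prev_end = t0  # left bound for left-alignment within the block
        # split the script into events separated by long matches
        t, q = t0, q0
        ev_t0 = ev_q0 = None
        ev_t1 = ev_q1 = None

        def emit_event() -> None:
            nonlocal prev_end, ev_t0, ev_q0, ev_t1, ev_q1
            if ev_t0 is None:
                return
            for v in _event_to_variants(
                chrom, reference, haplotig,
                ev_t0, ev_t1, ev_q0, ev_q1, prev_end,
            ):
                variants.append(v)
                prev_end = max(prev_end, v.end)
            ev_t0 = ev_q0 = ev_t1 = ev_q1 = None

        for op, ln in blk.script:
            if op == "match":
                if ev_t0 is not None and ln < join_gap:
                    ev_t1, ev_q1 = t + ln, q + ln  # absorb short match
                else:
                    emit_event()
                t += ln
                q += ln
            else:
                if ev_t0 is None:
                    ev_t0, ev_q0 = t, q
                    ev_t1, ev_q1 = t, q
                if op == "del":
                    t += ln
                else:
                    q += ln
                ev_t1, ev_q1 = t, q
        emit_event()
    variants.sort(key=lambda v: v.pos)
    return variants, IntervalSet(covered)


def _event_to_variants(
    chrom: str,
    reference: str,
    haplotig: str,
    t0: int,
    t1: int,
    q0: int,
    q1: int,
    left_bound: int,
) -> List[SmallVariant]:
    ref = reference[t0:t1]
    alt = haplotig[q0:q1]
    pos = t0
    # trim shared suffix, then shared prefix (may empty either side)
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while ref and alt and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if not ref and not alt:
        return []
    out: List[SmallVariant] = []
    if len(ref) == len(alt):  # per-base SNVs
        for j, (rb, ab) in enumerate(zip(ref, alt)):
            if rb != ab:
                out.append(SmallVariant(chrom, pos + j, rb, (ab,), (1, 1)))
        return out
    diff = len(ref) - len(alt)
    anchor = pos - 1
    has_left_context = anchor >= 0 and anchor >= left_bound - 1
    if diff > 0:  # net deletion of ref[pos : pos+diff]
        if has_left_context:
            npos, nref, nalt = normalize_variant(
                chrom, anchor, reference[anchor] + ref[:diff],
                reference[anchor], reference, left_bound=left_bound,
            )
            out.append(SmallVariant(chrom, npos, nref, (nalt,), (1, 1)))
        else:  # block edge: anchor on the base after instead
            rb = reference[pos + diff] if pos + diff < len(reference) else ref[-1]
            out.append(SmallVariant(chrom, pos, ref[:diff] + rb, (rb,), (1, 1)))
        tail_ref = ref[diff:]
        tail_alt = alt
        base = pos + diff
    else:  # net insertion of alt[: -diff]
        ins = alt[: -diff]
        if has_left_context:
            npos, nref, nalt = normalize_variant(
                chrom, anchor, reference[anchor],
                reference[anchor] + ins, reference, left_bound=left_bound,
            )
            out.append(SmallVariant(chrom, npos, nref, (nalt,), (1, 1)))
        else:
            rb = ref[0]
            out.append(SmallVariant(chrom, pos, rb, (ins + rb,), (1, 1)))
        tail_ref = ref
        tail_alt = alt[-diff:] if diff else alt
        base = pos
    for j, (rb, ab) in enumerate(zip(tail_ref, tail_alt)):
        if rb != ab:
            out.append(SmallVariant(chrom, base + j, rb, (ab,), (1, 1)))
    return out


def reconstruct_haplotig(
    reference: str,
    variants: Sequence[SmallVariant],
    block: BlockAlignment,
) -> str:
    """Apply the variants falling inside one block to the reference slice
    (round-trip check: the result must equal the haplotig slice)."""
    t0, t1 = block.target_interval
    local = [
        SmallVariant(v.chrom, v.pos - t0, v.ref, v.alts, (1, 1))
        for v in variants
        if t0 <= v.pos and v.end <= t1
    ]
    from .variants import apply_variants

    return apply_variants(reference[t0:t1], local, 1)


# ------------------------------------------------------------ diploid merge

def merge_diploid(
    h1: Tuple[Sequence[SmallVariant], IntervalSet],
    h2: Tuple[Sequence[SmallVariant], IntervalSet],
) -> DiploidCallset:
    """Combine per-haplotig callsets into one phased diploid callset.

    ``dip_regions`` is the intersection of the two covered sets — the
    reference territory where both haplotigs aligned and genotypes are
    fully determined.  GT is ``a|b`` with a from haplotig 1 and b from
    haplotig 2; a variant absent from one side contributes allele 0.
    Same site, different ALTs yields one multi-allelic record (GT 1|2).
    """
    vars1, cov1 = h1
    vars2, cov2 = h2
    dip = cov1.intersect(cov2)

    by_key: Dict[Tuple[str, int, str], Dict[int, str]] = {}
    for hap, vs in ((1, vars1), (2, vars2)):
        for v in vs:
            key = (v.chrom, v.pos, v.ref)
            by_key.setdefault(key, {})[hap] = v.alt

    by_pos: Dict[Tuple[str, int], List[str]] = {}
    for (chrom, pos, ref) in by_key:
        by_pos.setdefault((chrom, pos), []).append(ref)
    for (chrom, pos), refs in by_pos.items():
        by_len = {}
        for r in refs:
            if by_len.setdefault(len(r), r) != r:
                raise ValueError(
                    f"inconsistent REF alleles at {chrom}:{pos}"
                )

    merged: List[SmallVariant] = []
    for (chrom, pos, ref) in sorted(by_key):
        alleles = by_key[(chrom, pos, ref)]
        a1, a2 = alleles.get(1), alleles.get(2)
        if a1 is not None and a2 is not None:
            if a1 == a2:
                merged.append(
                    SmallVariant(chrom, pos, ref, (a1,), (1, 1))
                )
            else:
                merged.append(
                    SmallVariant(chrom, pos, ref, (a1, a2), (1, 2))
                )
        elif a1 is not None:
            merged.append(SmallVariant(chrom, pos, ref, (a1,), (1, 0)))
        else:
            merged.append(SmallVariant(chrom, pos, ref, (a2,), (0, 1)))
    return DiploidCallset(variants=merged, dip_regions=dip)
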