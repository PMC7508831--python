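"""Small-variant records, normalization and sequence reconstruction.

A :class:`SmallVariant` stores a reference-vs-alternate difference at a
0-based position with a phased diploid genotype.  Variants are kept in
the parsimonious, left-aligned representation used by assembly-based
callers: SNVs have 1-bp REF/ALT, indels carry exactly one base of left
context and are shifted as far left as the flanking sequence allows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, List, Sequence, Tuple

SV_MIN_SIZE = 50  # alleles this long or longer are structural, not "small"


@dataclass(frozen=True)
class SmallVariant:
    chrom: str
    pos: int  # 0-based; +1 applied exactly once at VCF write time
    ref: str
    alts: Tuple[str, ...]
    genotype: Tuple[int, int] = (1, 1)
    phased: bool = True
    allele_fraction: float | None = None
    filter: str = "."

    def __post_init__(self) -> None:
        if not self.ref or any(not a for a in self.alts):
            raise ValueError("REF and ALT alleles must be non-empty")
        if any(a == self.ref for a in self.alts):
            raise ValueError(f"ALT equals REF at {self.chrom}:{self.pos}")

    @property
    def alt(self) -> str:
        return self.alts[0]

    @property
    def end(self) -> int:
        """End of the REF span, half-open."""
        return self.pos + len(self.ref)

    def allele(self, index: int) -> str:
        return self.ref if index == 0 else self.alts[index - 1]

    @property
    def max_allele_len(self) -> int:
        return max(len(self.ref), *(len(a) for a in self.alts))

    def is_sv(self, sv_min_size: int = SV_MIN_SIZE) -> bool:
        return self.max_allele_len >= sv_min_size

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    @property
    def is_het(self) -> bool:
        return self.genotype[0] != self.genotype[1]

    def gt_string(self) -> str:
        sep = "|" if self.phased else "/"
        return f"{self.genotype[0]}{sep}{self.genotype[1]}"


def normalize_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    reference: str,
    left_bound: int = 0,
) -> Tuple[int, str, str]:
    """Return the parsimonious, left-aligned form of a single allele pair.

    Trims the shared suffix, then the shared prefix, then shifts pure
    indels leftwards while the preceding reference base matches the last
    base of the varying allele.  ``left_bound`` stops the shift from
    crossing an upstream variant or block edge.  Indels keep one base of
    left context (VCF convention); ``reference`` supplies that base.
    """
    # trim shared suffix
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # trim shared prefix
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if ref == alt:
        raise ValueError("degenerate variant: REF == ALT after trimming")

    if len(ref) > 1 and len(alt) > 1:
        return pos, ref, alt  # complex substitution, nothing more to do
    if len(ref) == 1 and len(alt) == 1:
        return pos, ref, alt  # SNV

    # pure indel: ensure the anchor-base form, then left-align
    if len(ref) < len(alt):  # insertion
        if ref[0] != alt[0] or len(ref) != 1:
            return pos, ref, alt  # not anchor-base form; leave as-is
        seq = alt[1:]
        anchor = pos
        while anchor > left_bound and seq[-1] == reference[anchor]:
            seq = reference[anchor] + seq[:-1]
            anchor -= 1
        return anchor, reference[anchor], reference[anchor] + seq
    else:  # deletion
        if ref[0] != alt[0] or len(alt) != 1:
            return pos, ref, alt
        seq = ref[1:]
        anchor = pos
        while anchor > left_bound and seq[-1] == reference[anchor]:
            seq = reference[anchor] + seq[:-1]
            anchor -= 1
        return anchor, reference[anchor] + seq, reference[anchor]


def apply_variants(
    reference: str,
    variants: Sequence[SmallVariant],
    hap: int,
) -> str:
    """Apply the haplotype-``hap`` alleles (1 or 2) to ``reference``.

    Variant REF spans must not overlap.  This is the ground-truth
    reconstruction used both by the simulator and by round-trip checks on
    extracted callsets.
    """
    if hap not in (1, 2):
        raise ValueError("hap must be 1 or 2")
    ordered = sorted(variants, key=lambda v: v.pos)
    out: List[str] = []
    cursor = 0
    for v in ordered:
        if v.pos < cursor:
            raise ValueError(
                f"overlapping variant spans at {v.chrom}:{v.pos}"
            )
        allele_idx = v.genotype[hap - 1]
        out.append(reference[cursor : v.pos])
        out.append(v.allele(allele_idx))
        cursor = v.end
    out.append(reference[cursor:])
    return "".join(out)


def split_by_size(
    variants: Iterable[SmallVariant], sv_min_size: int = SV_MIN_SIZE
) -> Tuple[List[SmallVariant], List[SmallVariant]]:
    """Partition into (small variants, structural variants)."""
    small: List[SmallVariant] = []
    svs: List[SmallVariant] = []
    for v in variants:
        (svs if v.is_sv(sv_min_size) else small).append(v)
    return small, svs
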