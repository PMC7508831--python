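"""Standard-format I/O: FASTA/FASTQ, VCF v4.2, BED, and track TSVs.

FASTA/FASTQ go through Biopython; VCF is read with pysam and written as
plain VCFv4.2 text (phased ``|`` genotypes, FILTER ``.`` when unset).
Internally everything is 0-based half-open; the +1 on VCF POS happens
exactly once, in :func:`write_vcf` / :func:`read_vcf`.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval, IntervalSet
from .variants import SmallVariant

VCF_VERSION = "VCFv4.2"


# ---------------------------------------------------------------- FASTA/FASTQ

def read_fasta(path: str | os.PathLike) -> Dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(path: str | os.PathLike, seqs: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | os.PathLike) -> List[Tuple[str, str]]:
    """Return (read id, sequence) pairs."""
    return [
        (rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fastq(
    path: str | os.PathLike, reads: Iterable[Tuple[str, str]], qual_char: str = "I"
) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual_char * len(seq)}\n")


# ------------------------------------------------------------------------ VCF

def write_vcf(
    path: str | os.PathLike,
    variants: Sequence[SmallVariant],
    contigs: Mapping[str, int],
    sample: str = "SYN",
) -> None:
    """Write a single-sample VCFv4.2 with phased GT (and AF when present)."""
    lines = [f"##fileformat={VCF_VERSION}"]
    for name, length in contigs.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append(
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
    )
    lines.append(
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele fraction">'
    )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample
    )
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
        info = (
            f"AF={v.allele_fraction:.4g}"
            if v.allele_fraction is not None
            else "."
        )
        lines.append(
            "\t".join(
                [
                    v.chrom,
                    str(v.pos + 1),
                    ".",
                    v.ref,
                    ",".join(v.alts),
                    ".",
                    v.filter,
                    info,
                    "GT",
                    v.gt_string(),
                ]
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path: str | os.PathLike) -> List[SmallVariant]:
    """Read a single-sample VCF into 0-based :class:`SmallVariant` records."""
    out: List[SmallVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            af = rec.info.get("AF")
            if isinstance(af, tuple):
                af = af[0]
            gt: Tuple[int, int] = (1, 1)
            phased = True
            if rec.samples:
                smp = rec.samples[0]
                alleles = smp.get("GT")
                if alleles and None not in alleles and len(alleles) == 2:
                    gt = (alleles[0], alleles[1])
                    phased = bool(smp.phased)
            out.append(
                SmallVariant(
                    chrom=rec.chrom,
                    pos=rec.pos - 1,
                    ref=rec.ref,
                    alts=tuple(rec.alts or ()),
                    genotype=gt,
                    phased=phased,
                    allele_fraction=float(af) if af is not None else None,
                    filter=";".join(rec.filter.keys()) or ".",
                )
            )
    return out


def read_genotype_callset(
    path: str | os.PathLike,
) -> Dict[Tuple[str, int, str, str], Tuple[int, int]]:
    """VCF -> map (chrom, pos0, ref, alt) -> genotype, biallelic sites only."""
    out: Dict[Tuple[str, int, str, str], Tuple[int, int]] = {}
    for v in read_vcf(path):
        if len(v.alts) != 1:
            continue
        out[(v.chrom, v.pos, v.ref, v.alt)] = v.genotype
    return out


# ------------------------------------------------------------------------ BED

def write_bed(
    path: str | os.PathLike,
    intervals: IntervalSet | Iterable[GenomicInterval],
    label: str | None = None,
) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if label is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\n")


def read_bed(path: str | os.PathLike) -> IntervalSet:
    ivs: List[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            ivs.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            )
    return IntervalSet(ivs)


def read_labeled_bed(path: str | os.PathLike) -> Dict[str, IntervalSet]:
    """BED4 -> {label: IntervalSet}; unlabeled rows go under ''."""
    groups: Dict[str, List[GenomicInterval]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            label = fields[3] if len(fields) > 3 else ""
            groups.setdefault(label, []).append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            )
    return {label: IntervalSet(ivs) for label, ivs in groups.items()}


# ------------------------------------------------------------------------ TSV

def write_tsv(
    path: str | os.PathLike,
    rows: Iterable[Sequence],
    header: Sequence[str] | None = None,
) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_allele_observations(
    path: str | os.PathLike,
) -> Dict[str, List[Tuple[int, str]]]:
    """Per-read allele TSV (read_id, pos0, observed_allele) -> dict."""
    obs: Dict[str, List[Tuple[int, str]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("read_id"):
                continue
            rid, pos, allele = line.split("\t")[:3]
            obs.setdefault(rid, []).append((int(pos), allele))
    return obs
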