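# diplobench

Locus-scale construction of **diploid-assembly-based variant
benchmarks** — the approach used to benchmark hyperpolymorphic regions
like the human MHC, where mapping-based callsets break down because at
least one haplotype is too diverged from the reference to map reads.

Instead of judging variants from read pileups, the assembly-based
approach assembles one contig per haplotype (a *haplotig*), aligns both
to the reference, reads the variants directly off the alignments, and
then defines the *benchmark regions* — the territory in which that
callset is reliable enough to score other callsets against.
`diplobench` implements every stage of that construction as a reusable
library plus CLI, together with a synthetic diploid simulator so the
whole pipeline can be validated end to end against known truth:

1. **Haplotype partitioning** (`diplobench.phasing`) — intersect
   genotype callsets into confident heterozygous SNV markers, assign
   each long read to H1/H2/untagged by majority vote over the phased
   markers it covers, locate regions of high untagged-read depth, and
   score phasings by **switch error rate** (adjacent-pair disagreements
   of the XOR vector, `/(n−1)`) and orientation-minimized **Hamming
   error rate** (`min(Σx, n−Σx)/n`).
2. **Repeat resolution** (`diplobench.kmers`) — classify canonical
   32-mers of the read pool into erroneous / repeat-specific / shared
   bands from the expected per-copy depth `d`
   (`t_err = max(2, d/4)`, `t_high = 1.5·d`), then separate reads from
   near-identical segmental-duplication copies as connected components
   of the share-≥3-specific-k-mers graph.
3. **Haplotig calling** (`diplobench.align`) — unique window-minimizer
   anchors (k=15, w=10), longest colinear chain, inter-anchor gaps
   closed with **Myers' O(ND)** greedy edit-script alignment
   (indel-only; substitutions recovered by pairing adjacent del/ins
   runs), a windowed divergence track, and gaps whose edit cost implies
   >5% local divergence declared unaligned rather than forced. Per-
   haplotig variants are normalized (left-aligned, anchored indels) and
   merged into a phased diploid VCF with `dip_regions` = territory
   covered by *both* haplotigs.
4. **Benchmark regions** (`diplobench.benchmark`) — subtract from the
   dip regions: read-back low-confidence clusters (allele fraction
   25–75%, clustered within 10 kb, +50 bp, ≥300 bp), SV neighbourhoods
   (≥50 bp alleles expanded over tandem repeats, +50 bp, merged within
   1 kb), dense clusters (>10 variants within 10 bp and >20 within
   1 kb, +10 bp), homopolymers >10 bp including single-base-interrupted
   ones (+5 bp), and a hyper-divergent annotation; finally drop any
   repeat only partially inside the result. Every rule logs removed bp.
   A constant-offset liftover (+32,223, with the one discrepant site
   dropped) moves the outputs between reference builds.
5. **Synthetic diploid loci** (`diplobench.simulate`) — 200 kb default
   loci carrying dense SNVs/indels, SVs, a two-copy segmental
   duplication with copy-specific variants, a hyper-divergent segment,
   a run of homozygosity, and HiFi-like reads (~99.9% base accuracy,
   homopolymer-scaled 1 bp indel errors) with full truth labels; an
   `mhc_like_config()` preset scales the geometry to 5 Mb.

See `docs/methods.md` for the models, defaults and numerical decisions.

## Worked example

Simulate a 200 kb diploid locus whose divergent segment is at 30% —
too diverged to align — then call variants from the two haplotigs and
build the benchmark:

```bash
cat > sim.yaml <<EOF
locus_length: 200000
divergent_region: {length: 20000, divergence: 0.30}
seed: 1
EOF
diplobench simulate --config sim.yaml --seed 1 --out sim/
# simulated 200000 bp locus, 9232 truth variants, 600 reads

diplobench call --hap1 sim/hap1.fa --hap2 sim/hap2.fa \
                --ref sim/reference.fa --out calls
# 352 variants, 179991 bp dip regions

awk '$4=="divergent"{print $1"\t"$2"\t"$3}' sim/annotations.bed > div.bed
diplobench make-benchmark --vcf calls.vcf --dip calls.dip.bed \
                          --ref sim/reference.fa --divergent div.bed \
                          --out bench
# {"dip_bp": 179991, "not_dip_bp": 20009, "sv_bp": 202,
#  "homopolymer_bp": 7846, "partial_repeat_trim_bp_new": 56, ...
#  "included_bp": 171885, "excluded_bp": 8106}
```

Reading the numbers: of the 200 kb locus, the 20 kb hyper-divergent
segment fails to align on both haplotigs and falls outside the dip
regions (`not_dip_bp` 20,009), so its ~8,900 planted variants are
absent from the 352-variant callset by design — exactly the "alignment
gap" behaviour such segments show in real data. Inside the dip regions
the SV rule removes 202 bp around two planted structural indels, the
homopolymer rule removes 7,846 bp, and the final trim removes 56 bp of
boundary-straddling repeats, leaving 171,885 bp (95.5% of the dip
regions) of benchmark territory. Within that territory, comparing
`bench.benchmark.vcf` to `sim/truth.vcf` gives zero false positives and
zero false negatives (that check is `compare_to_truth` in
`diplobench.benchmark`, exercised by the test suite and the acceptance
script).

Phasing evaluation of a test phasing against truth:

```bash
diplobench phase-eval --truth sim/truth_phase.tsv --test sim/truth_phase.tsv
# {"n_hets": 6153, "switch_errors": 0, "switch_rate": 0.0,
#  "hamming_errors": 0, "hamming_rate": 0.0}
```

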