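# Methods

`diplobench` re-creates, at locus scale, the workflow used to build
assembly-based small-variant benchmarks for hyperpolymorphic regions
such as the human MHC: phased heterozygous markers partition long reads
by haplotype, copy-specific k-mers separate reads from near-identical
segmental-duplication copies, the two haplotigs are aligned to the
reference and diffed into a phased diploid callset, and a set of
deterministic exclusion rules defines the regions in which that callset
can serve as truth. This note records the models, parameter choices and
numerical decisions behind each stage.

## Coordinates and variant representation

All internal coordinates are 0-based half-open; BED is written natively
and VCF positions gain +1 exactly once at serialization. The convention
is fixed by the observation that the printed MHC recruitment window
6:28,477,797–33,448,354 has length 4,970,557 bp only under half-open
arithmetic.

Variants are parsimonious and left-aligned: SNVs are 1 bp/1 bp, indels
carry one base of left context and are shifted left while the preceding
reference base equals the last base of the varying sequence, bounded by
the previous variant (or block edge) so records never overlap.
Genotypes are phased `a|b` with allele *a* from haplotig 1. When the two
haplotigs disagree at one site the record becomes multi-allelic with
GT `1|2`.

## Synthetic diploid loci

The simulator is the package's source of ground truth. A locus is a
random DNA string carrying, left to right: a two-copy segmental
duplication (copy 2 derived from copy 1 at a configurable divergence,
with at least one distinguishing SNV per half read length unless
disabled), a hyper-divergent segment, a run of homozygosity, and a set
of planted long homopolymers (12–18 bp). Phased variants are drawn per
base: SNVs at `snv_rate`, small indels (1–10 bp) at `small_indel_rate`,
plus a fixed count of structural indels (60–400 bp at desk scale).
One third of variants are homozygous; heterozygous alternates land on
either haplotype with equal probability, and inside the homozygosity
run all variants are forced homozygous. Haplotypes are produced by
*applying* the truth variants to the reference, so the invariant
"apply(truth, hap h) == haplotype h" holds by construction.

Inside the divergent segment SNVs are planted at rate
`divergence / (hom_fraction + (1 − hom_fraction)/2)` so that each
haplotype's per-base divergence from the reference matches the
configured fraction; the 20 bp spacing imposed elsewhere (which keeps
normalized representations of neighbouring indels unambiguous) is
lifted for these SNVs, since dense adjacent substitutions are exactly
what makes such segments hard.

Two scales are provided. The default `SimConfig` is a 200 kb locus —
10 kb duplication copies with a 2 kb spacer, a 20 kb divergent segment
(30% by default), a 20 kb homozygosity run, 10 kb reads at 15× per
haplotype — small enough that a full pipeline run takes ~2 s while
preserving every structural feature. `mhc_like_config()` scales the
same geometry to the real setting (5 Mb, 30 kb duplication, ~110 kb
divergent segment, 15 kb reads at 18×) for users who want the full-size
exercise.

Reads are HiFi-like: per-base substitution errors at 10⁻³ and 1 bp
indel errors at a base rate of 2×10⁻⁴ scaled linearly with the
surrounding homopolymer run length (factor `1 + m·min(run−1, 10)`,
default multiplier m = 2), reproducing the dominance of homopolymer
indels among HiFi errors. Each read records its true haplotype, its
source interval, and its injected indel offsets — the read's truth
alignment. The generator does **not** model ONT/linked-read error
profiles, chimeras, or coverage bias (GC or otherwise), so passing
tests demonstrate algorithmic correctness under idealized HiFi noise,
not robustness to platform artifacts.

All randomness flows from one master seed; each stage (`truth`,
`reads`, …) derives its own `numpy` Generator from the seed plus a CRC
of the stage name, so stages are independently reproducible.

## Haplotype partitioning and phasing metrics

Confident heterozygous markers are the intersection of ≥2 genotype
callsets restricted to biallelic SNVs heterozygous in *all* of them,
with drop counts reported by reason. Haplotagging is a deterministic
majority vote over the phased markers a read covers: strict majority
assigns H1 or H2, any tie (including zero informative sites) leaves the
read untagged. This is a documented simplification of likelihood-based
haplotagging; it preserves the three-way H1/H2/untagged semantics and
is exactly invariant under a global phase flip. In simulation, allele
observations are read bases looked up through the truth coordinate map
*and* the read's own injected-error offsets — the stand-in for
extracting alleles from a read-to-haplotype alignment; no realigner is
implemented.

Untagged coverage regions are maximal intervals where untagged-read
depth strictly exceeds a threshold (default 10), computed by an event
sweep; on default simulations these localize to the homozygosity run,
as expected, since reads there cover no marker.

Phasing accuracy uses the standard pair of metrics on the XOR vector
x between truth and test phase bits in genomic order: switch errors are
sign changes of x (rate over n−1 adjacent pairs), Hamming errors are
min(Σx, n−Σx) (rate over n, minimized over global orientation). With
n < 2 the switch rate is reported as 0 with a "not defined" flag.
Multi-block inputs are scored per block and aggregated site-weighted.

## K-mer repeat resolution

Canonical (strand-minimum) 32-mers are counted across the read pool.
Counts are banded by the expected per-copy depth d: below
`t_err = max(2, round(d/4))` is the error band, within
`[t_err, round(1.5·d)]` is haplotype/repeat-specific (≈ one copy's
depth), above is shared (≥ 2 copies / both haplotypes). Both thresholds
are exposed; the defaults put the boundary between the one-copy and
two-copy Poisson modes at 1.5d. Reads become nodes of a graph with an
edge when they share ≥ 3 specific k-mers; connected components of size
≥ 2 are the read groups, and everything else (including reads with no
specific k-mers, e.g. from deep inside identical copy sequence) stays
ungrouped, to be shared by all downstream assemblies. Components stand
in for the assembler's overlap machinery deliberately: the claim being
modelled is read *separation*, not graph construction.

The canonical test bed embeds two 5 kb copies differing by 3 SNVs in
distinct unique flanks and draws error-free 2 kb reads at 20× with
stratified-jittered starts. Stratification keeps local coverage within
±1 of nominal; with iid starts, ordinary coverage fluctuations push
single-copy k-mer counts across the 1.5d boundary often enough to
disconnect a copy's read chain — a property of coverage statistics, not
of the partition algorithm under test.

## Haplotig alignment and variant extraction

Alignment is anchor-and-fill. Window minimizers (k = 15, w = 10) that
occur exactly once in *both* sequences become anchors — uniqueness in
both prevents cross-anchoring between duplication copies — and the
longest strictly colinear chain (LIS over target positions) is kept,
splitting wherever consecutive anchors are > 200 kb apart. If forward
chaining yields < 3 anchors the reverse-complemented haplotig is tried;
inversions are not called.

Inter-anchor gaps are closed with Myers' greedy furthest-reaching
O(ND) algorithm, insertions/deletions only, with a chunked
longest-common-prefix for snake extension. The minimal D equals the
quadratic-DP indel distance (property-tested on random pairs). A gap is
declared an *alignment gap* rather than forced when its edit cost
implies real divergence: writing Δ = |len difference| (the unavoidable
indel cost), the gap is rejected when D − Δ > 2·mbd·min(len) + 20,
with mbd = 0.05 the maximum block divergence. The subtraction of Δ
keeps pure structural indels alignable (a clean 300 bp insertion has
D = Δ and naive divergence 1.0), the factor 2 converts substitutions to
indel-edit units, and the absolute slack of 20 lets short gaps holding
a single variant pass. mbd = 0.05 encodes the empirical boundary
between "very divergent but alignable" (HLA class I level, < 5%) and
"alignment gap" (HLA-DRB level) in this kind of data. Gaps > 5 kb on
both sides are prescreened by shared-15-mer fraction (reject < 0.2,
sampled every 5 bp) so hyper-divergent segments cost no O(ND) work; at
5% divergence ~46% of 15-mers survive, at 30% ~0.5%, so the screen is
far from the acceptance boundary. The O(ND) search budget per gap is
capped at min(band_init = 10 kb, that same divergence budget).

The divergence track tiles the reference in 1 kb windows; a window is
"aligned" when ≥ half its bases are covered by surviving blocks, and
its estimated difference is edited bases over covered bases (insertions
charged to their anchor position, clipped to 1). Because substitutions
cost one deletion plus one insertion in an indel-only script, a segment
with s% SNV divergence reads out near 2s% — the track is a relative
divergence profile, and hyper-divergent segments appear as unaligned
(white-gap) windows rather than as numbers.

Variant extraction walks each block's script, grouping del/ins runs
separated by < 10 bp of matches into single replacement events. Each
event is trimmed (shared suffix, then prefix); equal-length remainders
decompose into per-base SNVs, pure length differences become one
left-aligned anchored indel, and mixed events become indel-then-SNVs —
a decomposition chosen so that (a) applying the records reproduces the
haplotig exactly over covered intervals (tested exhaustively) and (b)
an isolated substitution whose minimal edit script happens to split
around a matching base still normalizes to the same SNV the truth set
contains. Per-haplotig callsets are merged site-wise into the diploid
callset; `dip_regions` — the intersection of the two covered sets — is
the only territory where diploid genotypes are fully determined.

## Benchmark regions

Starting from `dip_regions`, five rules subtract territory, each
logging raw bp and newly-removed bp (rules overlap, so raw counts
over-sum — as they do in published audits):

1. **Low confidence**: read-back variants with allele fraction in
   [0.25, 0.75] (reads disagreeing with their own contig), single-
   linkage clustered within 10 kb, extended 50 bp per side, kept when
   the extended region reaches 300 bp. The 300 bp floor treats the
   published "regions > 300 bp" phrasing as the filter it implies.
2. **Structural variants**: any call with an allele ≥ 50 bp, expanded
   over overlapping tandem repeats (single pass), padded 50 bp, merged
   within 1000 bp (pad before merge).
3. **Dense clusters**: clusters of > 10 variants within 10 bp whose
   1 kb-scale merge exceeds 20 variants, padded 10 bp. The sentence
   defining this rule admits an AND and an OR reading of the two
   stages; the default is the AND reading (stage 2 filters stage 1),
   with `dense_two_stage_and=False` exposing the OR reading.
4. **Homopolymers**: perfect runs and runs interrupted by isolated
   single bases, total span > 10 bp, padded 5 bp. Note the literal
   single-interruption rule makes a long dinucleotide tract (e.g.
   GCGCGC…) an "imperfect homopolymer" as well; the detector and its
   regex oracle agree on this reading.
5. **Hyper-divergent annotation**: supplied as a BED (the real-world
   analogue was chosen manually); the divergence track's unaligned
   windows are the natural candidate generator.

Finally, any homopolymer/tandem-repeat interval from the trim track
that overlaps but is not fully contained in the remaining territory is
removed outright, so no repeat straddles a benchmark boundary. Variant
records are never deleted — only the regions shrink. Tandem repeats
default to maximal perfect arrays with unit ≤ 6 bp, ≥ 2 copies and
span ≥ 10 bp; an external BED can replace the detector.

Liftover between assemblies whose sequence differs only by an offset is
a uniform shift (+32,223 between the relevant GRCh37 and GRCh38 MHC
coordinates) with an explicit drop list for the discrepant site(s) and
chromosome renaming; it is exactly invertible given the dropped
records.

## Problem sizes and determinism

Default test and acceptance runs use 200 kb loci (5–10 of them), 500
random pairs for the alignment oracle, 100 random sets for the interval
oracle, and 20 seeds for the duplication-separation scenario — sizes at
which every stage's behaviour is already asymptotic while a full run of
the suite stays near a minute. Identical `RunConfig`/seed inputs yield
byte-identical outputs; all RNG streams descend from the single master
seed.

## Known limitations

- The aligner has no inversion or translocation handling and does not
  attempt base-level alignment inside declared gaps; SV *regions* are
  excluded rather than SV alleles benchmarked.
- Record-level truth comparison (exact pos/allele/genotype match after
  normalization) is stricter than haplotype-aware comparison engines;
  it is the right tool for the synthetic round trip but would over-count
  representation differences on real callsets.
- The k-mer partition assumes a known per-copy depth; badly
  mis-estimated depth shifts the classification bands.
- Majority-vote haplotagging ignores base qualities, and the simulator's
  truth-alignment observation extraction sidesteps realignment
  uncertainty present in real data.
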