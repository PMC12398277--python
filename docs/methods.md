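# Methods

## Haplotype statistics

The substrate of every scan is a complete binary haplotype-by-site matrix
(allele 1 = derived) with strictly increasing bp positions on one chromosome.
Phased VCFs are converted by splitting multiallelic records and dropping any
site with a missing allele: EHH-type statistics have no principled treatment
of missing haplotype data, and upstream QC (GQ masking plus the missingness
filter) is expected to keep such sites rare.

**EHH.** For a core site and allele, EHH at extension site t is
Σ_h C(c_h, 2) / C(n_a, 2), where c_h counts carriers sharing an identical
haplotype from the core through t and n_a is the carrier count. At distance 0
EHH is 1; it is non-increasing because extension only refines groups.
Internally the whole decay profile of one arm is obtained at once: carrier
rows are sorted lexicographically along the arm, shared-prefix lengths
between adjacent rows are computed with vectorized comparisons, and a
union-find pass over merges in decreasing prefix-length order yields the
integer count of identical pairs at every distance. Counts stay exact
integers until a single final division, so results are bit-identical to
direct pair enumeration (the test suite asserts exact equality against a
brute-force oracle).

**iHH and iHS.** iHH is the trapezoidal integral of EHH against physical
distance (bp), left arm plus right arm, from the core to the truncation
point. The curve is truncated at the first point with EHH < `ehh_cutoff`
(default 0.05, the common tool default); that point is included, so the
integral covers the crossing segment. No genetic map is used. Unstandardized
iHS = ln(iHH_ancestral / iHH_derived). Under the default `skip` truncation
policy a core site is invalid when either allele's EHH fails to decay below
the cutoff before a chromosome edge; `clip` instead integrates to the edge,
which is useful on very short synthetic chromosomes but biases scores near
edges. Sites also require at least 2 carriers of each allele and a minor
allele frequency strictly above `maf_floor` (default 0.05, matching the
cohort variant filter).

**SL and nSL.** SL is the mean over carrier pairs of the number of
consecutive sites, inclusive of the core, over which the pair is identical
(so SL ≥ 1, counting the core itself; the convention is held fixed). It is
computed from the same arm profiles via mean L = 1 + Σ_t EHH_left(t) +
Σ_t EHH_right(t), with no cutoff: the identity holds because the fraction of
pairs still identical t sites out is exactly EHH(t). nSL =
ln(SL_ancestral / SL_derived), with the same carrier-count and MAF validity
rules (there is no decay requirement, as the statistic is inherently
bounded by the chromosome).

**Standardization.** Valid raw scores are binned by derived allele frequency
into `n_daf_bins` (default 50) equal-width bins on (0, 1). Bins below
`min_bin_count` (default 20) are merged iteratively — the smallest offending
bin joins whichever adjacent bin is smaller, ties toward lower frequency —
until every remaining bin meets the floor or one bin remains. Within each
final bin z = (raw − mean)/sd with the population (divide-by-n) standard
deviation; a zero-sd bin yields z = 0. The moments |mean z| < 1e−9 and
|sd z − 1| < 1e−9 hold in every non-degenerate bin by construction and are
asserted in the tests. Both bin count and floor are configurable since tools
differ and the choice is not standardized in the literature.

## Sweep peak calling

Standardized scores are averaged over consecutive, non-overlapping windows of
exactly 100 valid variants (trailing remainders are dropped rather than
padded, keeping window statistics comparable); the mean retains sign. A peak
is seeded at any window whose absolute mean reaches 1.5 and extended in both
directions over consecutive windows while the absolute mean stays at or
above 0.5; overlapping or abutting spans from different seeds merge.
Seeding high and extending low is a hysteresis rule: it prevents one broad
sweep signal from fragmenting into many small calls. Extension is
bidirectional so that a call does not depend on scan direction. Peak bp
coordinates run from the first to the last variant position of the member
windows; peaks merge into unique, disjoint BED regions, and genes overlap a
peak iff their 1-based intervals intersect by at least one base.

## Synthetic data

The generators aim for the *statistical structure the pipeline assumes*, not
for population-genetic realism.

- **Neutral panels** are founder mosaics: `n_founders` (default 8) haplotypes
  drawn i.i.d. Bernoulli(0.5) per site; each sample haplotype copies a
  founder, switching to a different uniformly chosen founder with probability
  `recomb_prob` = 0.01 per site and flipping alleles with `mut_prob` = 0.002
  per site. Site spacing is geometric with mean 1000 bp (minimum 1, so
  positions strictly increase). This produces linkage disequilibrium and
  realistic EHH decay without a coalescent simulation; it is a stylized
  stand-in, with no allele-age structure (the ancestral/derived labeling
  carries no temporal meaning) and no recombination-rate variation.
- **Hard sweeps**: round(`target_daf` · n) haplotypes (the prefix of a seeded
  shuffle) become carriers; across ±`halfwidth_sites` around the core their
  alleles are replaced by founder 0's (flipped per site with probability
  `template_noise` = 0.01, independently per carrier), and the core column is
  set to 1 exactly for carriers. The generated panel carries its founders so
  the implant can reference founder 0 without re-simulation.
- **Toy pangenomes** emit one pseudo-sample per assembly, presence patterns
  (singleton with probability 0.6, else uniform over non-empty patterns),
  hom-alt genotypes for presence (an assembly haplotype either carries the
  path or not), and allele-length differences log-uniform within [1, 49] or
  [50, `max_ins_len`] so that `sv_fraction` of variants are structural.
- **Kin cohorts** draw within-cluster kinship uniformly above the 0.0625
  third-degree threshold and cross-cluster kinship below it, with uniform
  per-sample coverage; isolated samples are included. Sample ids encode the
  true cluster.
- **PAF fusion cases** align query [0, b1) to one target and [b2, len) to the
  other; the truth is floor((b1 + b2)/2), invariant to cutting the blocks
  into contiguous sub-alignments.

Because the generators are stylized, passing tests demonstrate correctness of
the *computations* (statistics, callers, accounting) and internal consistency
of the pipeline — not field performance on real cohorts.

### Known limitation: sweep recovery at synthetic scale

The documented recovery experiment (panels of 100 haplotypes × 2000 sites
with a ±150-site implanted sweep at derived-allele frequency 0.8, window 100,
thresholds 1.5/0.5) does **not** detect the implanted sweep, and the package
reports this honestly rather than altering the conditions. Two mechanisms,
both verified numerically, are responsible. First, linked swept sites carry
both signs of iHS — where the shared template carries allele 1 the derived
allele rides the sweep (raw ≈ −2), where it carries allele 0 the ancestral
allele does (raw ≈ +2) — so signed 100-variant window means cancel to ≈ 0.1,
far below the 1.5 seed threshold, although the unsigned signal is plainly
present (mean |raw| ≈ 1.4 in-window versus ≈ 0.6 background). Second, the
sweep spans 15% of the synthetic chromosome and dominates the extreme-DAF
standardization bins it occupies, so bin standardization partly absorbs its
own signal — a finite-size artifact that vanishes when sweeps are a
negligible fraction of a genome, as in real data. The neutral half of the
experiment behaves as designed: matched neutral panels yield zero peaks in
all replicates, so any peak the caller does emit is trustworthy.

## QC conventions

Missing genotypes are excluded from allele-frequency denominators. A variant
is kept iff its missing-genotype fraction is ≤ 0.2 **and** its minor allele
frequency is strictly > 0.05; a variant with every genotype missing is
dropped (MAF undefined). GQ masking is strict (< 25 masked; 25 kept) and
leaves records without GQ untouched. Kinship pruning builds a graph from
pairs with kinship strictly > 0.0625, takes connected components, and keeps a
greedy maximum-coverage independent set (visit by coverage descending, ties
by sample id ascending; keep unless a kept neighbor exists). This retains
*all* mutually unrelated members of a component — maximizing retained samples
while guaranteeing that no kept pair is related and that every removed sample
has a kept relative of equal or higher coverage. Ti/Tv counts A↔G and C↔T as
transitions over SNVs only and returns inf/nan markers rather than raising
when transversions or SNVs are absent.

## Pangenome accounting

A missing genotype contributes a 0 presence bit: in a graph VCF built from
assembly haplotypes, missingness means the path is absent. Upset counts key
on exact SUPP_VEC patterns over variants with |length change| ≥ 50 bp.
Length accounting counts each insertion once per group (presence is a path
property, not a per-sample one): a group's total covers insertions carried by
at least one member, its exclusive length those whose carriers all lie inside
the group. Caller overlap matches exact (chrom, pos, ref, alt) keys — a
deliberate simplification of haplotype-aware matching, so calls representing
the same event with different alignments count as caller-specific.

## Fusion detection

Alignments below `min_alignment_len` (default 10 kb) are discarded to
suppress spurious hits before clustering by target chromosome; the cluster
with the smaller maximum query end is upstream. The fusion point is
floor((gap_start + gap_end)/2) over the inter-cluster gap. Clusters may
overlap by up to 1% of the chromosome length (real alignments are ragged
near the junction) — the midpoint is still returned with a warning; larger
interleaving raises. Splitting produces `<chrom>_a` = [0, fusion) and
`<chrom>_b` = [fusion, len) with an exact, invertible coordinate lift.

## Enrichment

The two-sided Fisher exact p sums hypergeometric point probabilities of all
tables sharing the observed margins whose probability does not exceed the
observed one. Tie comparison uses unnormalized integer weights
(C(K, x)·C(N−K, n−x)), so no floating-point epsilon enters; a zero-margin
table returns p = 1 and is flagged. The background is the set of variants
*outside* the regions (a disjoint 2×2 table, required for a well-formed
test). Odds ratios use the Haldane 0.5 correction when any cell is zero.
When a variant carries several impact annotations the most severe is
retained (standard SnpEff convention); raw p-values are reported alongside
Benjamini–Hochberg q-values across the impact × variant-class grid.

## Pipeline and problem sizes

All randomness in the orchestrated pipeline flows from one global seed
through named substreams, intermediate artifacts are plain TSV/BED/VCF, and
per-stage record counts are logged and conserved. The test suite and the
acceptance script use panels of 100 haplotypes × 2000 sites with 20 seeded
replicates, 50–100 seeded kinship cohorts and fusion cases, and exhaustive
enumeration of 2×2 tables to N = 40 — sizes chosen so the full battery runs
in a few minutes on one CPU while still exercising every code path at the
documented study conditions.
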