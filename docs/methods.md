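# Methods

## Coordinate and boundary conventions

All coordinates are 1-based inclusive internally (the convention of the
common CNV-caller output dialect); BED input is 0-based half-open and is
converted at the reader boundary (`triocnv.io.read_bed`). Thresholds
written with "≥" are inclusive and thresholds written with ">" or "<" are
strict, exactly as in the filter definitions: a 30-marker, 100.0 kb call
passes the size filter; a call covered by exactly 50% segmental
duplication is kept; a region at exactly 1% frequency is rare; a merge gap
equal to 20% of the merged span does not merge.

## Intensity FBAT

With complete trios and every offspring affected, any trait offset in the
family-based statistic multiplies the numerator and the denominator's
square root by the same constant and cancels; the test therefore reduces
to the unweighted midparent deviation `d_i = x_off − (x_fa + x_mo)/2`,
`z = Σd_i / √(Σd_i²)`, two-sided normal p. The empirical variance uses
`Σd_i²` without mean-centering — the conservative convention — with a
mean-centred variant switchable via `mean_center_variance=True`. Families
enter per marker only when all three intensities are finite (per-marker
dropout maximizes informative families). Markers with fewer than
`min_families` (default 10) informative families are reported but flagged
untested; zero empirical variance with non-zero families yields p = 1,
flagged degenerate. The genomic inflation factor is the median of the
implied 1-df chi-squares divided by 0.4549.

Power for the log-additive trio design uses the classical TDT
non-centrality: a heterozygous parent of an affected child transmits the
risk allele with probability OR/(1+OR), and the expected heterozygous
parent count is ascertainment-adjusted under the multiplicative model
(transmitted-allele frequency p·OR/(p·OR+q)). `population_risk` is
accepted for interface compatibility but does not enter this
approximation, and exact agreement with likelihood-based power calculators
is not claimed; at α = 5.6e-7, n = 660 trios, OR = 1.6, MAF = 0.49 the
approximation gives power ≈ 0.83.

## Stand-in CNV caller

`call_cnvs` is a deliberately simple fixed-parameter 3-state
(loss/neutral/gain) Gaussian hidden-state model decoded by Viterbi per
sample and chromosome. Emission means are −0.6 / 0 / +0.35 on LRR —
generator-matched conveniences, not constants from any published caller —
with the per-sample noise level estimated by 1.4826·MAD (floored at 0.05),
self-transition probability 0.999, and a 10-marker minimum segment.
Segment means below −1.5 re-classify a loss as CN 0 and above +0.55 a gain
as CN 4. The stand-in exists so the filter chain is exercisable
end-to-end; externally produced call lists are first-class input via
`io.read_cnv_calls`.

## Filter chain

The stage order is fixed: call → trio origin → size/marker filter →
sample QC pass 1 (≥ 50 calls or LRR_SD > 0.3 in any member removes the
trio) → blacklist filter (≥ 1 bp overlap) → 20 kb single-linkage grouping
and the ≤ 1% frequency rule → sample QC pass 2 (≥ 10 rare calls in any
member) → > 50% union-coverage segmental-duplication filter → iterative
same-type merging (gap < 20% of merged span, to a fixpoint). A
`PipelineReport` records calls and trios removed per stage.

Open choices resolved here:

* **Inheritance threshold** — 50% reciprocal overlap with a same-type
  parental call (common CNV practice); a relaxed `in_any_parent` flag uses
  ≥ 1 bp same-type overlap, separating "de novo at the threshold" from
  "not found in any parent at all".
* **Rarity denominator** — all QC-passed samples (founders + offspring),
  configurable via the `n_samples` argument to `group_into_regions`.
* **Mixed regions** — when deletions and duplications co-cluster the
  region type is "mixed"; locus burden matching therefore operates on
  call-level type, never region type.
* **Merge tie-break** — when two same-type calls with different copy
  number merge, the larger call's copy number is kept.

GC-wave correction regresses each sample's LRR on local GC content
(optionally smoothed over a window; a window larger than the chromosome
degenerates to the raw global fit) and subtracts only the fitted linear GC
component, preserving the sample mean and genuine copy-number shifts. A
per-window residualization would erase any CNV spanning a window, which is
why a single global fit per sample is used.

SNP QC applies call rate ≥ 0.95, exact Hardy–Weinberg p ≥ 1e-6 on
founders (conditional exact test summing configurations no more probable
than observed), MAF ≥ 0.01, zero Mendelian errors, then greedy LD pruning:
markers are scanned in map order and a new marker is removed when its r²
with any kept marker in the trailing 50-marker window exceeds 0.8.

## Burden statistics

2×2 tables are (case, control) × (carrier, non-carrier). If any cell is
zero, 0.5 is added to **every** cell before the odds ratio and Woolf
variance are formed; the two-sided Fisher exact p is always computed on
the uncorrected integer counts. When control studies are merged at a
locus, studies with unavailable counts are excluded from both numerator
and denominator. Random-effects pooling is DerSimonian–Laird on log odds
ratios with Woolf variances (τ² by method of moments, floored at 0; τ² = 0
whenever Q ≤ df); Mantel–Haenszel pooling of the raw tables (with the
Robins–Breslow–Greenland variance) is provided because the two flavors
bracket typical published pooled values — on the packaged carrier-level
tables DL gives 2.77 and MH 2.54. Exact-conditional confidence intervals
are not implemented; published CIs for such tables often match neither the
Woolf nor the exact convention exactly.

## Gene-set enrichment

The universe N is the consensus-gene file size (19,897 by default in the
packaged counts), not the genome. A gene is hit by ≥ 1 bp overlap,
boundary intersections included, and duplicate hits count once. The
enrichment p is the upper tail P(X ≥ k) of the hypergeometric law via
scipy's log-stable implementation. The removal-sensitivity sweep
decrements only k, holding n, K and N fixed (whether the draw count should
also shrink is a convention choice; decrementing k alone is the
conservative reading and is what is implemented).

## Polygenic-score stratification

Pseudo-controls take the untransmitted parental alleles, so case plus
pseudo-control allele counts partition the parental alleles at every
marker (a tested invariant). Double-heterozygote transmission ambiguity is
resolved by a seeded coin flip, which is irrelevant in expectation under
the null; trios with any Mendelian-inconsistent marker are excluded.
Scores are risk-allele counts (optionally log-OR weighted) averaged over
non-missing included markers (inclusion at discovery p < P_T, default
0.1). The 1:1 matched conditional likelihood reduces to a logistic law in
the pair score difference with no intercept, maximized by Newton
iteration; complete separation is flagged and reported without a standard
error. Nagelkerke's pseudo-R² uses L0 = n·log(1/2). The random-draw
comparison subsamples the non-carrier stratum without replacement
(default: ten draws of 116, mirroring the carrier-stratum size of the
motivating design), checks normality by Shapiro–Wilk and compares the
carrier R² against the draws by a two-tailed one-sample t-test.

## Synthetic-data generator

The generator emulates an Illumina-1M-like trio cohort at desk scale:
markers placed uniformly (defaults in tests: 2,000 markers over 1–2
chromosomes of 30–80 Mb, standing in for ~1M markers genome-wide), GC
content following a smooth positional sinusoid (baseline 0.45, amplitude
0.08, period 2 Mb, noise sd 0.02), LRR noise sd 0.15 per sample (the QC
statistic LRR_SD estimates it back; the QC threshold is 0.3), and
copy-number LRR shifts of −3.0 / −0.6 / +0.35 / +0.75 for CN 0/1/3/4 with
BAF bands at k/CN plus noise (CN 0 emits uniform BAF). These magnitudes
are chosen so a simple segmenter separates the states; no published noise
profile exists for the motivating cohort, so they are calibration
conveniences, not estimates. Inherited events appear in exactly one
parent and the offspring; de novo events only in the offspring.

Somatic-artifact regions model T-cell-receptor rearrangement signal in
blood DNA: each individual receives one independent Gaussian LRR offset
per region (sd 0.5), plus an offspring-specific mean shift (−0.25 by
default) representing the age-correlated component of rearrangement
burden. The independent draws alone would leave the within-family
statistic null in expectation; the age shift is what makes such regions
light up in the scan while remaining non-inherited, reproducing the
confound in which the only experiment-wide significant intensity-FBAT
hits fall in TCR-like regions and vanish when those regions are masked.

Deliberate non-realism: BAF genotypes are drawn per sample (not
Mendelian-consistent across the trio — nothing downstream consumes BAF
inheritance; the PRS module uses the separate Mendelian transmission
generator), there is no linkage disequilibrium between markers unless
injected, no batch/plate structure, and no IDAT/GTC-level normalization
artifacts. Passing tests therefore demonstrate correctness of the
statistics and filter logic under a clean signal model, not robustness to
every failure mode of real array data.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed and is bit-for-bit
reproducible. The test suite runs its simulations at reduced scale chosen
to keep each property sharp: the null-calibration scan at 500 trios ×
2,000 markers, the artifact-confound scan at 300 trios × 2,000 markers,
CLR recovery at 300 pairs × 50 markers, and interval-filter oracles on
randomized instances up to ~4 × 10⁵ bp against per-basepair bitmaps. The
packaged burden tables are computed at their true published scale (582
cases, 1,290–10,259 controls per study) since those are count-level
inputs.

## Known limitations

* The intensity FBAT assumes an approximately linear intensity–dosage
  relationship and a symmetric null; heavy-tailed intensity noise would
  make the normal reference approximate.
* The stand-in caller has no trained emission/transition model, no
  BAF-informed decoding and no boundary refinement; recovery guarantees in
  the tests hold for events ≥ ~40 markers at noise sd ≤ 0.2.
* The X chromosome is out of scope throughout (autosomal analysis only).
* Exact-conditional CIs for odds ratios and hybrid pooled estimators from
  legacy epidemiology packages are not implemented; DL and MH are the two
  supported pooling flavors.
* The removal-sensitivity sweep and the frequency-rule denominator encode
  one reading of ambiguous published conventions (documented above and
  configurable where meaningful).
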