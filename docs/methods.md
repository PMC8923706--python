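# Methods

## The inference problem

In a male-heterogametic (XX/XY) species, the Y chromosome carries sequence
absent from every female; in a female-heterogametic (ZZ/ZW) species the W
does the mirror. Two observable consequences drive this package:

* **Presence/absence of restriction tags.** A type IIB enzyme excises a
  fixed-length tag around each occurrence of its recognition motif. Tags
  originating from Y-private sequence occur in every male's tag set and no
  female's. With per-individual deduplicated tag sets
  `M_1..M_m, F_1..F_f`, the candidate-Y set is `⋂M_i ∖ ⋃F_j` and the
  candidate-W set the mirror; a decisively one-sided split determines the
  system.
* **Pooled allele-depth signature.** Pooling DNA by sex and resequencing,
  a fixed X–Y difference appears as a site where the female pool is
  homozygous and the male pool heterozygous with allele ratio near 1:1,
  both at adequate depth.

## Digestion model

The digestion is a motif scan, not an enzymology model. The default motif
`ACNNNNNCTCC` (11 nt, 6 fixed positions) is searched on both strands; each
hit emits a tag of `flank + motif + flank` = 8 + 11 + 8 = 27 bp centred on
the recognition site, reverse-complemented for minus-strand hits so each tag
reads 5'→3' on the strand carrying the motif. Only the uniform tag length is
modelled, not the enzyme's true double-sided cut offsets, partial digestion
or adapter chemistry; tags are compared by exact string identity, as in
set-based 2b-RAD analyses. Consequences of these choices:

* `N` bases match no motif position (including degenerate ones): assembly
  gaps yield no phantom tags.
* Tags are strand-specific by default (reads with chain specificity); an
  optional `canonicalize` folds a tag onto the lexicographic minimum of
  itself and its reverse complement.
* Digesting a genome and its reverse complement yields identical tag sets;
  hits whose window would cross a sequence end are skipped and counted.
* Expected motif density is `2·L/4^6 ≈ 488` tags per Mb of random sequence
  (both strands), which sets how much sex-limited sequence is needed for a
  detectable exclusive-tag count.

### Decision rule

With `M = |⋂males ∖ ⋃females|` and `F` its mirror, the call is XX_XY when
`M ≥ min_exclusive` and `F ≤ max_minor_ratio·M`, ZZ_ZW under the mirrored
condition, else inconclusive. The motivating comparison observed an
all-or-nothing split (a six-figure count against zero), so the thresholds
(`min_exclusive = 10`, `max_minor_ratio = 0.01`) exist only to keep the rule
robust to tag dropout and rare noise tags; both are configurable and both
counts are always reported.

## Pooled screen

Sites are processed in a fixed order — biallelic classification, hard
filter, per-pool depth, zygosity — and every input site lands exactly once
in the passed set or a reason tally (`multiallelic`, `unusable`,
`hard_filter:<metric>`, `depth_male`, `depth_female`, `hom_fail`,
`het_fail`, `allele_inconsistency`), making the tallies deterministic and
the screen auditable.

* **Hard filter.** The standard SNP and InDel exclusion expressions with OR
  semantics (see README). A metric absent at a site fails nothing: rank-sum
  annotations are routinely undefined and absence is not evidence against a
  call. The first failing metric, in written order, is reported.
* **Depth.** Strictly greater than `min_depth` (default 30) in *each* pool,
  reading "greater than 30×" per sequencing library literally.
* **Zygosity.** The homogametic pool's alt-allele frequency must be
  ≤ `hom_tol` or ≥ `1 − hom_tol` (default 0.05) — either bound, because the
  reference assembly may carry either gametolog allele. The heterogametic
  pool must satisfy `|AF − 0.5| ≤ het_tol`.

### Calibration of `het_tol`

The het band is a trade-off between binomial read-sampling noise and
excluding non-1:1 ratios. At pooled depth `DP ~ Poisson(60)` the alt-allele
frequency of a true 1:1 site has standard deviation ≈ 0.065, so:

| band (±) | P(true 1:1 site passes) |
|----------|-------------------------|
| 0.10     | 0.882                   |
| 0.12     | 0.935                   |
| 0.15     | 0.979                   |

A ±0.10 band silently discards ~12% of genuine sex-linked sites at 60×,
while ±0.15 (≈2.3 sd) keeps >97% of them and still rejects a 3:1 ratio
(AF 0.25/0.75) by a wide margin. The default is therefore
`het_tol = 0.15`, computed from these tail probabilities rather than tuned
on any simulation run. `hom_tol = 0.05` tolerates sequencing error up to
~1% comfortably (at 60× and 0.2% error, P(hom passes) > 0.999).

Mirror symmetry holds exactly: swapping the two pool columns while swapping
the model XX_XY ↔ ZZ_ZW yields the identical passed set.

## Marker model

A passed InDel supports a dominant allele-specific marker. `build_candidate`
cuts a ±500 bp reference window and constructs both local haplotypes; the
sex-limited allele is the one the homogametic pool is *not* fixed for.
`design_overlap_primers` reads the forward primer off the gametolog
haplotype with its 3' end a few bases past the divergent interval, so the
3'-terminal bases span the allele junction; the reverse primer is placed for
a ~350 bp product. Amplification is simulated as string matching: a primer
anneals with at most `max_mismatch` mismatches (default 0) and zero
mismatches in its 3'-terminal `three_prime_exact` bases (default 5 — a 3'
mismatch aborts extension); products are filtered to the 300–400 bp window.
Each design is verified in silico against both haplotypes before being
returned. One amplifiable haplotype suffices for a band, so XY males band
and XX females do not; a whole-PCR failure for an individual is a distinct
outcome that counts against the discrimination rate. The rate is reported
as a percentage to two decimals with an exact Clopper–Pearson 95% CI
(via the binomial-test inversion in SciPy).

Melting temperature, GC content and secondary structure are deliberately out
of scope: candidate regions can be exported for an external primer-design
tool, and this module checks only placement and allele specificity.

## Synthetic studies

`simdata` generates the full data structure with planted truth:

* **Reference**: `n_scaffolds` (default 5) uniform-random scaffolds of
  `scaffold_length` (default 1 Mb); one is sex-linked.
* **Planted sites**: `n_sex_linked_snps + n_sex_linked_indels` (defaults
  60 + 12) fixed gametolog differences on the sex scaffold, spaced ≥ 500 bp
  and ≥ 500 bp from scaffold ends so every marker amplicon (≤ 400 bp) is
  free of other planted variants; `n_autosomal_sites` (default 300) SNPs on
  the other scaffolds at population frequencies uniform on [0.05, 0.95],
  spaced wider than the largest indel. InDels are left-anchored as in VCF,
  sizes uniform on `indel_size_range` (default 3–12 bp), insertions and
  deletions equally likely.
* **Individuals**: under XX_XY every male is (X, Y) on the sex scaffold and
  every female (X, X); ZZ_ZW mirrors. The gametolog haplotype carries the
  alternate allele at every planted sex-linked site *plus* background
  divergence substitutions at rate `gametolog_divergence` (default 0.02),
  identical by descent across carriers, excluded within 500 bp of planted
  sites. The background divergence is what gives the sex-limited chromosome
  a detectable private tag complement: planted focal sites alone would fall
  inside tag footprints (~1.3% of a scaffold) far too rarely. Autosomal
  genotypes are independent Bernoulli draws per haplotype.
* **Pools**: per site and pool, `DP ~ Poisson(depth_mean)` (default 60, the
  target coverage of a pooled-resequencing design) and
  `AD_alt ~ Binomial(DP, f′)` with `f′ = f(1−e) + (1−f)e` for error rate
  `e = seq_error_rate` (default 0.002). Sex-linked sites use the realised
  pool frequency (exactly 0.5 / 0); autosomal sites use the population
  frequency in both pools, so the pools are identical in expectation and
  autosomal false positives arise only from read-sampling noise. Quality
  metrics are drawn from filter-passing ranges (QD ∈ [5, 35], MQ ∈ [50, 60],
  FS ∈ [0, 10], SOR ∈ [0.5, 2.5], rank sums ∈ [−2, 2]); a
  `frac_filter_fail_sites` fraction (default 0.05) gets exactly one metric
  pushed past its threshold, recorded in the truth table, so filter
  behaviour is fully attributable.
* **Tag sets**: union of in-silico digests of both haplotypes per
  individual, with independent per-tag dropout at `tag_dropout_rate`
  (default 0).

One global seed drives independent per-stage generators derived by fixed
stage keys, so any stage can be re-run in isolation and every output is a
pure function of (config, seed). The pooled VCF contains exactly the
planted sites; the gametolog background divergence feeds only the tag
stage (a real experiment's VCF would include those sites too — keeping them
out makes screen recovery exactly scoreable against the truth table).

### What the generator does not emulate

Read-level artifacts (alignment error, duplicates, mapping-quality
structure correlated with divergence), polymorphism on the X/Z,
recombination, population structure between families, and primer-site
polymorphism across geographic populations — the known failure mode of
otherwise valid markers — are all absent. Passing tests therefore
demonstrate correctness of the algebra, the screen and the marker logic
under the stated statistical model, not robustness to real-data artifacts.

## Problem sizes used in the checks

The shipped test-suite and acceptance script run simulations at 1 Mb × 5
scaffolds with 5 males + 5 females (tag stage), 200 sex-linked + 5000
autosomal sites at 60× (screen stage, 20 and 5 seeds respectively), and
10–100 kb fixtures for unit-level properties; these sizes give each check
ample statistical power while keeping the whole suite fast to run.

## Known limitations

* Exclusive-tag counts scale with the amount and divergence of sex-limited
  sequence; at desk-scale genome sizes the decision rule depends on the
  modelled gametolog divergence, and `min_exclusive` should be revisited
  for real genomes.
* The screen applies hard thresholds only — no genotype-likelihood model,
  no multiple-testing control; that matches its screening (not inference)
  role.
* In-silico PCR is a string-matching idealisation; a verified design still
  needs wet-lab confirmation.
* Even with zero sequencing error, read sampling is stochastic: a true 1:1
  site misses the ±0.15 band with probability ≈ 0.021 at 60×, so screen
  recall is ~0.98, not 1.0, by design.
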