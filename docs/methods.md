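# Methods

This package implements, end to end, a genotype-first analysis of how
common polygenic variation modifies the severity of rare genetic disorders
(RGDs) affecting three quantitative traits — height, BMI and LDL-C — in a
health-system-scale cohort.  Because the real cohort data are not
redistributable, every stage runs against a synthetic cohort generator
whose defaults encode the study conditions: a variant-negative testing
population of 31,430 adults, eleven carrier groups at their published
sample sizes and mean shifts, published trait moments, and a held-out
10,000-sample validation cohort for polygenic-score tuning.

## Trait and cohort model

The generator draws, for each individual, a latent polygenic value
G ~ N(0, 1) shared across traits and an independent residual, and builds
each standardized trait as

    Z = sqrt(r2) * G + shift(RGD) + sqrt(1 - r2) * eps,

where `r2` is the fraction of trait variance the polygenic score explains
(defaults: height 0.2171, BMI 0.1078, LDL-C 0.0799) and `shift` is the
carrier displacement in trait-SD units (e.g. −1.91 for 45,X on height,
+2.49 for pathogenic LDLR carriage on LDL-C).  The model is additive and
independent: carrier status shifts the mean but leaves the polygenic slope
within carriers equal to the population slope sqrt(r2).  This is the
simplest model consistent with the reported concordance between carrier
and population polygenic effects, and it is what the test suite's
recovery checks assume.

Native-unit phenotypes are produced by mapping Z through sex-specific raw
moments (female height 161.94 (6.66) cm, male 176.69 (7.20) cm, BMI 31.94
(7.72) kg/m², LDL-C 137.67 (41.63) mg/dl) and adding planted confounder
effects (age slope −0.05 SD/decade, a PC1 slope, batch offsets) so the
pre-adjustment stage has genuine structure to remove.  Visit counts per
trait are 1 + Poisson(3) with measurement noise of 1% of the trait mean —
the within-patient visit variance is not constrained by any published
value and is treated as a free parameter.

A single latent factor stands in for genome-wide structure: the dosage
panel (default 1,000 SNPs; desk-scale runs use a few hundred) gives each
SNP a loading on G of sqrt(20/m), so the true-weight score correlates with
G at ~0.97 regardless of panel size.  The ~1.2M-SNP scale of real scores
is emulated, not reproduced; there is no linkage disequilibrium, no
imputation-quality structure and no realistic allele-frequency spectrum.
Consequently, passing tests demonstrate the correctness of the pipeline's
estimators and decision rules under the stated generative model — not
robustness to LD misspecification or array artefacts.

## Aneuploidy calling

Samples are summarised by the median log-R ratio (mLRR) over X markers and
over male-specific-Y markers, chromosome-1 LRR SD, and the fraction of X
markers heterozygous in BAF.  Quality control fails samples with chr1 LRR
SD strictly above 0.28 or in an excluded genotyping batch.  Calling is
per-platform:

* **X loss (females).** Candidates must fall below the platform screen
  (HOEE −0.28, GSA −0.20) *and* show chromosome-wide loss of
  heterozygosity (BAF heterozygous fraction < 0.05, a configurable,
  automatable proxy for visual BAF review).  The mosaic fraction is
  mLRR / reference-minimum, where the reference minimum is the most
  negative complete-45,X mLRR on that platform.  Fractions ≥ 0.80 are
  called 45,X (complete to nearly complete), fractions in [0.60, 0.80)
  are called 45,X/46,XX, and below 0.60 no call is made.  The boundary at
  exactly 0.80 goes to the complete class and exactly 0.60 is included —
  a deterministic convention where the verbal rules are ambiguous.
* **Reference minima.** Defaults are HOEE −0.47 and GSA −0.34, chosen so
  the printed screens correspond to a 45,X ratio of ~0.60.  This is
  deliberate: the screen approximated the upper bound of the male X-mLRR
  distribution, which is the same thing as the 0.60 ratio bound, and any
  reference minimum at or above screen/0.6 would make the mosaic class
  unreachable.  Both minima are configuration values.
* **Age-related loss.** Low X mLRR with preserved heterozygosity is
  emitted as `ambiguous` — acquired loss removes a random X per event and
  does not produce chromosome-wide LOH — never force-fit to a germline
  karyotype.  Sex-inconsistent signals (Y material in an EHR-documented
  female, no Y in a male) are likewise ambiguous.
* **Gains.** X or Y mLRR above +0.10 (configurable; the published
  per-platform gain thresholds are in supplementary material not
  reproduced here) call 47,XXX / 47,XXY / 47,XYY according to Y presence.

45,X and 45,X/46,XX are analysed together as one "45,X" group downstream.

## Variant curation

Site QC: indels fail when QD < 5.0 and DP < 10; SNVs fail when QD < 3 and
DP < 7; anything with allelic balance below 0.15 fails.  Putative
loss-of-function = high-impact consequence, excluding start-loss and
variants confined to the last or penultimate exon; the terminal-exon rule
is applied to LDLR, APOB and PCSK9 but not to single-exon MC4R (the
bundled gene-rule table records applicability; exon-count bookkeeping is
all that is needed, so no GFF parsing).  Pathogenic missense requires a
P/LP assertion with ≥ 2 ClinVar stars; two APOB variants (p.Arg3527Gln,
p.Arg3527Trp) are whitelisted FH-causing regardless of review status.
MC4R p.Leu328Ter is excluded (functional receptor).  PCSK9
gain-of-function missense is not treated as monogenic FH.  16p11.2
BP4-BP5 CNVs must overlap ≥ 95% of chr16:29,638,675–30,188,534 (GRCh38);
copy number < 2 is a deletion, > 2 a duplication.  An MC4R whole-gene
deletion and the LDLR exon 13–17 tandem duplication are recognised by the
same overlap predicate.  A sample carrying both an FH and an FHBL variant
is contradictory for LDL-C and is excluded from that trait with a logged
warning (no published guidance; contradictory labels cannot be analysed).

## Inclusion and pre-adjustment

One member of each pair with PI_HAT > 0.1875 is removed; third-degree
pairs (PI_HAT > 0.09875) are broken only inside a first-degree family
network (connected components over PI_HAT > 0.40 serve as a lightweight
proxy for pedigree reconstruction).  Removal is deterministic: the member
with more missing phenotypes, then the lexicographically larger id.
Heights of exactly 10 cm (data entry) and below 121 cm with an
amputation-related code are excluded, as are samples flagged
non-European-ancestry by the generator.

Height and BMI are aggregated as per-sample medians over visits, LDL-C as
the maximum documented value (approximating the untreated state).  Each
trait is regressed on age, six ancestry PCs and genotype batch separately
by sex, **fitting on variant-negative samples only**; carriers are
residualized with the same coefficients and standardized by the reference
residual moments.  Whether the original analysis standardized with
carriers included is not stated; projecting carriers prevents large
carrier shifts from distorting the null scale, and at ~2% carrier
prevalence the difference is negligible.  Singular designs raise an error
naming the collinear column.

## Polygenic scores

Candidate weight sets — one per tuning parameter ρ — are *inputs*: the
Bayesian LD-reweighting that produces them in practice is an external
published method and is out of scope.  The generator fabricates a
ρ-family by blending the true weights with noise, with quality decaying
in |log10(ρ/ρ*)| (ρ* = 0.1 by default; the real ρ grid is a supplementary
detail and is configuration here), so tuning has a recoverable optimum.
Selection maximises the squared Pearson correlation between score and
adjusted trait on the validation cohort (ties to the smaller ρ; constant
scores score 0).  Scores are standardized on the variant-negative testing
cohort and cut into 100 rank-based percentile bins on that population
(stable ties, bin sizes within 1); carriers are mapped onto the same cut
points.  Tertiles are rank thirds within one carrier group.

## Statistics

All estimation uses standardized traits.  Carrier effects and
within-carrier polygenic effects are OLS with normal-approximation
two-tailed p-values and 95% CIs at ±1.959964·SE (Student-t corrections are
negligible at these n); Spearman's rank correlation accompanies the
within-carrier fits.  Carrier effects are also re-estimated adjusting for
the trait's PGS.  The percentile-equivalence of a carrier group is the bin
whose mean trait is nearest the carrier mean; extreme-bin contrasts are
OLS of carriers against the top (or bottom) bin's members.  Direction
concordance across the eleven disorders uses the exact two-tailed binomial
signs test at 1/2.  Multiple testing is Bonferroni per trait (height 4,
BMI 3, LDL-C 4 disorders).  Power for a correlation explaining R² at
sample size n is the Fisher-z approximation
Φ(λ − z₁₋α/₂) + Φ(−λ − z₁₋α/₂) with λ = atanh(√R²)·√(n−3), using the
trait-level validation R² with the carrier group's n — this is the
combination that reproduces the published power column — and without the
small-sample bias-correction term.  Equality of the polygenic coefficient
between carrier-negative and carrier-positive models is tested with
z = (β₋ − β₊)/√(se₋² + se₊²); the denominator is the standard pooled form
for coefficients estimated in disjoint samples (the subtraction form that
appears in print is not a valid variance and can be negative).  Statin and
CAD odds for top-percentile-bin membership come from maximum-likelihood
logistic regression with Wald CIs; perfect separation raises a diagnostic
error rather than returning an unbounded estimate.

## Numerical and design choices

* Determinism: every stochastic step draws from a `numpy` Generator
  seeded from the run seed; stages are pure functions of (config, seed),
  and the pipeline manifest records config, seed, stage counts and SHA-256
  digests of all outputs, which are bit-identical across reruns.
* Ties: percentile/tertile assignment uses stable sort order; ρ ties go to
  the smaller ρ; pruning ties are resolved lexicographically.
* Degenerate inputs raise: empty marker masks, non-negative reference
  minima, all-carrier or no-carrier contrasts, constant scores among
  carriers, empty bins/tertiles, singular designs, separation.
* Problem sizes: generator defaults are full study scale (31,430 + 609);
  the demo configuration used by the analysis scripts and the end-to-end
  tests runs 6,000 variant-negatives, a 300-SNP panel and a 1,500-sample
  validation split, which preserves every qualitative behaviour while
  keeping a full run under a few seconds.  Statistical unit tests that
  need tight Monte-Carlo error use the light standardized-trait simulator
  at full n instead of the full generator.

## Known limitations

* No LD, no imputation modelling, no real allele frequencies; one latent
  factor drives all three traits' polygenic components, so cross-trait
  score correlations are unrealistically high (harmless here because each
  trait is analysed separately).
* The aneuploidy signal model is Gaussian around karyotype means; real
  LRR/BAF artefact structure (waviness, GC effects) is not emulated, so
  caller performance on synthetic data bounds, but does not establish,
  performance on real arrays.
* CAD and statin status are planted binary labels on the extreme
  polygenic bin, not products of an EHR phenotyping algorithm.
* Power values for two FHBL rows in the published table are mutually
  inconsistent with their printed R²/n (they match exactly if swapped);
  the package computes, it does not "correct".
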