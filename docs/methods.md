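# Methods

This note documents the statistical procedures `cnvtrait` implements,
the model behind its synthetic data, the defaults and why they were
chosen, and what the test suite does and does not establish.

## Coordinates and formats

All coordinates are 1-based inclusive in memory (the PennCNV call
convention); BED files are 0-based half-open on disk and converted only
at the I/O boundary. Chromosome labels are normalized by stripping a
`chr` prefix; `X` is literal. The inclusive span `end − start + 1` is
used for every filtering and burden computation; the kb figures printed
in report tables use the `end − start` difference rounded to the nearest
integer, which is the convention the published report tables follow
(`call_span_kb`).

## Call-level and sample-level QC

A call is retained iff confidence ≥ 10 **and** span ≥ 20,000 bp **and**
probe count ≥ 10 **and** the fraction of its span covered by the union
of exclusion regions is < 0.50. All thresholds on the keep side are
inclusive; the exclusion-overlap rule is strict. Overlap fractions are
anchored on the call's own span (not reciprocal).

Adjacent calls of one sample with equal copy number on one chromosome
are joined when `gap / (B.end − A.start + 1) ≤ 0.20` with
`gap = B.start − A.end − 1`; overlapping calls always merge. Joining
iterates to a fixed point, so the output contains no joinable pair.
Merged probe counts add; merged confidence is the member maximum (which
preserves the ≥ 10 pass/fail status); joining across different copy
numbers is not meaningful and never happens.

A sample is dropped (with all its calls) iff it has **more than** 100
autosomal calls or an LRR standard deviation **above** 0.35. X calls do
not count toward the call limit.

Gene annotation attaches every gene whose transcript span, extended
50 kb on both sides, intersects the call; the flank is applied to the
transcript span (the UTR-specific reading is not resolvable without
transcript substructure). A call is *exonic* iff an exon interval
intersects it. A call is *rare* iff fewer than five reference-catalogue
events overlap at least 50 % of its span; reference rows carry event
counts so several catalogued events at one locus count individually.

## Composite phenotypes

PC1 is the first principal component of the correlation matrix of the
six standardized reading/language measures, computed per cohort on
complete cases only (listwise deletion). Only the first component is
used downstream, so the oblique rotation a factor-analysis package would
offer is a no-op and PC1 is taken unrotated. Loadings are reported as
correlations (eigenvector × √eigenvalue); the sign is fixed so the first
trait loads positively, matching the convention that reading measures
load positively on the shared-performance axis. Scores are standardized
to unit variance. IQadjPC1 is the OLS residual of PC1 on performance IQ
(intercept included); residuals are exactly uncorrelated with PIQ and
the operation is idempotent.

Case/control labels come from the distribution of the discriminant
composite: at or below the 10th percentile → case (poor reading), at or
above the 90th → control, ties included in the extreme group. A
fixed-threshold mode (< −1.4 case, > 2.2 control) reproduces the
published absolute cutoffs.

## Family-respecting permutation association

The probe-wise test regresses the score on the binary CNV+ state
(OLS slope). The null distribution permutes **scores**: within every
sibship the scores are shuffled, and whole sibship score blocks are
swapped across sibships of equal size. Siblings' scores are
exchangeable within a family and family blocks of equal size are
exchangeable with each other, so the permutation distribution is exact;
empirical calibration over 5,000 null replicates gives type-I error
0.046 at α = 0.05 with 199 permutations (the 0.045 expected from
permutation-count discreteness). p = (1 + #{|b*| ≥ |b|}) / (1 + n_perms),
two-sided. The family-based association software the protocol emulates
decomposes between/within-family components internally; that
decomposition is not reproduced — the implemented contract is
"score-on-state association with permutations that respect sibship
structure", which is the property the protocol relies on.

Monomorphic probes return p = 1, direction 0, and are excluded from
scans. The single-probe variant stops early once 100 exceedances have
accumulated (the p estimate is then stable to within a few percent);
scans share one permutation set across probes, which is valid because
the permutations are data-independent.

X-chromosome probes are tested separately in males (baseline copy 1) and
females (baseline 2) and the strata combined with the same weighting
scheme as cohorts. Strata without variation drop out; a probe
monomorphic in both sexes is untested.

## Meta-analysis

Per-cohort results combine by the sample-size-weighted scheme:
z_i = Φ⁻¹(1 − p_i/2) · sign(effect_i), Z = Σ √N_i z_i / √(Σ N_i),
p_meta two-sided from Z. Probes tested in only one cohort are excluded
from the meta table but kept in per-cohort output. A permutation p of 0
cannot occur with the (1+k)/(1+n) estimator; defensively, zero inputs
are clamped to 1e-300.

## Regions of CNV overlap

A region is a maximal run of consecutive tested probes with p below the
flank threshold that contains at least `core_len` consecutive probes
below the core threshold and at least `flank_len` member probes beyond
the core (on either side, in any split). Schemes: CNV-state
(0.005, 2, 0.05, 2); intensity (0.001, 2, 0.05, 2). Untested
(monomorphic or missing) probes break runs — a region cannot jump a
manifest gap. The implementation is validated against exhaustive window
enumeration on 1,000 random p vectors.

Because all probes under one CNV share carriers, each CNV footprint is
effectively a single test; at the nominal thresholds a genome-wide scan
therefore yields a handful of chance regions (the permutation floor at
the core threshold makes a footprint qualify with probability roughly
core_p). This mirrors the screening behaviour of the protocol, where
regions are nominal findings unless they survive the Bonferroni
threshold `α / (n_traits × n_probes)` — e.g. 0.05 / (2 × 5,173) ≈
4.8 × 10⁻⁶ for a two-trait meta-analysis of 5,173 probes.

## Intensity association

The score is residualized on the first two principal components of the
sample-by-probe LRR matrix (computed by SVD on probe-centered data;
the PCA also serves outlier screening), then per probe the residualized
score is regressed on raw LRR and tested with the same permutation
engine. The Spearman correlation between LRR and the unadjusted score is
reported as the effect surrogate and direction. Only autosomes are
tested. The variance-components model of the specialized intensity
association tool this stage emulates is not public; the implementation
here is a deliberate simplification that keeps every stated property:
per-probe intensity regression, intensity-PC covariates,
family-respecting permutation, rank correlation as direction.

Outlier screening flags samples whose score on any of the first two
components deviates from the median by more than 6 MAD-scaled robust
standard deviations; the rule is configurable since the original
criterion is unstated. At desk scale (19,000 autosomal probes) the
leading components partly track recurrent CNV loci, so the screen flags
some large-CNV carriers along with genuinely noisy samples; on real
~700k-probe arrays loci are diluted and the components are
batch-dominated. This is a scale artifact of the synthetic genome, not
of the rule.

## Burden statistics

Burden is computed per sample on the merged, QC-passing calls: event
count and total inclusive span, for classes all / gene / exon / rare /
short (< 100 kb) / medium (100–500 kb, inclusive) / large (> 500 kb).
The three length classes partition "all" exactly. Correlation with the
continuous scores is the median Spearman ρ over 100 random samplings of
one individual per sibship (rank-based because burden is heavily
non-normal). Alongside the median p over resamples, the result carries
the p of a single representative draw: overlapping resamples make the
median-p rule conservative (measured type-I ≈ 0.008 at α = 0.05),
whereas a single one-per-family draw is an exactly calibrated test. The
case/control analysis fits a logistic regression of status on burden per
resample; draws lacking both classes are redrawn, complete separation
excludes the draw (counted), a constant burden reports OR 1, p 1.

## Co-segregation screens

Two calls in different individuals count as "the same CNV" when they
overlap reciprocally by ≥ 50 % and agree in direction (loss vs gain
relative to the sex-specific baseline); clusters are single-linkage
transitive closures, so membership is order-independent. The shared-CNV
screen reports clusters carried by ≥ 2 affected co-siblings of one
sibship and absent — no ≥ 50 %-reciprocal same-direction call — in
unaffected members of that family and, in the default strict mode, in
every unaffected participant cohort-wide. Candidate-list screening
applies the 50-kb flank when the candidate is a gene and attaches a
per-family verdict: co-segregation iff every carrier in the family is a
case and at least one case carries.

## Interval-permutation enrichment

The statistic per gene set is the number of independent case intervals
(per-sample union-merged, duplicates across siblings collapsed)
overlapping at least one member gene ± 50 kb. Each permutation replaces
every interval with a random run of equally many consecutive
CNV-covered probes, uniform over feasible starts within chromosomes, and
recomputes the statistic; p = (1 + exceedances) / (1 + n_perms),
Bonferroni-corrected across tested sets. The two-stage bootstrap
correction of the reference interval-enrichment tool is deliberately
simplified to this one-stage test, which preserves the statistic and
the probe-matched null construction. Composite candidate sets are built
by case-insensitive keyword match on set names (e.g. all sets containing
"axon guidance"), taking the union of member genes.

## Synthetic data model

The generator emulates a two-cohort sibship study on an array scaffold:

* **Cohort**: 150 sibships of size 2–3 (P(2) = 0.8), ~330 children; 78 %
  of sibships labeled "RD"-ascertained, the rest "ADHD"; sex
  Bernoulli(0.5). One-child-per-monozygotic-pair selection is assumed
  already applied, so twins are not duplicated.
* **Genome**: 20 chromosomes (19 autosomes + X) × 1,000 probes at ~4 kb
  spacing (20,000 probes total — a desk-scale stand-in for a ~700k
  array), genes with exons, a centromere-like and a telomere-like
  exclusion region per chromosome, and a reference CNV catalogue with
  per-locus event counts.
* **CNV landscape**: private background events (Poisson mean 5 per
  sample, lognormal lengths with median 65 kb), ~25 recurrent
  polymorphic loci at 1–8 % frequency, sib-sharing probability 0.3, and
  one designated causal region (default: a 30-probe window on
  chromosome 2, placed away from the centromere-like exclusion zone)
  deleted in a configurable fraction of samples. These rates were
  calibrated once so QC-passing output matches the published cohort
  anchors — median 6 CNVs and ~600 kb covered per sample, with most
  calls gene-annotated and roughly a quarter rare — and were not revisited.
* **Intensities**: LRR mean shift per copy number (−3.5, −0.66, 0,
  +0.40, +0.68 for copies 0–4; configurable), Gaussian noise SD 0.15,
  2 % of samples rendered at SD 0.5 to exercise the sample QC; BAF
  cluster patterns per copy number on request.
* **Calls**: boundaries snapped to probes with ±1 probe jitter;
  confidence is evidence-scaled (per-probe increment × copy-state
  weight + noise), so marginal short calls fail the ≥ 10 filter while
  large clean events pass, as with HMM likelihood scores; ~0.5 false
  positive calls per sample with short lengths and weak confidence.
* **Phenotypes**: six traits `λ_t F + √(1−λ_t²) ε`, with cohort-specific
  loadings patterned on the published per-cohort PC1 loadings (giving
  ~63 % / ~52 % PC1 variance explained at scale), latent factor F with
  within-sibship correlation 0.4, causal carriers shifted by
  `causal_beta` on F; performance IQ correlated 0.3 with F, verbal IQ
  0.5; discriminant composite 0.5·word-reading + 0.3·spelling +
  0.2·orthographic-coding, re-standardized (the published discriminant
  function is not public; weights are configuration); 0.6 % missingness
  per trait, matching the published complete-case attrition.

Everything derives deterministically from one master seed via per-stage
streams. What the generator does **not** emulate: raw array output and
genotype calling, linkage disequilibrium between probes, GC-content
waves and batch structure in LRR (the "batch" analog is the per-sample
noise level), genuine HMM call artifacts (boundary jitter and false
positives are simple surrogates), and population structure. Passing
tests therefore establish the correctness and calibration of the
statistical machinery on data with the study's declared structure, not
robustness to every artifact of real array data.

## Problem sizes and runtime choices

Default pipeline scale (~330 samples, 20,000 probes, 2,500 permutations
for both scans, 500 enrichment permutations, 100 burden resamples) runs
in well under a minute on one CPU; permutation counts were chosen so the
permutation floor (1/(n+1)) sits below the region core thresholds,
making region calling meaningful. Null-calibration studies in the test
suite use 500–800 replicates at 199–399 permutations; the
planted-effect recovery study uses 50 replicates of a 400-sample
single-cohort design at 2,000 permutations, scanning the causal
chromosome.

## Known limitations

* With ~20 expected carriers at 5 % frequency in 400 samples, a 0.8-SD
  effect has at most ~73 % power to reach the two-sided region core
  threshold p < 0.005 even before QC attrition and PC1 measurement
  attenuation; the end-to-end recovery rate measured over 50 replicates
  is ~66 %. Claims that such an effect is recovered in ≥ 80 % of
  replicates hold only under a one-sided reading of the test; the
  two-sided test is kept because the emulated association tools report
  two-sided p values.
* The median-p burden summary is conservative (see above); use the
  representative-draw p for calibrated inference.
* Region detection treats each CNV footprint as one effective test;
  nominal-threshold regions are screening output, not discoveries.
* No mixed-model (kinship) alternative to resampling/permutation is
  provided; no liftover between genome builds (the build is carried as
  an opaque config tag).
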