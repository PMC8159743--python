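# Methods

## Scope and model

`dietcross` implements the statistical pipeline of a diet-response QTL study in
an F2 intercross between two inbred mouse lines (B6 × FVB): single-marker
genome scans under a combined sex/diet model, permutation-based genome-wide
thresholds, LOD-drop support intervals, conditioned scans for pleiotropy,
residual-regression causal inference between traits sharing a locus, an
observed-variable path model of the trait network, and the descriptive
statistics (Welch/Student/Wilcoxon tests, fold changes, broad-sense
heritability) that frame such a study. Because no real genotype/phenotype data
ship with the package, a synthetic-cross generator provides data with the
statistical structure every downstream stage assumes.

## The scan statistic

At each marker the trait is fitted by ordinary least squares under

    y ~ sex * diet + marker

with the marker a three-level factor (B6/B6 reference, 2 df). The reported
score is **−log10 of the partial-F p-value** for the marker term. We call this
"lod" throughout because that is the convention of the study design this
package serves; it is *not* the classical likelihood-ratio LOD, although for a
2-df test the two scales coincide exactly in the large-sample chi-square limit
(the survival function of χ²₂ at 2·ln10·L is 10^−L). The classical LOD,
(n/2)·log10(RSS_reduced/RSS_full), is emitted as an extra column. Signed
profiles carry the sign of the FVB-homozygote effect: positive means the FVB
allele increases the trait.

Rows are complete-case per marker; markers with a single observed genotype
class are flagged and skipped; markers with two classes get a 1-df test on the
available indicator. Numerically-zero p-values are capped at lod = 300.

Implementation: a scan is a rank-2 update of one shared covariate regression,
so the engine computes every marker (and every permutation replicate) by block
elimination of the covariate block from per-class sufficient statistics —
two (markers × individuals) × (individuals × 5) matrix products per replicate
plus closed-form 2×2 Schur complements. Per-marker missing genotypes are
handled exactly via per-marker cross-product corrections. The plain
single-marker reference implementation (`marker_regression`) is kept and the
engine is tested against it to 1e-9 relative agreement, and against a
closed-form one-way ANOVA oracle.

## Permutation thresholds

Genotype rows are shuffled as a block against intact (phenotype, covariate)
pairs, preserving the covariate–trait relationship under the null of no
linkage (the permutation scheme is a design choice; alternatives that permute
the trait alone would break the sex/diet association). The genome-wide maximum
lod is recorded per replicate and threshold(α) is the empirical (1−α)
quantile. On a study-scale null cross (1667 evenly spaced markers, 20 linkage
groups, 1400 cM, n = 469, standard-normal trait) 10,000 permutations put the
5% threshold at ≈3.9 and the 1% threshold at ≈4.7. The 99th-percentile
estimate needs many replicates: at 2,000 permutations its run-to-run spread is
roughly ±0.2, so the acceptance script uses 10,000 (about 20 s on one CPU).

## Support intervals

The 1.5-lod-drop interval spans all contiguous markers within `drop` of the
chromosome peak, extended by one flanking marker below the cut on each side
where available (a conservative convention); peak ties break leftmost. On
simulated single-QTL chromosomes the interval covers the true locus in ≥90% of
replicates at moderate effect sizes.

## Variance explained, interactions, conditioned scans

Variance explained is 100 × (SS_model with marker − SS_model without) /
SS_total on the analyzed rows; stratified estimates use a marker-only model
within one sex × diet cell. Sex/diet-by-marker interactions use sequential-SS
ANOVA of `y ~ sex*diet*marker` (statsmodels). Two-locus interactions report
the interaction coefficient of a configurable dichotomized grouping (default:
locus a B6/B6 vs rest × locus b carries-FVB vs not) with a Wald CI and F-test.
A conditioned scan adds a second trait as covariate; |ΔLOD| ≥ 2.0 at a peak
calls the locus shared (pleiotropic) between the traits, the 2.0 figure
corresponding to a 5% type-I error rate for this decision.

## Causal inference

For two traits T1, T2 sharing a locus, each trait is residualized on the other
plus sex, diet and sex:diet; residuals R1 and R2 are tested against the
3-class locus factor (2-df F; an additive-coded t-test would be the special
case of collapsing the factor). Holm–Bonferroni corrects the two p-values.
Rejecting only R1 ⇒ T1 upstream (locus→T1→T2); only R2 ⇒ T2 upstream; both ⇒
independent effects; neither ⇒ undetermined. On synthetic mediation chains
(locus→serum trait→body-composition trait) the correct upstream call is made
in ≥90% of replicates at moderate mediation; with direct effects on both
traits the "independent" call dominates. Two caveats surfaced during
development and are reflected in the tests rather than hidden:

* recovery is *not* monotone in the mediation coefficient — when mediation is
  total, conditioning the upstream trait on the downstream one removes most of
  the locus signal, and the undetermined rate rises;
* the AIC/BIC comparison of the two directed regressions (downstream ~
  upstream + sex*diet + locus) does **not** identify causal direction in this
  model class. With the locus in both models, both conditionals are correctly
  specified Gaussians; standardized, the criterion tracks conditional noise
  shares (algebraically favoring the reverse regression under mediation), and
  unstandardized it is dominated by the response scale (grams vs ng/mL can
  differ by thousands of AIC units). The scores are reported because they are
  part of the analysis this package reproduces, with a comparability note
  attached; the residual classification is the direction inference.

## Path model

The structural model is a recursive system over observed variables only: each
equation regresses a z-scored outcome on z-scored predictors (sex and diet
indicators, their product, marker loci coded additively as FVB-allele count,
or other traits), so coefficients are standardized paths; declared outcome
pairs get residual correlations. This per-equation least-squares formulation
reproduces the standardized paths of a recursive path diagram exactly; no
latent variables or covariance-structure optimizer is needed or provided.
Per-predictor variance shares are last-entry: 100 × (SS gained adding the
predictor last)/SS_total — they need not sum to the equation R² unless
predictors are orthogonal. Pruning removes the largest-p path above α
(ties by declaration order) and refits until all retained paths are
significant; the result is a fixed point of the procedure.

## Descriptive statistics

Welch (Satterthwaite df) and pooled t-tests accept raw vectors or printed
(mean, SD, n) summaries — the summary entry points exist so published group
summaries can be re-analyzed exactly. The Wilcoxon rank-sum test is exact for
tie-free samples with min(n) ≤ 8, otherwise a tie-corrected continuity-
corrected normal approximation; the shift estimate is Hodges–Lehmann with a
distribution-free CI (the normal-approximation order-statistic bounds).
Broad-sense heritability is H² = (V_F2 − V_F1)/V_F2 truncated to [0, 1]: the
F1 cohort is genetically uniform so its variance is environmental. The
literal variance ratio V_F2/V_F1 (which can exceed 1) is available behind
`literal_ratio=True` for comparison.

## Quality control

Outliers are values more than k = 3 *sample* SDs (strict inequality, n−1
denominator) from their sex-group mean, set to missing and re-screened
iteratively (batch per iteration) until none remain; groups with < 3 observed
values are skipped with a warning and zero-SD groups remove nothing. Grouping
is sex-only by default (configurable). Markers are dropped when monomorphic or
when missingness exceeds 10% (an artifact default; array-level call-quality
filtering is out of scope and emulated by the generator's uniform missing
mask). Trait–trait correlations are Pearson correlations of residuals after
sex + diet + sex:diet (interaction removable by flag).

## The synthetic cross

Meioses follow a no-interference crossover process: along each chromosome the
gamete allele is a two-state Markov chain with switch probability
r = (1 − e^(−2d/100))/2 between markers d cM apart (Haldane). An F2 genotype
is the union of two independent F1 gametes, giving 1:2:1 segregation and the
Haldane decay of linkage, both verified against closed forms. The X chromosome
is simulated and scanned like an autosome (the design it emulates reported
autosomal loci only); it can be excluded by subsetting the map. Phenotypes are
intercept + sex + diet + sex:diet + Σ locus terms (additive × modifier +
dominance), optional epistasis terms restricted to a stratum, an optional
mediated (λ × upstream trait) contribution, and Gaussian noise. Missing
genotypes contribute their population-mean effect; the missing-data mask is
uniform at a configurable rate.

The default configuration mirrors the study scale: n = 469 F2s of both sexes
on two diets, 20 cohort animals per parental/F1 line, 1667 markers on 20
linkage groups totaling 1400 cM (mouse-like relative lengths, 2 Mb/cM), three
fat-gain loci (linkage groups 1, 5, 7), a lean-gain locus coincident with the
group-5 fat locus, a serum-HDL locus linked to (16 markers proximal of) the
group-1 fat locus, a +5 g epistatic interaction in ketogenic males between the
group-5 and group-1 loci, 2% missing genotypes, and trait scales in grams
(noise SD 3.2 and 2.2 for fat/lean gain) and ng/mL (noise SD 45 for HDL). The
group-5 effects are sex- (×1.6) and diet- (×1.9) modulated with the base
effect chosen so the stratum-average matches the combined-model contrast —
ketogenic males then carry the dominant variance share. Scalar effect fields
accept per-trait mappings because the traits live on different scales.

What the generator does *not* emulate: array intensity data and call-quality
scores, genotyping error, uneven real marker spacing and LD clustering,
non-Gaussian trait distributions, litter/cage effects, and polygenic
background beyond the configured loci. Passing tests therefore demonstrate
correctness of the statistical machinery under the assumed model, not
robustness to those real-data features; in particular the permutation
threshold reproduces the study values under even marker spacing and Gaussian
traits, which is a statement about the scan's null distribution, not about
any particular dataset.

## Problem sizes and seeds

Simulation-based tests use: 10,000 permutations for the threshold check, 200
replicates for calibration/coverage/classification rates (binomial tolerance
bands), n = 2000 for parameter-recovery checks, cohorts of 1000 for
heritability (sampling SD of the estimator ≈ 0.012 there). All randomness
flows through `numpy.random.default_rng` seeds; identical seed + config is
byte-identical output, which the pipeline's JSON report relies on (no
timestamps; the provenance block records config hash, version and seed).

## Known limitations

* No interval mapping between markers (multipoint HMM genotype
  probabilities) and no multi-QTL model search; scans are single-marker.
* The X chromosome receives no dosage-compensation-aware model.
* Cross-response AIC/BIC comparability caveat above.
* Holm correction is applied within a causal test (m = 2); no multiplicity
  correction is applied across traits or across descriptive comparisons,
  matching the analysis design this package reproduces.
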