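# Methods

## Scope and model

`mirstage` analyses two independent cohorts, each consisting of a raw
miRNA count matrix (features × samples), a matched pre-normalized mRNA
matrix, and a binary stage annotation (stage I vs stage II/III, the
locally advanced group being the positive class throughout).  The
package covers the statistical analysis only: read-level processing
(adaptor trimming, collapsing, miRNA alignment and isomiR annotation)
and microarray/CQN mRNA normalization are out of scope — mRNA matrices
are accepted as already normalized, continuous values.

## Normalization

Size factors follow the median-of-ratios convention: for every feature
detected in all samples, compute the ratio of each sample's count to
the feature's geometric mean, and take the per-sample median of those
ratios (on the linear scale).  Factors are rescaled to geometric mean
1, which pins the overall count scale; the consequence is that
rescaling one library's depth changes the normalized matrix only by a
global additive constant on the log scale, not in any between-sample
contrast.  If no feature is detected everywhere, the estimator refuses
and asks the caller to prefilter rather than guessing.

The variance-tempering transform is a shifted log,
log₂(count/s_j + pseudocount), with pseudocount 1 by default.
Empirical-Bayes regularized-log or variance-stabilizing transforms
would shrink low-count features harder, but the downstream consumers
are a logistic classifier (insensitive to the exact monotone
transform of its inputs after internal z-scoring) and Spearman
correlation (invariant to any monotone transform), so the simple
shifted log is used for both.

## Differential expression

Counts for feature *g* in sample *j* are modelled as negative binomial
with mean μ = s_j·m_group(j) and variance μ + αμ².  The dispersion α is
estimated per feature by the method of moments on depth-corrected
counts, (var − mean)/mean², floored at 1e-8.  The estimator pools all
samples, so for genuinely differential features the between-group
variance inflates α and the resulting standard errors — a conservative
choice that costs little power at the fold changes of interest.  No
empirical-Bayes dispersion shrinkage, outlier-count handling or
independent filtering is applied: the package's contribution is the
cross-cohort procedure, and the DE engine only needs to be a correct
NB Wald test.

Group means are maximum-likelihood at the fixed dispersion.  Because
the two-group log-link model is orthogonal in the group log-means,
each mean solves the one-dimensional score equation
Σ_j (y_j − s_j m)/(1 + α s_j m) = 0, whose left side is strictly
decreasing in log m; a safeguarded Newton iteration finds the unique
root.  The Wald statistic is ln(m₂/m₁) divided by its standard error
√(1/I₁ + 1/I₂) with group information I_g = Σ_j μ_j/(1 + αμ_j),
referred to N(0,1); q-values are Benjamini–Hochberg across the tested
features of one cohort.  Features with zero counts everywhere are
excluded with a notice.  Features with all-zero counts in exactly one
stage group have no finite ML log fold change; both group means get a
+0.5 shift (for the fold change and, since the information vanishes at
a zero mean, for the Wald statistic as well) and the record is flagged
`zero_group`.

The discovery filter retains q < 0.05 and |log₂FC| > log₂ 1.5, both
strict, in either direction.

## Cross-cohort validation

Validation deliberately uses the nominal two-sided p (not FDR):
discovery screens ~1400 features, validation tests a short
pre-specified list.  A hit validates when its mature-mapped validation
record exists, p < 0.05 (strict), and the fold change has the same
sign.  Precursor-level records are expanded to all mature arms with
statistics copied verbatim — one precursor measurement speaking for
both arms is a known granularity loss, accepted because no arm-level
information exists in such datasets.  The pipeline reports validated
hits in both directions and counts them separately (`n_up_late`,
`n_up_early`).

## Classifier, ROC, calibration

The signature model is an ordinary binomial GLM fitted by IRLS
(convergence: max coefficient change < 1e-8 within 100 iterations).
Predictors are z-standardized internally; coefficients are stored on
the standardized scale and exposed on the raw scale.  Perfect
separation is reported via `converged=False` plus a warning flag
rather than an exception, since permuted-label refits can separate by
chance.

The ROC curve is empirical: one point per distinct score threshold.
Its trapezoidal area equals the Mann–Whitney statistic U/(n₁n₀) with
ties counted ½, which is how the AUC is computed.  The 95% CI is
DeLong's variance estimate with a normal interval, clipped to [0, 1];
the CI method is an assumption — the convention for empirical ROC
curves — as is the in-sample evaluation (fit and ROC on the same
cohort), which mirrors the apparent-performance convention; an
optional stratified cross-validated mode exists
(`evaluate_signature(..., cv_folds=k)`) but is off by default.

Calibration: Brier score = mean (prob − outcome)²; slope = coefficient
of a logistic refit of outcomes on logit(prob); intercept from the
offset fit with slope fixed at 1 (calibration-in-the-large).  The
fixed-slope intercept convention is an assumption recorded here.

## Permutation null

Because an in-sample AUC from a refitted 19-coefficient model is
optimistic even under the null, significance uses a relearned-
classifier permutation null: shuffle the labels, refit from scratch,
record the in-sample AUC against the shuffled labels, repeat B times.
The empirical p uses the add-one convention (1 + #{null ≥ obs})/(B+1),
never zero at finite B.  Permutations are drawn independently
(collisions negligible at n = 127).  Standardization depends only on
the expression matrix, so refits reuse the standardized design;
non-convergent refits keep their final-iteration AUC and are counted.

## Integration

Candidate pairs are the target-map edges whose miRNA is in the
validated signature.  Spearman ρ is the Pearson correlation of average
ranks; p-values use the t approximation on n − 2 degrees of freedom
(adequate at cohort scale), with an exact-permutation fallback below
10 samples.  BH adjustment is applied across all candidate pairs
within one cohort's screen — the most direct reading of a pairs-level
FDR, recorded as an assumption.  Significant pairs have ρ < 0 and
q < 0.1 (strict); an unsigned mode exists for sensitivity analyses.
The concordant set is the pairs significant with negative ρ in both
cohorts, ordered by the worse of the two q-values.

## Synthetic data

The generator emulates the study conditions: two cohorts of 127
samples, stage-I prevalence 41/127, 1426 miRNA features, 19 planted
miRNAs overexpressed in stage II/III with the fold-change spectrum
reported for validated stage-associated miRNAs (1.58–4.59), and 3
planted inverse miRNA–mRNA pairs.  Counts are negative binomial with
variance μ + αμ² (α = 0.2 by default), matching the DE model's
mean–variance form; baseline means are log-uniform over e^1.6–e^6.2
(≈5–500 counts); per-sample depths are log-normal with σ = 0.25.  The
mRNA matrix is generated directly on a continuous log-like scale, as
both real cohorts' mRNA arrive pre-normalized; planted target genes
follow baseline + pair_effect·(miRNA log₂ abundance, centred) +
N(0, 1) with pair_effect = −1.  None of the cohorts' depth or
dispersion characteristics are published, so these defaults are chosen
for plausibility, not fidelity.

Two random streams make twin cohorts: structural draws (baseline
means, which features/pairs are planted) depend on the seed alone and
are therefore shared; sampling noise is seeded by (seed, cohort
label).  Seeds are explicit arguments everywhere; no global RNG state.
The toy target map contains every planted pair plus a configured
number of decoy edges drawn from non-planted combinations; when
planted miRNAs exist, decoy miRNAs are drawn from the planted set so
decoys actually compete inside the screen (otherwise decoy edges would
mostly attach to non-signature miRNAs and never be tested).

What the synthetic data does *not* model: isomiRs, FASTQ-level noise,
batch and FFPE artifacts, correlated miRNA co-regulation, tumor-purity
gradients, or age confounding.  Planted effects are consequently much
cleaner than FFPE reality: the in-sample AUC of the fitted signature
saturates at 1.0 on default synthetic cohorts, where the real-data
analogue was ~0.85–0.9.  Passing tests therefore demonstrate that the
machinery is correct and calibrated (null inputs produce null outputs;
planted structure is recovered), not that real cohorts would achieve
any particular performance.

## Problem sizes and numerical choices

The test suite and the acceptance script run at the study's scale
(1426 × 127 per cohort) for single runs, and use 8–20 seed replicates
for averaged properties; the permutation B is 10000 in the acceptance
pipeline run and 99–200 in repeated-null experiments.  Dispersion
floor 1e-8; IRLS weight floor 1e-10; probabilities clipped to
[1e-12, 1 − 1e-12] before logits; Newton steps clamped to ±5 on the
log-mean scale; BH ties handled by stable sorting.  Degenerate inputs
fail loudly: single-class labels, constant vectors in correlation,
all-zero features (dropped with notice), matrices whose ids collide.

## Known limitations

- Precursor→mature expansion duplicates statistics to both arms.
- Moment dispersion is conservative for strongly differential features.
- The DeLong CI degenerates to a point at AUC = 1 (zero variance).
- In-sample evaluation overstates discrimination by construction; use
  the cross-validated mode for honest estimates on real data.
- The Spearman t approximation is crude below ~10 samples (the exact
  fallback covers that range).
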