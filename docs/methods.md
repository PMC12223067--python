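# Methods

`synores` re-implements, as a tested pipeline, the analysis chain used to
predict response to biologic therapy in rheumatoid arthritis from baseline
synovial-biopsy transcriptomes: count normalisation and variance
stabilisation, negative-binomial differential expression, cell-subset
module scoring, molecular clustering, nested cross-validated response
classifiers per drug class, calibration of a hybridisation-count
(nCounter-style) panel onto the sequencing scale, and a unified
three-drug allocation rule. Because patient-level trial data cannot be
bundled, a ground-truthed synthetic-cohort generator provides the inputs
for every test and for the acceptance script.

## Count model and variance stabilisation

Counts are modelled as negative binomial with mean `mu_gs = q_g * s_s`
(gene baseline times per-sample size factor) and dispersion following the
parametric trend `alpha(mu) = a1/mu + a0`, giving variance
`v(mu) = mu (1 + a1) + a0 mu^2`. Size factors are median-of-ratios
(geometric mean anchored at 1). The VST is the closed-form antiderivative
of `1/sqrt(v(mu))` rescaled to log2 units,

    vst(q) = 2 log2( sqrt(a0 q) + sqrt(a0 q + 1 + a1) ) - log2(4 a0),

which is finite at zero, strictly increasing, and converges to `log2(q)`
for large counts; it is verified against numeric integration of the
variance function to 1e-4 log2 units. We deliberately use the parametric
closed form instead of spline machinery; a `log2(q+1)` fallback exists
behind an explicit flag for dispersion-free data.

The dispersion trend is fitted by ordinary least squares of the raw
(unclamped) method-of-moments dispersions on `1/mean`, with the fitted
coefficients clamped at zero. Two numerical choices matter and are
deliberate: clamping *before* the fit would bias both coefficients upward
under Poisson noise (the Poisson null must recover `a0 = a1 = 0`), and
genes with mean normalised count below 1 are excluded from the fit
because the moment ratio `(var - mean)/mean^2` is dominated by its random
denominator there and drags the trend. Per-gene reported dispersions are
clamped at zero as usual. No shrinkage of gene-wise dispersions toward
the trend is performed; the Wald test below uses the trend value
directly, which simulation shows is adequately calibrated at cohort
scale (type-I error 0.044-0.052 at alpha = 0.05 across seeds, n = 100,
2000 genes).

## Differential expression

Per gene, a log-link negative-binomial GLM with design
`[intercept, responder, covariates...]` is fitted by IRLS (vectorised
across genes; dispersion fixed at the trend value evaluated at the gene's
mean). The responder coefficient is tested with a two-sided Wald test
against a standard normal — no t correction and no fold-change
shrinkage; both simplifications are validated by the type-I simulation
above and a log2FC bias check (|bias| < 0.08 at a true shift of 1 log2
unit, n = 100). Muscle contamination of biopsies is removed by including
the first principal component of the 17 skeletal-muscle marker genes
(ACTA1 ... TNNT3) as a covariate; the PC sign is fixed so that higher
scores mean more muscle expression (genes are not scaled before the PCA
by default, matching `prcomp`'s default).

Multiplicity uses Storey's q-value with a single-lambda pi0 estimate at
lambda = 0.5; when pi0 = 1 this reduces exactly to Benjamini-Hochberg,
which the tests assert. The three-drug comparison assigns E+/R+/T+,
mixed (two-drug) categories, or exclusion when a gene is significant for
all three drugs; polar coordinates project the three log2 fold changes
onto axes at 90° (E), 210° (T) and 330° (R). The axis order is a
convention and configurable. Module-level activity is a Welch-style
aggregation of member-gene fold changes — mean log2FC with squared
standard error `sum(se^2)/m^2`, optionally inflated by
`1 + (m-1) rho_bar` from the mean pairwise residual correlation — a
documented simplification of full posterior-convolution gene-set tests.
Over-representation analysis is a one-sided hypergeometric tail against
user-supplied GMT libraries with BH adjustment.

## Module scores and subset abundance

Bulk samples are scored against cell-subset marker sets by the
bin-matched control scheme: genes are ranked by average expression into
24 bins, each member gene draws up to 100 control genes from its bin
(members are never their own controls; the pool widens to neighbouring
bins when a bin holds only members), and the score is mean member minus
mean control expression. Scores are exactly shift-invariant and recover
an injected 2-unit spike within ±0.05 on a 1000-gene matrix. The shipped
subset marker sets and the 71-gene B-cell module are synthetic
placeholders (the published lists live in external resources); users
substitute real lists as GMT files. B-cell rich/poor classification
averages per-gene z-scored expression over the module and splits at the
predefined cutoff −0.0413 (the reference-cohort median); a score exactly
at the cutoff is labelled poor (strict inequality for rich) — the
boundary convention is ours, stated because the upstream definition is
silent. Differential subset abundance is OLS of score on the response
indicator (identical to an equal-variance t-test, asserted against the
scipy oracle), with optional empirical-Bayes variance moderation via a
moment-matched inverse-gamma prior — a light-weight analogue of
moderated t-statistics, not a reimplementation of them.

## Clustering

Gene clusters: k-means (Lloyd, k-means++ with 25 seeded restarts) on
per-gene z-scored VST expression of the genes passing the
`filterByExpr`-style rule (CPM equivalent of min.count = 20 in at least
`10 + 0.7 (n - 10)` samples, total count >= 5e5; thresholds
configurable — the "most expressed" gene counts emerge from the
thresholds, not from a target number). Samples: hierarchical clustering
with Pearson-correlation distance and complete linkage, exported as
Newick. Cross-cohort cluster overlap is scored hypergeometrically;
cluster-phenotype association uses chi-square with a Fisher fallback for
2x2 tables whose expected counts are <= 5, and Kruskal-Wallis for
continuous variables.

## Nested cross-validation engine

The prediction procedure is the contribution, so all fold logic is
bespoke and instrumented: stratified outer folds (class counts within one
sample of proportionality), inner folds partitioning exactly the outer
training samples, t-test or sparse-embedded gene filtering strictly
inside each outer training fold, inner-CV hyperparameter tuning on log
loss (binary) or R² (ordinal), and pooling of outer-fold predictions per
repeat before any metric is computed. Clinical covariates (sqrt-TJC,
sqrt-SJC, sqrt-ESR, log(CRP + 1 mg/L), VAS, RF and CCP titres) bypass the
gene filter and are always offered to the learner. A deliberately leaky
variant (filter before the folds) ships *only* as a test harness to
demonstrate selection bias: on null data it inflates AUC by ~0.3 while
the nested estimate stays at 0.48-0.52.

Three reference learners implement the model families, as
sklearn-compatible estimators: coordinate-descent elastic-net logistic
regression (glmnet objective, cross-checked against
`LogisticRegression(saga)` to 2e-3), gradient-boosted depth-limited trees
with Newton leaf updates (importance = total split gain), and ridge
regression on the 4-level disease-activity codes (remission < 2.6, low
[2.6, 3.2), moderate [3.2, 5.1], high > 5.1; response = code <= 1).
Ordinal predictions map to a response score via
`sigmoid((1.5 - code)/tau)` with tau = 0.5 — the midpoint and monotone
map are our convention; AUC is invariant to tau. Additional learners
plug in through a registry adapter. AUC is the Mann-Whitney statistic
with half-credit ties, asserted equal to brute-force pairwise
concordance. The default fold plan is 10x10 with 25 repeats; the CLI
defaults to 5 repeats for desk-scale runs. Variable-importance stability
reports mean, standard error and selection frequency across outer folds.
Final models are fitted on the whole cohort after a last round of CV
tuning and serialise to JSON (coefficients or trees plus the feature
scaling contract), so predictions reproduce exactly without refitting.

## Platform bridge

RCC lane files are parsed section-wise (Code_Summary dialect:
`CodeClass,Name,Accession,Count`). Normalisation is positive-control
geometric-mean scaling per lane followed by a housekeeping
geometric-mean factor on the stable housekeeping probes (geometric, not
arithmetic, means — the platform convention; ISY1, STK11IP and TFRC are
excluded by default after stability screening). Housekeeping stability
is the geometric CV `sqrt(exp(sd_log^2) - 1)` of positive-normalised log
counts, flagged above 0.2. Background flooring at mean + 2 sd of the
negative probes exists but is off by default. Panel design retains genes
with mean raw count <= 10,000 and max >= 100.

Cross-platform calibration fits, per gene, `VST ~ b0 + b1 ln(norm + 1)`
on matched samples (>= 3, zero-variance genes skipped); the stored
coefficients convert any future normalised run to pseudo-RNA-Seq on the
VST scale for direct model input. The calibration direction (VST
regressed on log counts, so conversion is a forward application) and the
natural-log-plus-one convention are documented choices; the synthetic
run generator inverts the same convention, making the noise-free round
trip exact up to count rounding (median absolute error < 1e-3 log2
units; at noise sd 0.1 the median per-gene Pearson r is ~0.97 and
per-subject model probabilities move by < 0.06). External validation
against a reference cohort uses per-gene location-scale adjustment of
the target onto the reference, with optional moment-based shrinkage of
the per-gene offsets and log scale ratios across genes (a simplified
reference-anchored analogue of empirical-Bayes batch adjustment);
zero-variance target genes get a location-only adjustment.

## Allocation rule

Each subject is scored by the three drug-class models independently and
allocated to the class with the highest predicted response probability;
if all three are below 0.5 the subject is biomarker-negative. Exact ties
resolve by the fixed priority TNFi > IL6i > B-cell depletion and are
flagged rather than silently resolved (a tie-break had to be invented;
flagging keeps it visible). The rule is exhaustively verified against a
brute-force reference on the full 0.01 probability grid. Probabilities
are raw model scores; no recalibration step is applied by default.

## Synthetic cohorts: what they emulate and what they do not

The generator draws gene baselines log-normal (meanlog 4, sdlog 2 on the
count scale, spanning the panel filters' dynamic range), library factors
uniform on [0.5, 2], NB counts with per-entry dispersion `a1/mu + a0`
(defaults 2.0 and 0.05), three arms at response rates 0.57 / 0.74 / 0.61,
and clinical covariates with plausible marginals. Response arises from a
per-arm logistic model whose intercept is solved numerically so the
expected rate equals the target.

The response signal has two modes. In the default `latent` mode each arm
has a latent severity `u ~ N(0,1)` per sample; the arm's 40 informative
genes shift by `effect_size_log2fc * u` and response is
`logistic(1.9 u + clinical effects)`. The latent design makes the
prediction ceiling come from label noise rather than gene noise: with
the default coefficient 1.9 the oracle AUC (classifying by `u` itself)
is ~0.85, which is the regime in which feature selection is feasible and
nested CV can be meaningfully evaluated against a known ceiling. In
`group` mode informative genes shift by a fixed amount in responders
only, giving an exact group-level log2FC truth for differential
expression bias checks. DAS28-ESR is drawn from truncated normals on
[0.5, 3.2) for responders and [3.2, 9.4] for non-responders (means 2.4
and 4.8), so the < 3.2 dichotomy is exact by construction without
implementing the DAS28 component formula. Muscle contamination inflates
the 17 muscle markers by 5 log2 units in a configurable sample fraction;
latent cluster structure can shift gene blocks per cluster. Matched
hybridisation-count runs are generated by inverting the stored per-gene
calibration truth (`b0 ~ N(0, 0.5)`, `b1 ~ N(1, 0.1)` clipped at 0.5)
with Gaussian log-scale noise, lane factors, rounding, and appended
housekeeping / positive-ladder / near-zero-Poisson control probes.
`permute_response` builds null cohorts by permuting the
(response, DAS28) pair jointly within arm — jointly, because the
response label and the score must stay coherent.

What the generator does *not* emulate: gene-gene co-expression beyond
the injected latent factors, pathotype histology, joint-level clinical
structure, batch or cartridge artefacts beyond scalar lane factors, or
any real marker-gene biology (gene identities are arbitrary). Passing
tests therefore demonstrate the statistical correctness of the
procedures — unbiasedness, calibration, recovery, round-trip identities —
not clinical performance on real cohorts.

## Problem sizes used in tests and the acceptance script

Simulations are sized to exercise each property at desk scale: null
nested CV at n = 200 with 600 genes (5x5 folds, 5 repeats, averaged over
5 label permutations — a single permutation's nested AUC has Monte-Carlo
sd ~0.05, so the unbiasedness measure is the permutation average, as in
a permutation test); signal recovery at n = 150 with 800 genes and 40
informative (the acceptance script redraws on a deterministic seed
sequence until the realised oracle AUC lies in [0.82, 0.88], i.e. it
conditions on the stated design point, never on the measured outputs);
differential-expression calibration at 2000 genes x 100 samples. The
full suite runs in under two minutes on one CPU.

## Known limitations

- Dispersion estimation is moments-plus-trend without per-gene shrinkage;
  at very small n (< ~30) the Wald test will drift anticonservative.
- The module-activity test is a Welch aggregation, not a posterior
  convolution; its VIF correction floors the mean correlation at zero.
- Variance moderation and batch adjustment are simplified analogues of
  their canonical empirical-Bayes implementations, adequate for the
  pipeline's use but not drop-in replacements.
- The ordinal model treats disease-activity codes as equally spaced.
- Probabilities feeding the allocation rule are not calibrated; an
  optional Platt-style recalibration is a natural extension.
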