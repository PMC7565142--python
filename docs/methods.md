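# Methods

## Scoring model

The synergy score is the mean deviation of observed combination growth
from the Bliss-independence expectation over the dose grid, in percent
growth units.  The implementation follows the observed-minus-expected
sign convention throughout: the score of a grid whose combination wells
sit `delta` percent above the Bliss expectation is `+delta`, and the
binary synergy call is `score > 10` (strict; a score of exactly 10 is
non-synergistic).  Expected growth truncates each single-agent growth
fraction at 100 before taking the product, and switches to the
min rule when either single agent is at or below zero (net stasis or
kill).  For growth fractions confined to [0, 100] the score is bounded
by [-100, 100] and both extremes are attainable; the bound is *not*
enforced outside that domain — negative observed combination growth can
legitimately push the score outside it, and no clamping is applied.

Missing combination wells are excluded from the mean with the averaging
count reduced accordingly; replicate averaging, if the assay has
replicates, is assumed to have happened upstream of the reader.  A
control endpoint equal to the time-zero measurement makes the growth
fraction undefined and raises an explicit error naming the record.

Pair selection: a drug pair enters the association analysis when it is
synergistic in at least `min_synergistic` (default 5) training cell
lines.  Selection is computed on the training cohort only, since the
scans are fitted there.

## Calls and filters

* Activity: a gene is active where its detection call is `P`.  Marginal
  (`M`) calls count as inactive by default — the activity rule is
  present-vs-absent — with a `marginal_active` switch for sensitivity
  analysis.
* Essentiality: dependency score strictly below -0.5; exactly -0.5 is
  nonessential.  Lowering the threshold can only remove essential
  calls (monotonicity is property-tested).
* Expression filter: retain a gene iff its active-cell count strictly
  exceeds 0.2 x (number of training cell lines) — with 43 cells this
  means at least 9 — and its coefficient of variation (sample SD with
  ddof 1 divided by the mean of the normalized values) is at least 0.1.
  Genes with nonpositive mean have undefined CV and are excluded under
  the CV rule.
* Essentiality filter: retain genes essential in at least one training
  cell line.  The much stricter pan-essential reading ("essential in
  all cells") is available as `essential_rule="all"` but keeps almost
  nothing and is not the default, because only the at-least-one reading
  is consistent with a genome-scale surviving gene set.

## Features and design matrices

Counts and ratios are computed over the post-filter gene universes by
default, so ratio denominators match the gene sets that actually enter
the scan; computing against the unfiltered genome is possible by
passing unfiltered call matrices.  Ratios with a zero denominator are
defined as 0.

Per-pair designs: pair-level set sizes (target union/intersection) and
the pathway size never vary across cell lines, so they are dropped as
zero-variance columns — they are listed in the feature table for
completeness but cannot enter a per-pair regression.  Remaining columns
are z-scored (a pure numerical-stability choice: Wald and LRT p-values
are invariant to affine rescaling of predictors, which is asserted in
the tests), and columns linearly aliased to earlier columns are removed
greedily in the declared column order via incremental Gram-Schmidt with
a relative tolerance of 1e-8.  A design with no surviving column is
degenerate and yields an NA p-value with reason `degenerate`.

## Logistic fits and p-values

One p-value per model: a single retained predictor reports the
two-sided Wald p of its slope; several predictors report the
likelihood-ratio p of the full model against the intercept-only model
(whose maximum likelihood is available in closed form).  Fits use
Newton-Raphson maximum likelihood (statsmodels `Logit`).

With ~43 cell lines and often fewer than 10 synergistic ones,
complete or quasi-complete separation is expected.  A fit falls back to
Firth-penalized likelihood when the MLE fails to converge, emits a
separation warning, produces non-finite standard errors, or yields a
slope beyond 12 on standardized predictors (odds ratios beyond e^12 per
SD are not estimable at this sample size).  The Firth fallback
maximizes the Jeffreys-penalized likelihood by modified-score Newton
steps with step-halving, and reports the penalized LRT p against the
Firth-fitted intercept-only model, flagged as `firth_lrt` with a
convergence indicator — never silently.  P-values are floored at
1e-300 to stay within (0, 1].  Responses with a single class give NA
with reason `no_events`.

## Aggregation and multiple testing

* Minimum-p aggregation: per gene over pairs (gene scan) and per pair
  over pathways (DD level); NA p-values are ignored in the minimum and
  an all-NA group stays NA.  The naive expected counts below are not
  adjusted for the minimum statistic; the DD-level FDR entries are
  therefore optimistic in the usual way for min-p summaries and should
  be read as descriptive, matching common practice for this table
  layout.
* Bonferroni thresholds are computed exactly as `alpha / m` (for
  example 0.05 / (165 x 114) = 2.66e-6).  The genome-scale shortcut of
  rounding `0.05/3024 ~ 0.05/4381` to 1e-5 is available as a documented
  preset, not hard-coded.
* FDR tables: per threshold t, `observed = #{p <= t}` among non-NA
  p-values, `expected = round(t * n_tests, 2)` — rounded to the two
  decimals at which such tables are conventionally printed, which is
  required to reproduce their quotients exactly — and
  `FDR = expected / observed` (NA when nothing is observed).  The
  unrounded quotient is also emitted as `fdr_raw`.  `n_tests` stays the
  design size of the scan (pairs, or pairs x pathways), counting models
  whose p-value is NA.

## Wilcoxon validation

The validation cohort has expression data only, so validation is a
single-feature comparison: the number of active pathway genes per cell
line (the raw count, not the ratio) between cell lines with and without
synergy for the pair.  The two-sided rank-sum test uses the exact
permutation null when the pooled sample has no ties and at most 20
observations, and otherwise the normal approximation with tie and
continuity corrections; the method used is always reported.  An
all-identical pooled sample returns p = 1.  Empty groups (for example
no synergistic validation cell) give NA with a warning.

## Synthetic-study generator

The generator emulates the structure of the real study: 43 training and
16 validation cell lines, 3000 genes, 165 pathways (20-200 genes,
uniform), 69 drugs with 1-6 targets each, 114 drug pairs, 3x3 dose
grids.  Presence calls are Bernoulli with per-gene Beta(2, 2)
prevalence (marginal calls at 5% of the non-present mass); expression
values are log-normal with per-gene location N(6, 1) and log-SD
U(0.2, 0.6), giving CVs mostly above the 0.1 filter; dependency scores
are N(-0.1, 0.25) in non-essential cells and N(-0.8, 0.2) in essential
cells, with a per-gene essential-cell fraction from Beta(1, 6).

Synergy is planted at the (pair, cell line) level *through the pathway
expression feature*: for a causal pair, the true-synergy probability is
`logistic(beta0 + beta1 * z)` where z is the z-scored active-gene count
of the causal pathway (standardized on the training cells and applied
to both cohorts), with defaults beta0 = -1.4 (background prevalence
~0.20) and beta1 = 1.1 (odds ratio ~3 per SD).  Non-causal pairs use
the intercept alone.  True synergy is written into the dose-response
data as a positive Bliss deviation: combination wells are
`Z + delta * S + noise` (delta default 30 score units, well noise SD 5
percent), monotherapy wells follow decreasing three-parameter logistic
curves in dose with per-(drug, cell) parameters k in U(0.8, 2) and
midpoint U(1, 3), staying within [0, 100] before noise.  The planted
deviation is added (not subtracted) so that planted synergy produces
*positive* scores under the observed-minus-expected sign convention and
the `score > 10` call recovers the labels; this placement routes signal
through the pathway analyses (PA2/PA3) while leaving the target-only
analysis (PA1) mostly null.  Raw endpoints are emitted with T0 = 100
and control 400, both noiseless, so the reader recovers the simulated
growth fractions exactly; the fraction of wells falling outside
[0, 100] after noise is reported in the ground-truth sidecar.

What the generator does **not** emulate: tissue-of-origin structure and
expression covariance between genes, probe-level microarray noise,
correlation between expression level and presence call, shRNA
off-target structure, or dose-grid layouts other than a full factorial
grid.  Passing tests therefore demonstrate correctness and calibration
of the statistical machinery under a clean generative model, not
biological validity on real screens.

Named fixtures (scaled down for speed, cohort sizes kept at 43 + 16):
`tiny` (6 cells, 30 genes, 4 pathways, 3 pairs; hand-checkable),
`null` (400 genes, 40 pathways, 30 pairs; no feature effect:
beta1 = 0, causal fraction 0 — labels are random with respect to every
feature while delta keeps the label-to-score link intact), and
`strong_signal` (300 genes, 12 pathways, 12 pairs; causal fraction 0.5,
beta1 = 1.2, delta 40).

## Calibration checks and problem sizes

* Null calibration: on the `null` fixture, PA2 expression +
  essentiality scans give >= 2000 per-(pair, pathway) fits at n = 43;
  the fraction of p <= 0.05 must lie in the binomial 99% band around
  0.05.
* Signal recovery: 50 replicates of a 2-pair, 8-pathway study with a
  planted odds ratio above 3 per SD; the causal pathway must attain the
  per-pair minimum p (PA2, expression — the modality carrying the
  planted signal) in a majority of replicates.
* Effect recovery: the mean score of planted-synergy grids must equal
  delta within three standard errors; label recovery from dose-response
  must meet the analytic bound derived from the noise model (the score
  of a null grid is a mean of 9 noisy wells plus shared monotherapy
  noise, so its SD is below the well noise SD and the flip probability
  across the +10 margin is below Phi(-2)).

These sizes keep the default suite around half a minute on one CPU
while leaving each check statistically meaningful.

## Known limitations

* The expected-count rounding in the FDR tables is a presentation
  convention; `fdr_raw` should be preferred for downstream computation.
* Min-p aggregation without a null adjustment makes DD-level expected
  counts anti-conservative descriptors, as noted above.
* The Firth fallback reports a penalized LRT even for single-predictor
  models, so the p-value family changes at the separation boundary;
  the `method` column makes this visible.
* Pearson correlation on raw p-values (as in the modality-correlation
  summary) is dominated by the bulk of non-significant values; the
  Spearman coefficient is emitted alongside for that reason.
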