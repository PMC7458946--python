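# Methods and design notes

This note documents the statistical procedure implemented by `cifrisk`,
the assumptions behind the synthetic-data generator, and the numerical
and design choices made where the method leaves room.

## Problem setting

The unit of analysis is one quality-assurance **activity** — an audit or
a regulatory inspection of one investigator site within one study in one
calendar year.  An activity yields zero or more findings per Clinical
Impact Factor (CIF).  Only presence matters to the risk question asked
here, so each CIF is a binary classification: did the activity produce
at least one finding of that CIF?  Five independent logistic models are
fitted, one per CIF.  The goal is a *well-calibrated, interpretable*
risk estimate, not an optimal classifier: audit programs operate in a
low signal-to-noise regime where flexible learners happily fit noise,
which is why the feature set is hand-crafted and the model is plain
maximum-likelihood logistic regression without regularization.

## Feature engineering

All model inputs are binary indicators built from study and site
covariates:

- **Continuous covariates** (enrollment, screen-failure rate, screening
  duration per enrolled patient, AE reporting latency, concurrent-trial
  counts) are Yeo-Johnson power transformed (λ by maximum likelihood,
  via `scipy.stats.yeojohnson`), standardized to mean 0 / SD 1, and
  binned into 5 quantile segments.  Segment indicators, or fixed
  thresholds identified during exploration (enrolled < 5, > 32;
  screen-failure rate > 0.62; AE latency ≤ 2 days), are the candidate
  features.
- **Categorical covariates** (country, phase, therapeutic area, design)
  are binarized per level after pooling levels below 5% prevalence into
  `other`.  Missing values always map to 0 ("no").
- **Site burden score**: within each study, sites are ranked (ascending,
  ties by average rank) by the number of other sponsor trials running
  concurrently at the site in the same therapeutic area; the rank
  divided by the number of sites gives a score in (0, 1].  The band
  indicator `score > 0.75` flags the most burdened quarter.
- **Interaction**: randomization and design are combined into exactly
  two flags — non-randomized parallel-or-sequential, and non-randomized
  single-group — at most one of which is set.  No automated interaction
  search is performed; this is the single interaction the domain
  analysis supports.

Any engineered feature whose realized prevalence falls below the 5%
rare-level threshold is dropped (near-zero-variance predictors never
reach the models).  The prevalence rule is applied after missing→0
imputation, because the prevalence must describe the column the model
actually sees.

A correlation screen computes all pairwise Pearson correlations of the
candidate columns.  Pairs with |r| > 0.3 are flagged and never
co-selected.  The 0.3 bound is a deliberate design choice: comfortably
above the ≈0.2 magnitudes tolerated in practice on data of this kind,
low enough to keep coefficients individually interpretable.  (In the
synthetic data the mutually exclusive therapeutic-area indicators reach
|r| ≈ 0.45 and are correctly barred from co-selection.)

## Model fitting and selection

Fits use Newton/IRLS maximum likelihood (`statsmodels.Logit`),
certified by a score-vector norm below 1e-8.  Complete separation is
detected up front (per-feature scan) and reported as an error naming
the separating feature; a singular Hessian (quasi-separation or
collinearity) is reported likewise.  The null model is closed-form
(intercept = logit of the event rate).

Feature selection minimizes BIC = (1 + k)·ln n − 2·ℓ by greedy forward
search: starting from the null model, each step adds the candidate that
lowers BIC most, stopping when no candidate lowers it.  Ties are broken
alphabetically by feature name, which together with sorted candidate
processing makes the search deterministic and invariant to row and
column order.  Greedy search is not guaranteed globally optimal; on
simulated candidate sets of ≤ 10 features it matches the exhaustive
2^k-subset minimum in ≥ 95% of cases (verified in the test suite by
full enumeration).  Selection runs on the 2011–2015 window only (to
control overfitting to later years); the selected set is then refit on
all years for the final coefficients.

## Validation

Backtesting mimics annual audit planning: one split per calendar year
from the second observed year on, training on all strictly earlier
years.  Test activities whose study appears in any earlier year are
excluded from the test set (training keeps them) — otherwise the model
is rewarded for recognizing studies rather than risk factors.  Same-year
repeat activities are not excluded, and a split whose test set empties
entirely is dropped with a warning.  Feature selection is *not* redone
per split; only coefficients are refit.  Features constant within a
training window are dropped from that split's refit, and splits with a
single-class training outcome are skipped, both with warnings.

Metrics: rank-based (Mann–Whitney) AUC with half-credit for ties, and
the Brier score (mean squared error of the probability).  Aggregates
are means with SE = sd(ddof = 1)/√(number of splits); a single-class
test set leaves that split's AUC undefined (NaN) while its Brier still
counts.

## Calibration

Pooled test-set predictions from all splits are divided into 4
equal-width bins over their observed range (range-based, not
quantile-based; half-open [lo, hi) bins, last bin closed; an
all-identical prediction set degenerates to a single bin with a
warning).  Each bin's observed event rate gets a Wilson score 75%
confidence interval (CI75); Wilson rather than Wald because the bins
are small and rates sit near 0/1.  The curve is then built by:

1. folding empty bins' ranges into the nearest non-empty neighbor
   (left neighbor on ties);
2. while a bin whose CI75 contains the base rate is adjacent to another
   such bin, merging the two (toward the neighbor with the closer
   observed rate, ties toward larger n), pooling counts and ranges and
   recomputing the CI75 — pooling like bins sharpens the interval and
   may resolve it either way;
3. defaulting every remaining base-rate-overlapping bin to the base
   rate; all others keep their observed rate.

A bin merges only with a neighbor that *also* overlaps the base rate:
merging into a decisively deviating neighbor would dilute that
neighbor's evidence, and the merge-or-default semantics requires a
default branch to be reachable.  Note the flip side: a spurious CI75
exclusion (a 25% false-positive rate per bin is inherent in a 75%
interval) in an otherwise flat region is kept, so null-effect runs can
occasionally show a nonzero calibrated range.  A constant curve has
width exactly 0.

At application time a prediction outside the fitted range clamps to the
first/last step (the curve defines the trustworthy boundaries; it is
not extrapolated), and a prediction on an interior edge belongs to the
right-hand step.  The curve's step values span the **calibrated
prediction range**; its width Δ is the headline per-CIF quantity: how
far the model can credibly move the risk off the base rate.

## Synthetic-data generator

The generator emulates the descriptive shape of a large sponsor's QA
program and gives every downstream stage a known ground truth.

Defaults (all configurable through `GeneratorConfig`):

| parameter | default | meaning |
|---|---|---|
| `n_years` / `start_year` | 8 / 2011 | program span 2011–2018 |
| `audits_per_year` | 86.7 | Poisson mean of annual activity volume |
| `inspection_fraction` | 0.13 | share labeled inspection (no risk effect; audits and inspections are pooled) |
| `mean_findings_per_audit` | 5.9 | overall mean finding count per activity |
| `cif_base_rates` | .55/.84/.86/.59/.76 | marginal presence rate per CIF (consent, data integrity, protecting primary endpoints, safety, sponsor oversight) |
| `n_studies` / `sites_per_study` | 150 / (2, 8) | study pool and per-study site counts |
| `true_coefficients` | see `DEFAULT_TRUE_COEFFICIENTS` | ground-truth log-odds per CIF |
| `seed` | 0 | fixes every output bit-for-bit |

Mechanics: studies carry phase / therapeutic area / randomization /
design / pediatric covariates and stay auditable for a geometric number
of years (mean 2), so a fraction of studies is audited in several years
— this is what the CV exclusion rule needs to bite.  Sites carry
country, enrollment (negative binomial, mean 18), screen-failure rate
(Beta(2,2)), screening duration (lognormal), concurrent-trial count
(Poisson) and AE latency (exponential); these distributions are chosen
so every thresholded feature (enrolled < 5 / > 32, screen failure
> 0.62, burden band, latency band, screening top quintile) has
prevalence ≥ 0.05 and the thresholds sit inside the support.
Covariates are drawn independently within their family — the simplest
structure that exercises every engineered feature.

Per CIF, presence is Bernoulli(sigmoid(b_c + Σ β·x)) on the binary
truth features.  The intercept b_c is solved by root-finding over the
*realized* activity rows so the in-sample expected presence rate equals
the configured base rate exactly (the standalone
`intercept_for_base_rate` solves the same problem over independent
Bernoulli marginals by exact enumeration of the binary support).  Given
presence, the finding count is 1 + Poisson(μ), with a single μ for all
CIFs chosen so the overall mean findings per activity hits its target;
this reconciles a presence-only model with a realistic findings-per-
activity mean.  A configuration whose mean findings target is below the
sum of base rates is rejected as infeasible.

Default true coefficients put moderate effects (|log-odds| 0.5–0.9) on
the risk factors the per-CIF models identify in practice — US sites and
pediatric studies raise consent risk, oncology and slow AE reporting
raise safety risk, small low-burden sites lower data-integrity risk,
non-randomized designs lower sponsor-oversight risk, phase I and
neuro/psychiatry studies raise primary-endpoint risk.  Magnitudes were
fixed once to emulate a weak-signal regime (backtest AUCs land around
0.55–0.70).

What the generator does **not** emulate: auditor site-selection bias
(sites are sampled uniformly), free-text finding statements (counts are
generated directly per CIF), country-portfolio imbalance beyond a fixed
country mix, year-over-year drift (the risk structure is stationary),
and within-site outcome correlation beyond shared covariates.  Passing
tests therefore demonstrate that the *pipeline* recovers a known
structure under clean conditions, not that real audit data contain such
structure.

## Problem sizes

The default generator scale (~700 activities over 8 years) mirrors the
emulated program and is the scale used throughout the test suite.
Repetition counts were sized for stable Monte-Carlo averages: 40/20
seed batches in the acceptance script (SEs of a fraction of a percent
on the headline statistics), 50 seeds for recovery/null selection
rates, 30 simulated candidate sets for the greedy-vs-exhaustive
comparison, 1,000 random instances for the AUC oracle.

## Known limitations

- Presence-only modeling ignores multiplicity; a Poisson count model is
  the natural extension and deliberately out of scope here.
- Greedy BIC selection bounds, but does not guarantee, global
  optimality.
- The CI75-based step calibration inherits a 25% per-bin false-positive
  rate by construction (see above); with 4 bins, occasional spurious
  steps are expected and visible in null simulations.
- Exploratory alternatives with built-in feature selection (decision
  trees, random forests, lasso) are intentionally not implemented: in
  this signal regime they select noise features as readily as real
  ones, which defeats the interpretability requirement.
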