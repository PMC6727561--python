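# Methods

`pathpanel` implements the computational workflow around a custom digital
counting (nCounter-style) gene-expression panel for small cancer cohorts:
panel design from overexpression training data, control-based normalization,
two-profile pathway-activity scoring, negative-binomial differential
expression, hypergeometric gene-set enrichment, and survival stratification.
A synthetic-data generator with known ground truth stands in for patient,
cell-line and proteomics inputs, so every stage can be validated end to end
by parameter-recovery and calibration experiments.

## Count model and the synthetic generator

Endogenous counts are generated as negative binomial with mean

    m_gj = d_j * 2^(mu_g + a_j * delta_g) + lambda,   Var = m + phi * m^2

where `mu_g` is a per-gene baseline drawn uniformly on a log2 range (default
5–11, i.e. typical panel counts of ~32–2048), `a_j in [0, 1]` the latent
pathway activity of sample j, `delta_g` the true log2 effect of signature
gene g, `d_j` a lognormal lane size factor (default sd 0.15 on the natural-log
scale), `phi` a single global dispersion (default 0.05; `phi = 0` degenerates
to Poisson, drawn as a gamma–Poisson mixture otherwise), and `lambda` the
background mean (default 5 counts). Positive controls are Poisson with mean
proportional to their nominal concentration (200 counts/fM over the standard
128–0.125 fM ladder); negative controls are Poisson(lambda). Housekeeping
genes share the baseline model with no activity effect.

Cohort simulation adds: proteomics = activity + Gaussian noise (default sd
0.1); drug EC50 as a rank-remap of `-activity + tau * noise` with `tau`
solved by bisection so the Spearman correlation with activity hits a target
(default −0.8) within 0.05; and survival times that are exponential with
hazard `h0 * exp(gamma * a)` (default gamma 2; h0 set so median survival is
roughly two years for recurrence-free survival), censored by an independent
Uniform(0, 1.5 × median) time, which yields roughly 30 % censoring — a
censoring rate typical of retrospective cohorts, chosen once since no rate
is dictated by the data model. Random streams are split per component
(panel/counts/survival/ancillary) from one seed, so enlarging one component
does not reshuffle another.

What the generator does **not** emulate: FFPE degradation profiles,
probe-specific hybridization efficiencies, lane imaging artifacts,
gene–gene correlation beyond shared signature membership, and non-exponential
hazards. Passing recovery tests therefore demonstrate correctness of the
estimators under the stated model, not robustness to those real-data
features.

## Normalization

The scheme follows the vendor-default workflow: per-lane positive-control
factor `pos_j = mean_l(geomean_l) / geomean_j` (so the spike-in geometric
mean is equalized across lanes), flooring of pos-scaled values at a
background threshold count T (default 20 — "threshold" semantics, not
subtraction, keeping log2 finite), a housekeeping content factor computed
the same way on pos-scaled, floored housekeeping counts (geometric lane
average by default, arithmetic behind a switch), then log2. Zeros are mapped
to 1 before geometric means and flagged `zero_control`. Lanes with a
positive factor outside [0.3, 3] or housekeeping factor outside [0.1, 10]
are flagged, never dropped.

Because the anchor (the mean of control geometric means) is data-dependent,
rescaling any lane — or all lanes — shifts the whole log2 matrix by one
additive constant while leaving every within-matrix contrast unchanged;
the tests assert this uniform-shift form of scale invariance.

## Activity scoring

Each signature carries per-gene baseline/activated means (mu0 from GFP
lanes, mu1 from overexpression lanes) and a pooled SD floored at 0.1 log2
units (the floor prevents a near-zero-variance gene from dominating the
precision weighting). A sample's activity is the precision-weighted
least-squares projection of its expression onto the mu0→mu1 axis, clamped to
[0, 1]; with adaptive gene selection on, per-gene weights are
responsibilities of a consistent component `N((1-a)mu0 + a*mu1, sigma^2)`
(prior 0.8) against a wide baseline `N(mu0, (3*sigma)^2)`, iterated with the
activity update to a 1e-6 fixed point (≤100 iterations). This two-profile
constrained-regression scorer is a deliberate simplification of Bayesian
factor-model scoring toolkits: it preserves the interface (scores in [0, 1],
an adaptive flag, per-gene weights) and is isolated so a full Bayesian
implementation could replace it behind the same API. Scores are computed
per sample with no cross-sample coupling, so cohort composition cannot leak
into an individual score.

## Signature design

Candidate gene lists are ranked by a moderated standardized effect
`z_g = (mean_active - mean_GFP) / (s_g + s0)` with `s0` the median pooled SD
(an additive shrinkage offset in the SAM tradition; the panel-design
toolkit's Bayesian gene selection is not re-implemented, and this ranking is
isolated in one function for substitution). Candidates are nested prefixes
on a 5-gene grid down to 5 genes. Selection procedures: per-pathway lengths
under a total budget of 150 genes by exact dynamic programming on the grid
(default "sum" semantics; a greedy "union" mode counts shared genes once,
since published per-signature lengths can exceed a stated cap unless
overlaps are pooled); single-signature selection by the most negative
Spearman correlation of candidate activity with drug EC50, or by the largest
standardized mean separation between activated and control samples (pooled
SD floored at 1e-6); blocklist filtering (default heat-shock screen:
HSP*/DNAJ* prefixes, user-suppliable list) with removal counts reported; and
literature-signature reduction to the top k = 25 genes by mean normalized
expression in a reference cohort. All tie-breaks are deterministic: higher
objective, then shorter list/total, then lexicographic order.

## Differential expression

Per endogenous gene, raw counts follow `NB(d_j * exp(b0 + b1 x_j) +
lambda_j, phi_g)` with `d_j = 1/(pos_j * hk_j)` from the normalization
factors and `lambda_j` the lane's negative-control mean — the background
enters the mean additively because subtracting it can produce negative
means. Dispersion is estimated per gene (no trend shrinkage: the panel is
hundreds of genes, not genome-wide) by a one-step Cox–Reid adjusted profile
likelihood, evaluated at the full-model ML coefficients and maximized by
golden-section search on log phi in [1e-8, 10]; the adjustment matters
because plain ML dispersion is biased low at panel-scale lane counts and
makes the test anti-conservative. The test of `b1 = 0` is a likelihood
ratio at fixed dispersion, referred to an F(1, N−2) distribution (N = lanes
in the contrast) in the quasi-likelihood style, which accounts for the
estimated dispersion where a chi-square(1) reference does not; simulation at
the study conditions puts the null rejection rate at 0.05 within Monte Carlo
error. Genes never rising above the lane background are flagged
`below_background` with p = 1; optimizer aborts are resolved by a
derivative-free polish and flagged `non_convergent` (p = 1) only if a real
improvement was found missing — never a silent NaN. BH adjustment is step-up
with an explicit total test count m (default: number of endogenous genes),
so a subset of p-values can be adjusted against the full panel.

## Enrichment

Right-tailed Fisher exact test: `p = P(X >= k)` for hypergeometric X, via
scipy's log-space survival function, validated against exact rational
enumeration. The reference universe defaults to the panel's endogenous
genes, which corrects for the sampling bias of a targeted panel; gene sets
are intersected with the universe before sizing. Rows with p below alpha
(default 0.05) are reported sorted by p; overlap percentages are rounded to
one decimal in reports.

## Survival and group statistics

Median split assigns the odd-n median sample to the side whose nearest
member value is numerically closer (ties to "low"); even n splits the sorted
halves. The log-rank test accumulates the standard hypergeometric O/E/V per
distinct event time; the hazard ratio is the score estimator
`exp((O1-E1)/V)` with CI `exp(±1.96/sqrt(V))` (a Pike-style
`(O1/E1)/(O2/E2)` estimator is available behind a switch for sensitivity; a
group with zero events yields a flagged one-sided bound rather than a
crash). ANOVA is the standard one-way F with Tukey–Kramer studentized-range
post hoc comparisons (scipy), the t-test is pooled-variance two-sided, and
cohort summaries report per-level counts with percents to one decimal and
median/min/max for continuous fields (midpoint median for even n).

## Problem sizes in tests and the acceptance script

Recovery and calibration suites run at: activity recovery — 100 cohorts of
n = 50 with a 30-gene signature at dispersion 0.05; DE null calibration —
200 panels of 336 genes at dispersion 0.1 with 8 + 8 lanes; planted
fold-change recovery — 100 experiments with a 4-fold gene at mean 500,
dispersion 0.01, 10 + 10 lanes; budget optimizer — exhaustive comparison on
6 pathways × 4 grid points; survival calibration — 1,000 cohorts of n = 40
under zero hazard effect. These sizes give Monte Carlo standard errors
comfortably inside the asserted bands.

## Known limitations

- The activity scorer is not numerically equivalent to any published
  Bayesian factor-model implementation; only interface and qualitative
  behavior correspond.
- Dispersion is per-gene with no empirical-Bayes shrinkage across genes;
  at fewer than ~3 lanes per arm the F-reference calibration degrades.
- One two-level contrast (plus a one-vs-rest wrapper); no multi-factor
  designs, no Cox regression, no competing risks.
- GMT gene sets are taken at face value; no identifier mapping is attempted,
  so symbol mismatches silently shrink overlaps.
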