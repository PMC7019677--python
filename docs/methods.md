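# Methods

This note documents the statistical procedures `salivadx` implements, the
assumptions behind them, the choices made where the underlying study design
left details open, and what the synthetic-data results do and do not say
about real cohorts.

## Relative quantification (2^−ΔΔCt)

Replicate Ct values are combined by arithmetic mean on the cycle scale
(not by averaging 2^−Ct), with undetermined (NA) wells dropped; a
(sample, gene) cell whose replicates are all NA is missing, and downstream
analyses are complete-case per gene. ΔCt = mean Ct of the target minus mean
Ct of the reference gene (GAPDH by default) within the same sample; a sample
without a usable reference measurement is excluded and reported.
Amplification efficiency is fixed at 2 — one cycle equals one doubling — so
relative expression is 2^−(ΔCt − ΔCt_calibrator). No efficiency correction
or fluorescence-curve processing is attempted.

The calibrator is explicit configuration because the quantity "relative to
what" is otherwise ambiguous:

- `control-mean` (default): per gene, the mean ΔCt of the control group, so
  control-group mean expression is ≈ 1 and case values read directly as
  fractions of the control level;
- `sample:<id>`: a named reference sample;
- `none`: report 2^−ΔCt.

Group fold changes are invariant to this choice (the calibrator cancels in
the ratio), which the tests assert. Ct values outside a plausible window
(default 5–45 cycles) are flagged in the log but kept: truncating them
would bias ΔCt.

## Group summaries and the mean−SD call rule

Per gene: group means and sample SDs (n−1 denominator, the convention of
standard statistical software), fold change = case mean / control mean, and
a two-sided Wilcoxon rank-sum test — exact enumeration when the combined
sample is ≤ 12 without ties, otherwise the normal approximation with tie
and continuity corrections. The Shapiro–Wilk test is available for
reporting, but the group comparison is always the rank-sum test: salivary
relative-expression values are positive and right-skewed, and normality
cannot be assumed at these sample sizes.

The diagnostic cut-off for each gene is the control mean minus one control
SD. A sample strictly below the cut-off is called *low level* (cancer-like);
a value exactly at the cut-off is *high* — the boundary is read strictly,
and ties at the boundary are measure-zero for continuous data. If control
values were Gaussian, the rule's specificity would converge to
Φ(1) ≈ 0.8413 as the control sample grows; a Monte-Carlo test checks this
at n = 100,000 within ±0.02. Reported tables round means, SDs, fold changes
and cut-offs to two decimals; all internal computation is at full
precision. Published tables of this kind occasionally disagree with their
own rounded inputs by 0.01 in a cell (e.g. a cut-off of 4.01 − 1.20 printed
as 2.80, or a fold change 0.70/4.01 printed as 0.18); this pipeline always
computes from unrounded values and does not reproduce such artefacts.

Cohort-balance 2×2 tables use Pearson's χ² without continuity correction
(df = 1); the uncorrected statistic is what reproduces the typical printed
baseline p-values, and a Yates-corrected variant is a flag away. Raw
p-values are reported without multiplicity adjustment, matching the
single-cohort screening setting; a Benjamini–Hochberg column is available
behind `summarize_genes(adjust=True)`.

## ROC analysis

Scores carry an explicit direction; for these markers, *lower* expression
indicates disease, and AUCs are reported on that orientation (so an
informative marker has AUC > 0.5). The empirical ROC has one point per
distinct score value with ties grouped; the AUC is the trapezoidal area,
which is algebraically the Mann–Whitney probability with half credit for
ties. A randomized property test checks exact agreement with an O(n²)
pairwise-count oracle, ties included.

Operating points maximise Youden's J = sensitivity + specificity − 1, with
ties broken toward higher sensitivity and then the lower threshold.
Reported thresholds are midpoints between adjacent distinct scores (±∞
sentinels at the extremes), so the reported decision rule reproduces the
reported sensitivity/specificity exactly. Note that published
single-number sensitivity/specificity pairs for a marker do not always come
from the Youden point and the selection rule is frequently unstated; the
Youden convention here is a documented choice, not a claim about how any
particular published pair was chosen.

95% CIs for the AUC use a class-stratified percentile bootstrap, B = 2000
by default, seeded and vectorised (resampled AUCs are computed by midranks
row-wise, so B = 2000 at n ≈ 67 costs milliseconds). Stratification
guarantees both classes survive every resample. Coverage is checked by
simulation: under a binormal model with true AUC 0.8 at group sizes 34/33,
the interval covers the truth in ≈ 93–94% of replicates — slight
undercoverage is expected for percentile intervals of a bounded statistic
at this n. DeLong intervals (`method="delong"`) are provided for
comparison.

## Logistic risk scores and the greedy combination

A panel is a maximum-likelihood logistic regression of case status on its
markers (intercept included, no regularisation by default — appropriate for
≤ 6 predictors at n ≈ 67). Fitting is Newton–Raphson with convergence at
relative log-likelihood change < 1e−8 or 100 iterations. Under complete or
quasi-complete separation the coefficients diverge; the fit is flagged
(`separation=True`) and the final-iterate coefficients retained, because
the risk score's *ranking* of samples — all that ROC analysis uses — is
already determined. An optional ridge penalty and an optional log2 input
transform exist for sensitivity analysis; expression enters untransformed
by default.

The greedy combination: (1) rank candidates by univariate empirical AUC,
descending, with ties broken by larger absolute standardized mean
difference and then gene name; (2) fit the top two as a panel; (3) add the
next-ranked candidate and refit all coefficients jointly; (4) repeat until
all candidates are included, keeping every intermediate panel. Joint
refitting is the default reading of "combine with the next marker"; a
`frozen` strategy (previous risk score kept as a single composite
covariate) is available since combination recipes in the literature differ.
The path is invariant to the order candidates are supplied in, and a test
matches it step by step against an independent re-implementation built on
a different optimizer.

Panels are evaluated in-sample (apparent AUC), which mirrors the original
analysis and is optimistic at n ≈ 67;
`cross_validated_auc` quantifies that optimism but is deliberately not part
of the headline tables.

## Age stratification

The cohort is split at 60 years: *under-60* is age < 60, the 60-plus
stratum takes age ≥ 60 (the boundary goes to the older stratum so the
partition is total). Within each stratum everything is recomputed from that
stratum's own samples — in particular the mean−SD cut-offs come from the
stratum's controls, which is why stratum cut-offs differ from the overall
ones. A stratum lacking two samples in either class is skipped with a
warning rather than failing the run.

## The synthetic cohort generator

The generator emulates the data structure behind a two-group salivary qPCR
study: per-gene group means/SDs on the relative-expression scale, group
sizes 34/33, ages from per-group truncated normals (control 53.2 ± 17.4 on
[25, 83]; case 61.2 ± 18.1 on [24, 97]), and independent Bernoulli
covariates (sex, smoking, alcohol, mild periodontitis) at the published
group rates. Expression is drawn from a log-normal with parameters solved
from the target mean m and SD s (σ² = ln(1 + s²/m²), μ = ln m − σ²/2):
positive, right-skewed, and consistent with the non-normality reported for
such data. The log-normal is a stand-in — the true per-subject
distributions are unknown — and a zero-truncated normal variant
(`distribution="truncated_normal"`) is provided for sensitivity checks
(its realised moments shift slightly when m/s is small). An optional
per-gene age slope (expression units per year, default 0, centred at the
group age mean) lets stratification tests induce known age structure;
additive tilting is floored at 10⁻⁶ to preserve positivity.

Seeding: one master seed; each (gene, group), the age stream and each
covariate stream get independent substreams keyed by CRC32 of their names,
so adding a gene never perturbs existing genes' draws and identical
(config, seed) is bitwise-reproducible.

The plate simulator inverts quantification for round-trip testing: target
Ct = reference Ct + calibrator ΔCt − log2(expression), with optional
per-sample loading shifts and iid normal replicate noise on the cycle
scale. At zero noise, quantification with calibrator `none` recovers the
expression matrix to numerical precision (tested at 1e−9); replicate noise
of SD σ inflates mean recovered expression by exp((σ ln 2)²/3) for
triplicates, which the tests verify rather than ignore.

**What passing tests do not show.** The published group dispersions, taken
at face value as SDs, imply standardized group separations of ~2–3 per
gene, so synthetic univariate AUCs at n = 34/33 sit at or near 1.0 —
whereas studies of this design report univariate AUCs of 0.63–0.70.
Dispersions of that magnitude are more consistent with standard errors of
the mean than with SDs, but the generator deliberately encodes the printed
values as given rather than reinterpreting them. Consequently the synthetic
cohort validates the *machinery* (quantification, summaries, calls, ROC,
panels, stratification) and the printed-table arithmetic, not the
discriminative performance one should expect on real saliva samples, where
group overlap is far larger. Panel fits on the default cohort routinely hit
perfect separation; this is expected and handled, not a defect.

## Problem sizes and numerical choices

Monte-Carlo checks use: n = 10,000 per group for generator moment matching
(means within 2%, SDs within 5%); 1,000 random instances, n ≤ 50 with
ties, for AUC-oracle agreement; all group-size splits with combined n ≤ 8
for exact rank-sum enumeration; n = 5,000 for logistic coefficient recovery
(within 10%); 500 replicate cohorts × B = 2000 bootstrap for CI coverage;
n = 100,000 for call-rule specificity. These sizes put Monte-Carlo error
comfortably inside the stated tolerances while keeping the whole suite
fast. Degenerate inputs have defined behaviour throughout: all-tied
rank-sum input returns p = 1 with a warning; single-class ROC input is an
error; constant markers are rejected before fitting; empty strata are
skipped with warnings.

## Known limitations

- The log-normal expression model is an assumption, not an inference; only
  the first two moments are calibrated.
- No PCR efficiency correction, RNA-yield modelling, or saliva degradation
  effects.
- Covariates are independent of expression by default (the design found no
  significant covariate effects); confounded scenarios must be constructed
  manually via the age-effect hook.
- In-sample panel AUCs are optimistic; use `cross_validated_auc` before
  taking any panel's discrimination at face value.
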