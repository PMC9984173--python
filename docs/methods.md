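# Methods

This note records the models, assumptions and numerical choices behind
`crisiscast`, and what the synthetic experiments do and do not show.

## The forecasting problem

The target is the IPC phase `y_{d,t} ∈ {1..5}` of district `d` for the
reporting period ending in month `t`. Reporting is quarterly (January,
April, July, October) before a regime-switch month (default 2016-01) and
three times a year (February, June, October) after it. All "previous
period" logic is period-indexed, so lags remain well defined across the
schedule change, where consecutive period ends are four months apart.
Forecasts must use only information at least one quarter old: every
monthly regressor for a target `t` is dated `t−3` or earlier (for a
horizon `h > 3`, `t−h` or earlier), and the phase lags are the six most
recent periods ending at or before `t−h`.

## Synthetic world

The generator emulates the data-generating assumptions of the analysis,
not any real geography.

**Latent risk.** Five components (conflict, price, weather, pest,
displacement) follow independent AR(1) processes per district,
`z_{k,d,t} = ρ z_{k,d,t−1} + ε`, with ρ = 0.8 and unit innovation
variance split between district, province and country shocks in weight
proportions (0.75, 0.47, 0.47). The shared shocks create the spatial
correlation that the province/country aggregation terms of the design
exploit.

**Phases.** The reported phase is an ordinal cut of the component-mean,
window-mean latent risk, with each component delayed by its `lead_tau`
(defaults: conflict 3, price 2, weather 4, pest 4, displacement 3
months). Cutpoints (0.3, 0.9, 1.5, 2.1) give a realistic long-run phase
distribution (roughly 60/25/10/4/1% from phase 1 to 5) with multi-period
episodes.

**News.** Article counts per district-month are Poisson with a mean-one
log-normal coverage bias (σ = 0.5); by default coverage is independent of
risk — the joint distribution of press attention and food insecurity is
unknown, so coupling is off unless `coverage_risk_coupling` is set. An
article mentions a planted cause feature of component `k` with
probability `0.02 + 0.6·logistic((z_{k} − 0.8))` evaluated at the
article's month; because the phase reacts to `z` only `lead_tau` months
later, news mentions lead crisis onsets by construction (the empirical
mention–phase cross-correlation peaks at a 4–6-month lead for the
weather component). Near-synonyms are mentioned at 0.4 of the same rate
but never appear in frames, so only keyword expansion can recover them;
noise features are mentioned at a constant 5% rate. A fraction
(`frame_prob` = 0.3) of cause mentions emits a semantic frame (cause
constituent containing the feature, effect constituent containing a seed
phrase, causal trigger), alongside low-rate distractor frames that each
violate exactly one filter step.

**Traditional factors.** Nine time-varying factors are monotone
transforms of one latent component observed through Gaussian measurement
noise of 1.0 latent standard deviations and reported 3 months late, plus
five time-invariant district attributes. The delay and noise encode the
premise under test — traditional indicators are outdated and incomplete
relative to the news — and they are what gives the combined model its
measurable advantage in the replicate experiments. With the delay at 0
and noise near 0, traditional factors observe the risk as well as the
news does and the advantage disappears; passing superiority tests
therefore demonstrate internal consistency of the pipeline under the
stated premise, not evidence about any real data.

## Lexicon

Word mover's distance is the exact optimal-transport cost between the
uniform bag-of-words distributions of two token lists under the
Euclidean ground metric, solved as a linear program (documents here are
n-grams and short constituents, so exact solves are microseconds). An
n-gram is a document of its tokens: phrases compare via transport, not
averaged vectors. Out-of-vocabulary tokens are dropped before transport;
a fully out-of-vocabulary document has undefined distance and can never
be selected. Seed matching inside effect constituents is case-insensitive
contiguous-token matching. Step 4 of the frame filter emits *all*
contiguous 1–3-grams of the surviving cause/effect constituents —
including function words; downstream screening is what prunes them. The
candidate pool for keyword expansion is every corpus unigram plus
bigrams/trigrams occurring strictly more than `min_count` times;
`min_count` defaults to 1000 in the CLI (sized for a multimillion-article
corpus) and is set around 20–100 in synthetic runs. The scholarly
literature path is the same frame-filter operation applied to a second
frame stream with a different `origin` tag.

## Granger screen

Screening estimates the pooled panel ADL of the phase on its own period
lags and the factor's monthly lags starting at `t−3`, with a single
intercept and no district fixed effects. All (p, q) candidates are fit
on the common sample implied by the largest orders so AICs are
comparable; `p ∈ {1..4}`, `q ∈ {1..6}` by default. The retention test is
the standard nested F-test of all `b` coefficients jointly zero at the
1% level; no multiple-testing correction is applied across features
(deliberately — the screen is a filter, not an inference). A variant
screen (`drop_insignificant_lags`) first removes factor lags whose
individual |t| < 1.96 and then tests the survivors jointly; the default
is the plain nested test of all factor lags. Features are
differenced to stationarity first: the ADF test uses a constant, no
trend, lag order by AIC up to 12 (capped by series length), at the 5%
level, with at most 2 differences. The per-feature difference order is
the rounded-up median of per-district minimal orders, computed on the
training window only (optionally on a district subsample for speed); the
differenced series is what enters both screening and forecasting.
Screening uses only data up to the end of the first cross-validation
fold's validation window, which precedes every test window.

Calibration: on pure-noise features the screen retains about 1–2% at the
1% level (the acceptance suite checks the [0.3%, 2.5%] envelope over
1000 null features). AIC order selection never drops a true lag at high
signal-to-noise but overselects with the classic ~16% probability per
extra-lag direction (ΔAIC = 2 corresponds to P(χ²₁ > 2) ≈ 0.157), so
exact-order recovery plateaus near 70%, not above 90%; the suite asserts
both the no-underselection property and, separately, the stricter
exact-recovery figure.

## Forecasting

The design has one row per (district, period): 6 phase lags; 5 static
attributes plus 9 traditional factors × 3 levels × 6 monthly lags (167
columns) for the traditional block; and |w| × 3 × 6 columns for the news
block. Province/country traditional values are unweighted means over
member districts; province/country news factors use the mention counting
rule directly (an article mentions a unit if it mentions any of its
districts). Zero-coverage months yield factor value 0 with a coverage
flag rather than missing values, keeping lag matrices complete.

Cross-validation is rolling-origin: disjoint ordered test windows
partition the post-burn-in periods (burn-in 8 periods, validation 2
periods by default); training is everything before the validation
window. Hyperparameters minimize validation RMSE per fold; the model is
refit on training+validation before predicting the test window. The full
printed grid (10 × 7 × 3 × 5 combinations) is available as `PAPER_GRID`;
the default desk-scale grid searches 4 combinations (40 trees, split
thresholds {2, 5}, √p feature sampling, impurity decrease {1e−4, 1e−3}).
`min_samples_split` values ≤ 1 are interpreted as sample fractions and
`max_features="auto"` as all features (its historical regression
meaning). The reported RMSE is the unweighted mean of per-fold test
RMSEs; pooled errors feed the Diebold–Mariano machinery. RMSE is
computed on the raw 1–5 ordinal scale, so absolute levels are not
comparable to results computed on other scales; all headline synthetic
claims are ratios or paired comparisons, which are scale-invariant.
Model comparisons intersect the two designs' (district, period) rows
first so both models see identical observations. Expert forecasts, when
provided, enter as one extra regressor column.

## Outbreak evaluation

Outbreak onset: phase ≥3 at `t` and `t+1` with phase ≤2 at `t−1`;
series-initial and -final periods can never be onsets. The episode lasts
while the phase stays ≥3; severity means the episode reaches phase 4+.
The dual-threshold classifier applies the analogous rule to predictions,
reading "±3 months" as the adjacent reporting period so it survives the
schedule change; the prior-period condition uses the *predicted*
`ŷ_{t−1}` (an observed-y variant is a flag). The sweep varies `l` and
`u` over [1, 5] with `l ≤ u`; the upper threshold starts one step above
the scale floor, since a predicted phase at the floor carries no
outbreak signal. Grid points with zero predicted positives are skipped.
The Pareto front is the non-dominated subset of (precision, recall)
points; AUC is the trapezoidal area under the front anchored at
(recall 0, precision of the lowest-recall front point), with no credit
beyond the maximum achieved recall, and is computed on the raw front —
smoothing a PR front can create infeasible operating points, so any
smoothing is display-only. The default sweep step is 0.01 (the printed
0.001 over the (l, u) simplex is ~8M evaluations; available by passing
`step=0.001`), and on finite fixtures the front is step-insensitive once
all confusion matrices are resolved.

The Diebold–Mariano statistic divides the mean squared-error loss
differential by a long-run standard error with truncated autocovariance
sum (truncation lag ⌊n^{1/3}⌋ + 1), two-sided normal p-values. The same
correction yields the single-model RMSE interval: mean squared error
± 1.96 standard errors, reported on both the squared and root scales
(the bracketed autocovariance sum divided by n is a variance; its square
root is the standard error used). A negative truncated variance estimate
is clamped to zero and flagged.

## Problem sizes

Unit tests run on worlds of 8–24 districts and 4–10 years. Replicate
experiments (`trial_config`) use 48 districts, 10 years, ~40 articles
per district-month, 8 folds — about half a minute per replicate — and
the acceptance script runs one such replicate plus a 200-feature null
calibration. The full default scenario (189 districts, 11 years) runs
the same code unchanged, only slower.

## Known limitations

- Articles carry explicit district-mention lists; free-text gazetteer
  matching is out of scope.
- The synthetic world has no seasonality, no missing assessments, no
  coverage collapse (censorship is only a static bias multiplier), and
  phase transitions are driven by a single latent family — real
  assessment data are rougher in every respect.
- Pooled OLS screening has a single intercept; district heterogeneity in
  baseline phases is absorbed by the phase lags, not modeled.
- Random forests are not monotone in feature sets, so ablations are
  evaluated empirically, never assumed.
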