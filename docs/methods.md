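# Methods

## Kinetic model

Transcript abundance is assumed stationary over the labeling window:
synthesis balances first-order decay, so a transcript with decay rate
δ = ln2/t½ partitions after *t* minutes of 4-thiouracil exposure into a
pre-existing fraction P/T = e^(−δt) and a newly synthesized fraction
N/T = 1 − e^(−δt) of its total pool. The three ratio estimators

* np: t½ = t·ln2 / ln(1 + N/P)
* nt: t½ = −t·ln2 / ln(1 − N/T)
* pt: t½ = −t·ln2 / ln(P/T)

are the same identity rearranged; they differ only in which measured
ratio enters, and therefore in their noise behavior. The np form is the
default: it combines the broad dynamic range of nt with the
short-half-life precision of pt. Defaults throughout are the study
settings: t = 120 min, detection p ≤ 1e-4 on every array, caps at
floor = 1 min and ceiling = 8640 min (6 days), six replicates per
fraction. Estimates outside the caps are clamped and flagged; an nt
ratio ≥ 1 means decay faster than resolvable (floor), a pt ratio ≥ 1
means no resolvable decay (ceiling).

Numerical domain: at t = 120 min a half-life of 3 min leaves a
pre-existing fraction of ~1e-12. Below P/T ≈ 1e-8 the complement
1 − N/T is no longer resolvable in double precision, so nt-based
estimates saturate at the floor for half-lives under ~4.5 min. This
mirrors the physics — no assay resolves a 1e-12 remnant — and is why
estimator-agreement checks constrain the nt form to its representable
domain while np and pt are compared over the full grid.

## Regression normalization and probe quality

Template amounts differ between pools, so each fraction carries an
unknown scale factor. Since N + P = T, the raw ratios n = new/total and
p = pre/total lie on a line p = α + βn with β < 0; the scale factors
follow as c_n = −β/α and c_p = 1/α, making c_n·n + c_p·p = 1 on the
line. A fit with β ≥ 0 or α ≤ 0 is diagnosed as "fractions not
complementary" rather than silently normalized.

Both coordinates are measured ratios, and they share the total-fraction
denominator. Their errors are therefore (a) multiplicative — SD roughly
proportional to the measured value — and (b) positively correlated, with
correlation 1/2 when the three pools carry equal log-noise. Ordinary
least squares is inconsistent under error in the regressor (the shared
denominator roughly halves the fitted slope at array noise SD 0.2), so
the default fit is York's errors-in-variables solution with per-point
error SDs proportional to the measured values and correlation 1/2; the
common noise scale cancels from the weights. The fit reduces to least
squares as regressor noise vanishes and agrees with OLS exactly on
noiseless data; `method="ols"` selects plain least squares of p on n.
The regression is done on the linear (not log) scale, matching the
additive pool constraint.

The probe quality score of a feature is its perpendicular distance from
the fitted line divided by k·σ_d, where σ_d is the SD of the signed
perpendicular distances of all features and k = 3 by default — so
"PQS > 1" is a 3-SD cut, which removes ≈0.3% of features under Gaussian
ratio noise (the filter's observed behavior on the real series was 16 of
7102, ≈0.23%). Fit, scoring and filtering are repeated (default
max_iter = 2, i.e. one repeat); the fit of the last executed round
defines the normalized ratios, so every kept feature has PQS ≤ 1 under
the reported fit. Distances within 1e-12 of the line count as zero so
that exactly collinear data is never filtered by float rounding.
Features with non-positive normalized ratios are dropped with a logged
reason. Replicates are pooled per fraction by the median of per-array
intensities before ratio formation (mean and geometric mean are
selectable); pooling before ratio formation keeps the total-fraction
denominator common to both ratios, which is exactly the correlation the
EIV fit models.

## Enrichment

Features are binned by half-life ([lower, upper), lower edge included;
default summary edges 6 h, 12 h, 24 h, 48 h, 72 h, 144 h). Each term is
tested for over-representation in the bin against all arrayed features
with a one-sided hypergeometric (Fisher) test — published enrichment for
this design reports over-enriched categories only; a two-sided variant
is available behind a flag. FDR control is Benjamini–Hochberg. Terms are
tested exactly as annotated: no GO-graph ancestor propagation (slim
mappings are an upstream input).

## Differential de novo transcription

The original analysis used a proprietary composite-array error model;
this package substitutes a declared one. Per-replicate intensity
variance is σ_add² + (ε·x)² (defaults σ_add = 10 intensity units,
ε = 0.1), the composite mean is the inverse-variance-weighted mean, and
the composite variance is the larger of the model variance of that mean
and the empirical variance of the mean — replicate scatter can widen
but never shrink the error. Between conditions, L = ln(b/a) with
var(L) = se_a²/a² + se_b²/b² (delta method) gives a two-sided normal
p-value; fold changes use the signed convention (magnitude ≥ 1,
negative = decreased), and a feature is significant at |fold| ≥ 1.7 and
raw p ≤ 1e-4 — no multiplicity correction, matching the analysis this
replaces. Consequence of the substitution: published per-feature
p-values and fold changes are not reproduction targets; the published
tables' direction counts are instead carried as packaged input data.

## qPCR decay fitting

Relative expression is efficiency^−(Ct_treated − Ct_control) with
per-primer efficiency in (1, 2]. Because expression is measured relative
to time-matched carrier controls, it is 1 at t = 0 by construction, so
ln(expression) is fitted through the origin; δ = −Σt·ln y / Σt² and
t½ = ln2/δ. A non-positive fitted rate is reported as "no detectable
decay" (tubulin/PCNA-like behavior) rather than a negative half-life.
Undetected points (no amplification after 40 cycles) are censored and
excluded with a log entry — conservative relative to imputing the
detection limit. A free-intercept variant is provided for curves with an
amplitude offset.

## Synthetic data: what it does and does not emulate

The generator draws true half-lives log-normally, parameterized by
median (default 1998 min = 33.3 h) and log-SD (default 1.0) — the
simplest heavy-tailed positive law consistent with a right-skewed
distribution summarized only by median/mean/range. Steady-state
abundances are an independent log-normal (median 1e5 intensity units,
log-SD 0.5, arbitrary scale). Pools are mixed through an imperfect
bead-separation model — capture efficiency 0.95, carryover of unlabeled
RNA into the new pool 0.01, labeled leakage into the pre pool 0.02;
carryover contaminates without depleting, since pool amounts are
relative — then scaled by hidden per-fraction factors (total 1.0,
pre 1.3, new 0.25, emulating unequal template amounts; values arbitrary
and recorded in the truth sidecar). Noise is per-array log-normal
(default SD 0.2) plus an additive background; detection p-values are a
monotone stand-in, p = clip(background/intensity, 1e-6, 1), chosen so
only pass/fail behavior at the threshold matters. Every simulator takes
an explicit seed and derives its generator from a per-simulator stream
id plus that seed, so reusing one seed across simulators never replays
the same random stream.

Fraction purity is not reported for the real experiment, so the
contamination defaults are guesses and configurable. Carryover biases
stable transcripts short (a 1% unlabeled carryover roughly doubles the
apparent new fraction of a 33-h transcript) and no normalization can
remove it; recovery guarantees (noiseless exactness; noisy median
within 10%) are therefore stated for contamination-free separation.
The simulation does not model probe sequences, hybridization physics,
spatial array artifacts, or circadian departure from steady state —
passing tests show the estimator and normalization behave correctly
under the stated statistical model, not that a real labeling experiment
satisfies that model.

## Problem sizes and numerical choices

Tests and the acceptance checks run at the study's own scale where the
claim depends on it (7086 features × 18 arrays for parameter recovery,
10,000 features for filter calibration and type-I checks) and at small
fixture scale elsewhere; the whole suite completes in seconds on one
core. Removal-rate calibration places Gaussian noise on the response
ratio (pre/total), the well-posed regime for a residual-based filter;
recovery under full multiplicative array noise is tested separately.
York iteration stops at a relative slope change of 1e-12 (≤50
iterations). Ties in rank correlations are mid-ranked; concordance is
computed on capped values, as a published half-life table would contain.
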