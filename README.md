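# thiolife

Global mRNA half-life analysis from 4-thiouracil (4tU) metabolic-labeling
microarrays, written for transcriptome studies in which most regulation is
post-transcriptional — the motivating system is the dinoflagellate
*Karenia brevis*, whose transcripts turn over unusually slowly.

## The measurement and the model

Cultures are exposed to 4tU for a labeling window *t*. Thiolated (newly
synthesized) RNA is biotinylated and bead-separated, splitting every
transcript population into three pools that are hybridized separately:
**total** (T), **pre-existing** (P) and **newly synthesized** (N). Under
steady state, synthesis balances first-order decay with rate
δ = ln2 / t<sub>½</sub>, so after labeling for *t* minutes

```
P/T = e^(-δt),   N/T = 1 − e^(-δt),   N/P = e^(δt) − 1
```

and the half-life follows from any one ratio:

```
t½ = t·ln2 / ln(1 + N/P) = −t·ln2 / ln(1 − N/T) = −t·ln2 / ln(P/T)
```

Because the template amounts of the three pools differ, per-array
intensities are not comparable across fractions. The pipeline exploits the
constraint N + P = T: the raw ratios n = new/total and p = pre/total of all
features must fall on one straight line with negative slope, p = α + βn.
Fitting that line yields the unknown per-fraction scale factors
c<sub>n</sub> = −β/α and c<sub>p</sub> = 1/α such that
c<sub>n</sub>·n + c<sub>p</sub>·p = 1, a **probe quality score**
(PQS = perpendicular distance from the line in units of k·σ<sub>d</sub>)
flags unreliable probes, and features with PQS > 1 are removed before the
fit is repeated. Estimates are clamped to a configurable range (defaults
1–8640 min) with explicit cap flags; the newly-synthesized/pre-existing
(np) ratio is the primary estimator.

Around the core estimator the package provides:

* `thiolife.synthetic` — ground-truthed simulation of the whole design
  (log-normal half-lives, imperfect bead separation, hidden per-fraction
  scale factors, log-normal array noise, detection p-values, GO-like
  annotations with stability-class enrichment, two-condition response
  designs, qPCR time courses);
* `thiolife.normalization` — detection filtering (p ≤ 1e-4 on every
  array), replicate pooling, ratio regression (errors-in-variables or
  plain OLS), PQS computation and iterative outlier removal;
* `thiolife.halflife` — the three closed-form estimators with capping,
  distribution summaries, Spearman concordance between estimators;
* `thiolife.enrichment` — Fisher's exact over-representation of GO terms
  in a half-life bin against the arrayed background, with
  Benjamini–Hochberg FDR;
* `thiolife.diff_transcription` — composite replicate pooling under an
  additive+multiplicative intensity error model and a delta-method
  log-ratio z-test for condition-dependent de novo transcription
  (≥1.7-fold, p ≤ 1e-4 convention), plus the published nitrate-response
  fold-change tables as packaged inputs;
* `thiolife.qpcr` — efficiency-corrected ΔCt relative expression and
  through-origin exponential decay fits for transcription-inhibition
  (actinomycin D) validation.

## Worked example

Simulate a six-replicate, three-fraction labeling experiment (2 h label,
2000 features, array noise SD 0.2) and run the full pipeline:

```sh
thiolife simulate halflife-design --n-features 2000 --noise-sd 0.2 \
    --seed 1 --out-prefix demo
thiolife run --intensities demo_intensities.tsv --arrays demo_arrays.tsv \
    --out-dir out
cat out/summary.txt
```

which prints

```
1995 detected; 1979 summarized; median 25.8 h; outputs in out
features summarized      : 1979
median half-life         : 1545.1 min (25.8 h)
mean half-life           : 1875.2 min (31.3 h)
range                    : 102.0 - 7901.2 min
features removed by PQS  : 16
```

Reading this: 1995 of 2000 simulated probes pass the detection filter on
all 18 arrays (the weakest newly-synthesized signals of stable,
low-abundance transcripts drop out), 16 probes fall more than 3
distance-SDs from the cross-fraction regression line and are filtered,
and half-lives are reported per feature in `out/halflives.tsv` from all
three ratio forms. The recovered median (25.8 h) sits below the simulated
true median (33.3 h) because the default simulation includes imperfect
bead separation — 1% of unlabeled RNA carried into the new pool inflates
the apparent synthesis of stable transcripts, an effect regression
normalization cannot remove; with contamination disabled the pipeline
recovers the noiseless truth exactly (see the test suite).

The other presets work the same way: `thiolife respond` compares
newly-synthesized pools between conditions, `thiolife enrich` tests GO
terms in a stability bin, and `thiolife qpcr-decay` fits decay curves
from Ct tables, e.g.

```
$ thiolife qpcr-decay --table q_qpcr.tsv --out qfit.tsv
gene: t1/2 = 6.96 h (r2=1.000)
```

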