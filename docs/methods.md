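# Methods

## The problem and the model

A menstrual cycle is ovulatory when a corpus luteum forms and secretes
progesterone (P4). In urine, the luteal phase is visible as a rise of P4
and, more strongly, of its inactivated metabolite pregnanediol-3-glucuronide
(PDG). Raw urinary concentrations depend on hydration, so every analysis in
this package works on the analyte-to-creatinine ratio (P4 in µmol/mol,
PDG in mmol/mol; corrected-value objects carry explicit unit tags because
the literature mixes nmol/mol, µmol/mmol and mmol/mol labels for the same
quantity, and a silent factor-1000 error is the main failure mode here).

Timing is anchored to the day of ovulation (day 0, as fixed externally by
ultrasound/LH monitoring — the package never infers it from hormones). The
follicular window is days −10..−3 and the luteal window +3..+10: eight days
each, disjoint, with the periovulatory days −2..+2 excluded from phase
contrasts.

## Classifiers and summary statistics

*Percent change* is defined multiplicatively throughout:
`100·later/earlier`, a ratio in percent, not a percent increase. This is the
only reading under which the conventional operating points make sense (a
rise threshold of 165% means "the later sample is more than 1.65× the
earlier one"); an unchanged pair scores 100% and can never exceed a
threshold ≥ 100%.

The per-cycle summary for daily sampling is the **median over all
(follicular × luteal) pairwise ratios**. Using all pairs rather than window
means makes the statistic insensitive to a single aberrant collection day;
on a noise-free cycle whose luteal plateau covers at least half of the
luteal window it equals exactly 100× the fold change.

All threshold comparisons are strict (`>`). Ties have probability zero for
continuous data but the convention must be deterministic; "exceeds"
reads as strict. Weekly series are compared over all ordered pairs
(8×7 = 56 per full series; n(n−1) when samples are missing), cycles are
called ovulatory by the PDG referent iff *any* weekly PDG value exceeds the
PDG threshold, and the weekly peak analysis takes the maximum of each
sliding 4-sample window (5 windows from 8 samples). Sliding rather than
disjoint windows was chosen because it uses every 4-consecutive-sample
subseries a clinician could have observed; disjoint blocking is a trivial
slice of the same output.

In 2×2 diagnostics any 0/0 rate (e.g. sensitivity when no referent-positive
observations exist) is reported as undefined-with-flag, never as 1.0: an
empty column carries no information about the rate.

## ROC machinery

ROC curves are empirical. Thresholds are placed at midpoints between
adjacent distinct scores (plus sentinels), tied scores collapse into one
step, and the AUC is the trapezoidal area — which then equals the
Mann–Whitney concordance probability `(concordant + ½·tied)/(n₊·n₋)`,
a property the tests verify against an independent U-statistic computation
on randomized instances with ties. Curve vertices are ordered
lexicographically by (FPR, TPR); the empirical curve is monotone in both
coordinates, so this reconstructs the path and keeps tie-induced diagonal
segments (and only those) in the integral.

Paired AUC comparison uses the DeLong–DeLong–Clarke-Pearson estimator:
placement values per positive and per negative, their empirical covariance
across the two score vectors, a z-test for the difference, and the same
variance yields a single curve's 95% CI. The literature this package serves
usually reports AUC-difference p-values without naming the method; DeLong
is the standard choice for paired empirical curves, and third-decimal
differences from other software are expected. Monte-Carlo calibration
(equal-AUC correlated binormal null, 500 replicates of 200 per class) keeps
the 5%-level rejection rate inside the binomial band, and CI coverage is
checked at ≈95% on binormal data.

Operating points are selected by Youden's J (sensitivity + specificity − 1),
ties broken toward higher specificity; the criterion is a convention — the
package treats published cutoffs (1.14 µmol/mol P4, 0.208 mmol/mol PDG,
165%/195% rises, weekly P4 1.67 µmol/mol) purely as configuration defaults,
whose printed unit labels are ambiguous in the source literature, and
derives fresh operating points from ROC on simulated data when asked.

## Method comparison and assay validation

Pearson correlation is computed on natural-log-transformed values (urinary
hormone data are right-skewed; r is log-base invariant). Bland–Altman
reports mean difference, ±1.96·SD limits of agreement and, because a
"trend toward greater discrepancy" should be a number rather than a visual
impression, the least-squares slope of difference on pairwise mean.
Passing–Bablok uses the classical procedure: all pairwise slopes, slopes of
exactly −1 excluded, offset K = #(slopes < −1), K-shifted median, intercept
as `median(y − b·x)`, CI by the rank-based normal approximation (no
bootstrap). Precision decomposes replicate variance by one-way
random-effects ANOVA (between-run component truncated at zero; harmonic-
mean group size for unbalanced designs). Freeze-thaw stability is percent
change from the count-0 index aliquots; cross-reactivity is
`100·(mean spiked − mean unspiked)/spike concentration`.

## The synthetic-data generator

The generator emulates the data the analyses assume, with ground truth:

* **Cycle structure** — length drawn from a discretized log-normal, median
  28 d, clipped to 25–38; ovulation day median 14, clipped to 12–20 and to
  ≤ length − 10 so both phase windows exist.
* **Hormone profile** — per-cycle log-normal follicular baselines
  (defaults: P4 0.58 µmol/mol, PDG 0.05 mmol/mol, geometric CV 35%
  between cycles) and a piecewise-linear luteal elevation: rise over days
  +1..+4, plateau +4..+9 at baseline × fold change (defaults 2.8× P4,
  4.27× PDG), fall to baseline by +13. A plateau-shaped rise matches what
  daily corrected series look like; the exact shape is a modelling choice.
  Anovulatory cycles force all fold changes to 1.
* **Noise** — multiplicative log-normal day-to-day variation (CV 30%) per
  analyte, and per-sample log-normal creatinine (median 10 mmol/L, CV 30%)
  independent of the analytes. Creatinine enters raw concentrations
  multiplicatively, so correction removes it exactly — which is the point
  of correcting. Creatinine distributions and within-woman autocorrelation
  are declared assumptions, not estimates; real series are autocorrelated
  day to day, and this generator's days are conditionally independent given
  the profile.
* **Platform error** — measured = true·(1+proportional)·matrix + constant
  + crossreactivity·PDG(nmol/L), times a mean-one log-normal with the
  combined within/between-run CV, times (1−loss)^freeze-thaws, clipped at 0.
  Three default platforms: a specific PDG ELISA (unbiased, ~8% CV), an
  accurate automated P4 assay (matrix 1.13, 0.59% PDG cross-reactivity,
  2.6% loss per freeze-thaw) and a matrix-affected P4 assay (matrix 1.20
  plus a constant 8 nmol/L bias at cycle-range concentrations). The
  constant bias inflates the follicular baseline and compresses the
  apparent luteal ratio — the mechanism by which a matrix-affected platform
  loses discrimination. A real matrix effect is concentration-dependent:
  at spike-range concentrations (tens of nmol/L) the biased platform
  over-recovers ≈1.7×, and `dilution_series_models` shrinks the
  over-recovery as `1 + (m−1)·d^(−0.25)` with dilution factor d, so
  simulated spike-recovery falls with dilution while an accurate platform
  stays flat. No single affine error model reproduces every published
  summary of such a platform simultaneously; the defaults were calibrated
  once to the corrected-concentration ranges and the qualitative ordering
  and left alone.
* **Reproducibility** — each cycle's generator is seeded by
  `SeedSequence([master_seed, crc32(cycle_id)])`: byte-identical output
  under regeneration, stable when cohorts grow or reorder.

Passing tests on this generator shows the *analysis machinery* is correct
and the qualitative platform phenomena are reproduced; it does not validate
the biology (no pharmacokinetics, no estradiol/LH, no autocorrelation, no
real assay drift).

## Problem sizes and numerical choices

Simulation-backed checks use: 1000 random instances (n ≤ 50) for the
AUC-oracle equivalence; 100 random 15-point fixtures for Passing–Bablok
against a brute-force oracle; 500 null replicates at 200 per class for
DeLong calibration; n = 2000 for Bland–Altman coverage; 100 replicate
20-cycle cohorts for the platform-ordering rate; and the published
experiment designs for validation statistics (3 spiked/unspiked aliquots,
3 × 6 freeze-thaw aliquots, 7 donors × 4 dilutions). Noise-free parameter
recovery is asserted to relative 1e−9 (pure float round-off);
oracle equivalences to 1e−12.

## Known limitations

* Ovulation day is an input; nothing here detects the LH surge.
* Empirical ROC only — no binormal smoothing, no partial AUC.
* Passing–Bablok CI is the classical approximation; no bootstrap, no
  Deming or weighted variants.
* The weekly percent-rise confusion is per ordered pair, which
  double-counts information within a cycle relative to a per-cycle call;
  this mirrors the impartial all-pairs design rather than a clinical rule.
* For the percent-rise ROC in an all-ovulatory daily cohort the negative
  class is within-follicular (earlier→later) ratios, where no luteal rise
  exists by construction; other choices (e.g. anovulatory-cycle pairs) are
  possible when anovulatory cycles are simulated.
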