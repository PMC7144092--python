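# Methods

This note records the statistical models behind each pipeline stage, the
conventions and numerical choices the implementation commits to, what the
synthetic generators do and do not emulate, and known limitations.

## Statistical core

**Fisher's exact test.** Two-sided p-values use the probability-mass
convention: the sum of conditional hypergeometric probabilities, over all
2×2 tables with the observed margins, that do not exceed the observed
table's probability. All masses are exact integers (`math.comb` products),
so ties between table probabilities — common in symmetric tables — are
resolved exactly rather than through a floating-point tolerance. The sample
odds ratio is (a·d)/(b·c), `inf` when only the denominator vanishes, and
flagged undefined when both products are zero. The suite verifies the
implementation against an independent rational enumeration for **every**
table with N ≤ 40 and against scipy on random larger tables.

**Multiplicity.** Benjamini-Hochberg is the standard step-up with an
optional family size m larger than the number of supplied p-values;
Holm-Sidak is the step-down max-accumulation of 1−(1−p₍ⱼ₎)^(m−j+1). Both
return values in input order, clipped to [0, 1], and are monotone (property
tested). The screen's significance calls use the plain Bonferroni threshold
α/m because that is how the published table was gated.

**Rank tests.** Midranks are used everywhere and tie-correction terms are
always included. Mann-Whitney: exact enumeration of all C(n₁+n₂, n₁) rank
assignments when n₁+n₂ ≤ 12 (remains exact under ties; two-sided by
deviation of U from its mean), otherwise the normal approximation with tie
correction and a continuity correction (on by default, toggleable).
Kruskal-Wallis uses the chi-squared reference with k−1 df. Dunn's post hoc
compares mean ranks of each group against the control with the
tie-corrected pooled variance; the family correction defaults to Bonferroni
over the k−1 control comparisons (the common desktop-statistics default;
Šidák available). Which exact/approximate paths the original desktop
software took per test is not documented anywhere we could rely on, so
these defaults are explicit package choices.

**Mixed two-way repeated-measures ANOVA.** Genotype is the between factor,
the replicate group is the subject, the 5-s time bin is the within factor.
The classical univariate decomposition is used: the genotype F is tested
against subjects-within-genotype, time and interaction against the residual.
Unbalanced designs are rejected, never imputed. No sphericity correction is
applied by default; Greenhouse-Geisser df scaling is available
(`sphericity_correction="greenhouse-geisser"`, ε bounded to [1/(t−1), 1]).
Per-bin pairwise genotype contrasts are pooled-variance t tests on the
subject values with Holm-Sidak adjustment across all bins × pairs. The
implementation is verified against a brute-force sums-of-squares oracle and
against pingouin's mixed ANOVA.

## Countercurrent model

Each fly receives exactly five independent Bernoulli(p) climb
opportunities; its final tube is its number of successes, so
CI = Σ(Nᵢ·i)/(5·ΣNᵢ) is the MLE of p with 5·ΣNᵢ Bernoulli trials and
E[CI] = p. The 95% interval is Wilson. The alternative protocol reading in
which a fly stops being tested after its first failure is available as
`ClimbModel(sequential=True)` (final-tube distribution p^k(1−p)); optional
beta-distributed per-fly climb probabilities provide over-dispersion and
default off. Group comparisons compute one CI per replicate run and
delegate to Kruskal-Wallis/Dunn.

## Locomotion metric

Center occupancy is the fraction of analyzed frames with
(x−x_c)² + (y−y_c)² < r_in², strict inequality, so a frame exactly on the
circle counts as outside. `r_in` defaults to 0.743·R — the scale-free form;
an absolute `inner_radius` override exists for literal reproduction of
fixed-threshold analyses (the published inequality's absolute constant "13"
is not consistent with the stated 15-mm well if read as millimeters, which
is why the ratio is the default parameterization). Tracking dropouts are
simply absent frames: excluded from numerator and denominator alike, so the
metric is a fraction of observed time. The analysis window keeps frames in
[(total−keep)·fps, total·fps) — by default the last 5 min of a 10-min,
30 fps recording, i.e. 9 000 frames.

## Seizure and recovery

Seizure state is an instantaneous per-bin status (scored every 5 s over
2 min, 24 bins); remission is representable in data but the default
generator is onset-only. Incidence is computed within replicate groups and
summarized as mean ± SEM (SD/√groups) across them. Recovery times carry an
explicit right-censoring flag with a shared horizon; the median is taken
over the combined ordering with censored flies above every observed time
(reported as `inf` when the median position is censored), and the recovered
fraction at a horizon counts only uncensored times ≤ horizon. For the
Mann-Whitney comparison censored flies enter as ties at the larger horizon,
which is exactly their rank contribution under shared-horizon censoring.

## Penetrance tables

Printed tables give n and a 1-decimal percentage; counts are rebuilt as
round(n·pct/100), half away from zero — the rounding that regenerates the
printed percentages — with a validity flag from re-deriving the percentage.
Across the shipped screen table every cell round-trips except one (GstT3
thorax, printed 94.2% of 34 flies: no integer count yields 94.2; 32/34 gives
94.1, and the printed p-value 0.691 reproduces exactly with count 32, so we
treat the percentage as a printing slip and the flag marks it). One other
printed p-value (GstE13 wings, 0.480) re-computes as 0.479 — a rounding
discrepancy we report but do not chase. Fisher rows are oriented deficiency
first; the two-sided p is orientation invariant (tested). The control for
the screen is the no-deficiency row (44 flies), stated explicitly because
the published layout leaves it implicit.

## Differential expression

Counts are modeled as K_gj ~ NB(mean s_j·q_gc, dispersion α_g) with
Var = μ + αμ². Size factors are DESeq2-convention median-of-ratios: the
median over all-positive genes of count/geometric-mean; no rescaling to
geometric mean 1 is applied (after normalization the re-estimated factors
collapse to the geometric mean of the originals). Per-gene dispersion is
method-of-moments **per condition** — α̂_c = (v_c − m_c·mean(1/s))/m_c² —
pooled across the two conditions with df weights and floored at 1e-8;
estimating against per-condition means matters because pooling the raw
variances against a pooled mean inflates dispersion exactly for the
differentially expressed genes. The log2 fold change uses a pseudo-count of
ε = 0.5 normalized units (rows where a raw condition mean is zero are
flagged `lfc_uses_pseudocount`). The Wald statistic divides the log2FC by a
delta-method standard error and is referred to a **t distribution with
n_A+n_B−2 df**: at 4 vs 4 replicates the normal reference is visibly
anti-conservative (null type-I ≈ 0.09 at nominal 0.05 in our simulations,
with massive BH false-discovery inflation), while the t reference is
calibrated (≈ 0.047). Genes with zero counts everywhere are dropped.

This stage is deliberately a simplified reimplementation of the standard
count-based DE workflow: no dispersion shrinkage across genes, no
fold-change moderation, no independent filtering, and the GO stage is a
plain one-sided hypergeometric without transcript-length bias correction.
Consequences: single moderate effects (e.g. one 2-fold gene among 2000 at
4 vs 4) are estimated accurately but are only borderline after BH, and
published DE tables produced with shrinkage-based tools are not expected to
match numerically — notably, a published log2FC of −0.76 alongside
normalized means whose ratio is 0.50 implies fold-change moderation that
this stage intentionally does not emulate.

## Synthetic generators

All generators are deterministic given (seed, parameters) and default to
the assay designs the analyses assume: 3 replicate countercurrent runs of
20 flies with 5 trials; 10-min 30 fps trajectories; 3 seizure groups of 30
flies, 24 bins; log-normal recovery times (default median 60 s, log-SD 0.6,
600-s horizon); binomial penetrance records; 2000-gene NB matrices with 4
replicates per condition, dispersion 0.05, log-uniform means over
10–10 000, log-uniform size factors in [0.5, 2] normalized to geometric
mean 1, and one GstS1-like gene spiked at log2FC = −1 at baseline mean
5 000.

Trajectory dynamics are invented — the assay defines only the metric, not
fly motion. Wall-followers hold a radial distance ~N(0.9 R, 0.02 R) while
their angle random-walks (SD 0.12 rad/frame). The tremor walker is a
mean-reverting (discrete Ornstein-Uhlenbeck) Gaussian jitter about the
center with reflection at the wall; a pure reflected random walk would
equilibrate to the uniform distribution on the disc (occupancy 0.743² ≈
0.55) regardless of step size, so the center pull (rate 0.05/frame, step SD
0.10 R) is what gives the step-size-controlled stationary spread, ≈ 0.94
occupancy at the defaults. The two regimes are designed solely to separate
the metric's output; neither models fly biomechanics, thigmotaxis kinetics
or thermal physiology, so passing tests demonstrate the metric and test
behavior, not realism of locomotion. A streaming variant
(`simulate_center_occupancy`) computes occupancies without materializing
trajectories for the 200-cohort power studies; it is statistically, not
bit-for-bit, equivalent to windowing full trajectories.

Seizure onsets are Exponential(hazard); a fly is scored seizing at every
5-s assessment at or after onset, so final-bin incidence is
1 − e^(−120·hazard). Remission is off by default.

## Problem sizes and tolerances

The simulation studies run at: 1000 runs × 20 flies for climbing-index
unbiasedness (tolerance 3 Monte-Carlo SE); 200 cohorts of 20 + 20 flies for
the occupancy separation (≥ 95% of cohorts at p < 0.01); 200 simulations
for the repeated-measures power check at hazard ratio 3 (≥ 90% detection);
100 experiments of 2000 genes for DE recovery (spike mean within ±0.1,
size-factor max relative error within 2%, null FDR ≤ 0.07 at BH 0.05); 2000
replicates for null rejection-rate checks (bound α + 2 Monte-Carlo SE). The
Fisher oracle comparison is exhaustive over all 135 750 tables with N ≤ 40
at 1e-12 absolute tolerance.

## Known limitations

* The DE stage's power at small replication is intentionally below that of
  shrinkage-based tools (see above).
* The mixed ANOVA treats per-bin proportions as Gaussian responses, as the
  original analysis did; with 30 flies per group this is serviceable but
  approximate near incidence 0 or 1.
* Recovery medians become `inf` under heavy censoring rather than switching
  to a survival estimator; survival regression is out of scope.
* The GO stage ignores transcript-length bias.
* `estimate_climb_prob`'s Wilson interval treats the 5·ΣNᵢ Bernoulli trials
  as independent, which under-covers if flies are heterogeneous (use the
  beta heterogeneity option to explore this).
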