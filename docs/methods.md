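# Methods

## Model and estimator

Wing length is a linear trait measured on both sides of each individual,
with every wing measured r ≥ 2 times. The balanced two-way mixed model

    y_isk = μ + I_i + D_s + A_is + ε_isk,   i = 1..n, s ∈ {L, R}, k = 1..r

treats the individual effect I as random (inter-individual size variation,
variance σ²_ind), side D as fixed (directional asymmetry, a consistent mean
R−L offset δ_DA split as ∓δ_DA/2 across sides), the individual × side
interaction A as random (true fluctuating asymmetry, variance σ²_FA), and
replicate scatter ε as residual measurement error (variance σ²_ME). Under
this model the expected mean squares of the balanced decomposition are

    E[MS_res]  = σ²_ME
    E[MS_int]  = σ²_ME + r σ²_FA
    E[MS_side] = σ²_ME + r σ²_FA + n r δ²_DA / 2        (two sides)

FA10a = (MS_int − MS_res)/r is therefore unbiased for σ²_FA. Repeated
measurement is what identifies it: with r = 1 the residual stratum is empty
and measurement error — which behaves statistically exactly like FA — cannot
be partitioned out; the code refuses r = 1. A raw FA10a can be negative by
sampling noise when σ²_FA is small relative to σ²_ME; it is reported as-is
with a flag, never clamped, because clamping would bias Monte-Carlo means
and any calibration built on them. Directional asymmetry is tested as
F = MS_side/MS_int on (1, n−1) df — the interaction is the correct error
stratum for a fixed effect crossed with a random one. The individual main
effect is never tested; nothing downstream uses it.

The ANOVA core is a closed-form sums-of-squares decomposition vectorized
over leading batch axes (`batch_anova`, arrays shaped `(..., n, 2, r)`);
the per-sample API wraps it. A test pins the two routes together, the suite
checks 200+ random blocks against a brute-force loop oracle at 1e−10
relative, and one fixture is frozen against an independent R `aov()` fit.

## Comparing FA between genotypes

The default two-genotype statistic is F = MS_int(a)/MS_int(b) with
(n_a−1, n_b−1) df, two-sided (doubling the smaller tail, capped at 1),
because a screen seeks both suppressors and enhancers. This ratio is
*exactly* F-distributed under H0 when the two genotypes share σ²_ME — the
situation when one measurer follows one protocol — whereas a ratio of
FA10a values (differences of mean squares) has no exact reference
distribution. The FA10a-ratio mode is provided for sensitivity analysis and
labelled approximate. The reported effect size is always the FA10a fold
change (ratio of FA10a values); when the reference FA10a is non-positive
the fold change is undefined and flagged, while the mean-square-ratio test
is still reported. Simulation over 10,000 null pairs at n = 30 confirms the
size (rejection rate 0.0497 at α = 0.05) and p-value uniformity
(Kolmogorov–Smirnov p ≈ 0.21).

## Quality control

All QC operates on the per-individual signed asymmetry d_i = mean_R −
mean_L, never on the raw values, and alters only sample membership. A
sample passes when Shapiro–Wilk p > α_norm, Lilliefors p > α_norm
(statsmodels' table-based p, mode recorded in every report), bias-adjusted
skewness g1 ∈ [−0.5, 0.5], and excess kurtosis g2 ∈ [−3, 3]. The kurtosis
bound is read on the excess scale (normal = 0): a raw kurtosis below −3 is
impossible, so excess is the only interpretation under which both bounds
are attainable. The kurtosis lower bound doubles as the antisymmetry screen
(bimodal d is strongly platykurtic); no dip test is added. α_norm defaults
to 0.05 and is configurable.

Outlier elimination is deliberately narrow. When a sample fails, the
individual with the largest modified robust z-score
|d_i − median| / (1.4826·MAD) is removed and the battery re-run — but only
while that score exceeds `min_robust_z` (default 6.0). The gate encodes
what "obvious measurement error" means operationally: at n = 30 the
expected maximum |z| of a clean normal sample is ≈ 2.1 and
P(any |z| > 6) ≈ 6·10⁻⁸, so a 6-σ point is essentially certainly a blunder
(a 10× transcription error produces z in the hundreds), while an
ungated rule would strip genuine distribution-tail individuals from the
~25% of clean n = 30 samples that fail the ±0.5 skewness bound by chance
alone. Samples failing the thresholds without such a point — e.g. genuinely
antisymmetric (bimodal) samples — are flagged and retained intact, as are
samples still failing at the removal cap (default 3) or shrinking below the
usable minimum (default 10). Calibration: a planted single 10× blunder is
the sole removal in 99–100% of simulated samples; clean bimodal samples are
never pruned.

Size dependence (allometry) is checked by correlating FA10a against group
mean size across genotypes: a positive association would mean larger
genotypes are more asymmetric and FA contrasts could be size artifacts; a
null or negative one clears the concern.

## Screen design

A series is the unit of experimental comparability: up to 25 deficiency
genotypes raised and measured together with their internal controls — a
positive control (sensitized background alone) and, in the secondary stage,
a negative control (driver alone). Every experimental genotype is F-tested
against its own series' positive control; those raw p-values form one Holm
family per series. Deficiency-alone genotypes are tested against the
negative control and Holm-corrected as their own family, since they address
a different null hypothesis. Classification at α = 0.05 (configurable) on
the adjusted p: decreasing if fold < 1, enhancing if fold > 1, otherwise
neutral; genotypes with no usable sample (no progeny, or n below a
configurable minimum of 10) are recorded lethal, damaged ones unmeasurable.
A modifier is confirmed only when significant with the same direction in
both independent stages. Simulated null screens confirm the per-series
family-wise error stays below 0.05 (measured 0.032–0.034 over 10,000
series; the 25 tests share a control denominator and are therefore
positively dependent, which Holm tolerates and which makes it mildly
conservative here).

### Power of the two-stage design

The confirmation rule is intentionally conservative, and its sensitivity
has a hard ceiling worth knowing. For a true FA fold f, the expected
mean-square ratio is λ = (σ²_ME + r·f·σ²_FA)/(σ²_ME + r·σ²_FA), which is
capped at f even with perfect measurement. With n = 30 per genotype, a
two-sided test at the Holm-effective level α/25 ≈ 0.002 on F(29, 29) has
per-stage power ≈ 0.81 for f = 5 and ≈ 0.56 for f = 0.2 at the default
σ_FA = 2, σ_ME = 1; requiring both stages squares those. Even as
σ_ME → 0 the per-stage power tops out near 0.87, i.e. two-stage
confirmation ≤ 0.76 for a fold-5 enhancer. The simulated scorecard (100
two-stage screens, 2 series × 25, three fold-5 enhancers and three fold-0.2
suppressors planted) measures ≈ 3.0/6 planted modifiers confirmed on
average, with zero false confirmations of truly neutral deficiencies —
specificity is excellent, sensitivity is the price of Holm-in-both-stages.
Screens needing more sensitivity should raise n, relax to one corrected
stage, or treat the confirmed list as a high-precision subset.

## Synthetic data

The simulator draws exactly the generative model above. Defaults are the
screen's design point: n = 30 individuals per genotype, r = 2 measurements
per wing, a micrometre-like mean wing length μ = 2500 with σ_ind = 50
(≈2% inter-individual CV), δ_DA = 1, σ_FA = 2 (FA10a = 4 in the sensitized
background) and σ_ME = 1. Screen scenarios scale σ²_FA per deficiency by
its true fold change; the negative (driver-alone) control runs at
σ²_FA/50, placing the positive/negative FA ratio in the tens, as observed
between sensitized and unsensitized controls. Lethal deficiencies emit no
individuals and a ground-truth table always accompanies generated data. One
global seed expands into independent substreams keyed by a stable CRC-32
hash of (stage, series, genotype), so adding or removing a genotype never
perturbs any other genotype's values, and primary and secondary stages are
independent replications.

What the generator does *not* emulate: temporal/batch drift within a
series, digitization error structure beyond i.i.d. Gaussian replicates
(an optional heavy-tailed mode exists only via planted blunders in the
calibration), genotype-dependent measurement error, non-Gaussian true FA,
and any coupling between canalization and developmental stability — σ_ind
is constant across genotypes, so the FA-vs-inter-individual-variance
correlation in simulated screens is weak (inter-individual variance is
σ²_ind + σ²_FA/2 + σ²_ME/(2r), dominated by σ²_ind). Passing tests
therefore certify the estimator, the tests' calibration and the screen
logic — not that real wing data meet the model's assumptions; the QC
battery exists precisely to check those on real data.

## Numerical and interface choices

Balanced blocks only: individuals with missing sides/replicates are dropped
at assembly (FA10a has no unbalanced analogue; REML variance components are
out of scope) and mixed replicate counts within a sample are a hard error.
Inter-individual variance uses denominator n−1 on per-individual means.
Pearson correlations report a two-sided t-based p labelled descriptive.
All tabular outputs are UTF-8 TSV/CSV with dot decimals; thresholds, seeds
and removals land in the run log. Two runs with identical inputs and
configuration produce byte-identical numeric outputs. Holm adjustment,
Lilliefors, Shapiro–Wilk, moment estimators and F/t distributions come from
statsmodels/scipy; the ANOVA decomposition, FA10a, the comparison test and
the screen logic are implemented here and oracle-checked.
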