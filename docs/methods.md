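# Methods

This note records the models implemented in moakit, the defaults and why,
the numerical choices, and what the synthetic generators do and do not
emulate.

## Dose–response and combination indices

Single-agent viability is modeled two ways. The 4PL fit
`RV = bottom + (top − bottom)/(1 + (D/EC50)^h)` is a least-squares fit on
log10 dose (`scipy.optimize.curve_fit`, hill slope bounded positive); it
reports the plateaus, EC50, hill slope, ECmax (smallest tested dose whose
fitted response is within 1% of the maximal-effect plateau, or the highest
tested dose) and IC50 (dose where fitted RV crosses 0.5, NaN when 0.5 lies
outside the plateaus). The median-effect fit regresses log10(fa/fu) on
log10 D by OLS; Dm = 10^(−intercept/m). The two agree exactly when
bottom = 0 and top = 1, because the 4PL is then itself a median-effect curve
with Dm = EC50 and m = hill.

Combination indices use the mutually exclusive form
CI = d1/Dx1 + d2/Dx2 (no product term), matching the default of the
standard CI software workflow. For a CI–fa curve the total combination dose
achieving each fa comes from the combination series' own median-effect fit
and is split by the design ratio — the standard constant-ratio procedure.
Consequences worth knowing:

* A sham self-combination (d/2 + d/2 of the same drug) gives CI = 1
  identically, which the tests assert as an analytic oracle.
* If both drugs share a hill slope, a Loewe-additive surface is itself a
  median-effect curve in total dose and the recovered CI is 1 to numerical
  precision. With unequal hill slopes the combination series is no longer
  exactly log-linear, and a noiseless additive pair shows |CI − 1| of a few
  percent at mid-range fa. This is a property of the constant-ratio
  median-effect interpolation, not noise.

Fraction affected is fa = 1 − RV clipped into [ε, 1 − ε] with ε = 1e−4;
clipped points are flagged and excluded from median-effect regression, since
log(fa/fu) diverges at the bounds. Replicates are averaged before fitting;
per-replicate RVs are retained for error bars. A non-positive control mean
is a calibration error; a flat response (dynamic range below twice the
replicate noise) is a degenerate fit naming the indistinguishable plateaus.

## Death-kinetics metrics

Total population size between the two lysis anchors is extrapolated
exponentially, `total(t) = T0·exp(kt)` with `k = ln(end/T0)/T`, reproducing
both endpoints exactly. Each condition uses its own endpoint lysis (a dying
well's total differs from the untreated well's); the untreated well supplies
the GR denominator. FV/LF are clamped into [0, 1] with clamp events counted;
a dead signal exceeding total by more than 5% (plate-reader noise near full
lysis can overshoot slightly) is a calibration error rather than a clamp.

LF(t) is fitted by the lag-exponential death (LED) form

    LF(t) = LF0                                    t < onset
    LF(t) = LF0 + (LFmax − LF0)(1 − e^(−rate(t−onset)))   t ≥ onset.

The onset enters non-smoothly, so the fit first grid-searches candidate
onsets over the sampled timepoints and interval midpoints with an inner
3-parameter fit, then refines all four parameters by bounded least squares.
A series whose LF range is below 0.05 is flagged `no_death` with the onset
reported as not observed — a flag, not an exception, because flat wells are
an expected outcome. AUC integrates the fitted curve when the fit converged
(noise robustness) and the raw points otherwise, with the fallback flagged.
AOC is 1 minus the mean endpoint FV over the tested log-dose range, so 0
means no response and 1 complete kill at all doses.

LF-based combination indices treat endpoint LF per dose as the fraction
affected and reuse the median-effect machinery unchanged; on matched
synthetic truth the LF- and RV-based CI agree to numerical precision, and
the tests require agreement within 0.1.

## Screen scoring

Size factors are the median over all-positive guides of count over
guide-wise geometric mean, computed in linear space and rescaled to
geometric mean 1. L2FC per replicate is
`log2((n/f_n + c)/(d/f_d + c))` with pseudocount c = 0.5, then averaged
across replicates; gene FC is the arithmetic mean over guides. This
replaces a DESeq2 parametric fit deliberately: the chain is deterministic
and dependency-free, and inference runs through the non-targeting bootstrap
null rather than negative-binomial Wald tests, so dispersion shrinkage
would buy nothing here.

Non-targeting guides are shuffled (seeded) and chunked into pseudo-genes of
four. When the pool is not divisible by four, the remainder set is completed
by resampling already-used guides; the reused ids are recorded. 142 controls
therefore yield exactly 36 sets. Genes are z-scored against the pseudo-gene
FC mean and sample SD (ddof = 1 — the pseudo-genes are a sample of the
null); a zero-spread null (e.g. a noiseless count table) is refused rather
than silently producing infinite z.

Empirical p-values are two-sided (hits are called on both signs): B
bootstrap draws of n_guides values from the non-targeting guide pool are
scored and z-scored identically, and p = (1 + #{|z_null| ≥ |z|})/(B + 1),
with attainable minimum 1/(B+1). The null depends only on n_guides, so
draws are shared across genes of equal size. An all-guides pool is available
behind the `pool` option. BH-FDR comes from statsmodels; hits at FDR < 0.1
(configurable) are split by zL2FC sign, and with two treatments R² of their
zL2FC over the union of hit genes is reported. The KS QC compares essential
vs non-essential zL2FC in the untreated-vs-T0 comparison
(`scipy.stats.ks_2samp`, asymptotic p).

Note on the bootstrap floor and FDR: with B = 1000 the smallest possible p
is ~0.001, so a BH threshold of 0.1 can only be met by the top
~0.1·(B+1) ≈ 100 ranks per 1,000 genes; screens with few true hits need
B ≈ n_genes/(0.1·k) or larger for the floor not to censor discoveries. The
acceptance checks use B = 2000 on the 1,000-gene desk screen for this
reason.

## Signature classification

RI is computed in the odds-ratio form, algebraically equal to the
difference form printed in assay protocols but stable near the boundaries;
measurements at G_t = 1 or G_c ∈ {0, 1} are degenerate and refused.
Signatures are fixed-order 8-vectors over a configurable hairpin roster
(default names one DNA-damage-checkpoint hairpin, shCHK2, plus seven
conventional placeholders; only the length and order matter to the
classifier). Replicate measurements per hairpin are averaged; missing,
duplicated-outside-roster or unknown hairpins are roster errors naming the
hairpin.

The classifier is deliberately simple and isolated behind
`knn_classify`/`classify_drug` so alternative definitions can be swapped:

* vote: majority class among the k = 3 nearest references (Euclidean on RI
  vectors); ties break toward the smaller mean distance, then
  lexicographically;
* linkage ratio: mean distance from the query to its k nearest members of
  the called class, divided by the class's mean leave-one-out k-nearest
  within-class distance. LR ≤ 1 reads "the query sits within the class's own
  spread";
* p-value: class labels are permuted B = 999 times (class sizes preserved),
  the vote re-run and the query's k-nearest class distance recomputed;
  p = (1 + #{stat_perm ≤ stat_obs})/(B + 1). The observed within-class
  spread acts as a fixed normalizer, so the permutation tests whether the
  labels carry information about the query's neighborhood. Because the
  observed labeling is itself one permutation, p is uniform under
  label-free references — the type-I simulation in the tests confirms a
  ~5% rejection rate at the 0.05 cutoff.

A call is confident when LR ≤ 1 and p < 0.05 (LR exactly 1 passes);
otherwise the query is reported as NEW_CLASS with the nearest candidate
retained. Note that a genuine class member drawn at one within-class SD has
LR distributed around 1 — the confident-call guarantee applies to queries
materially inside a class's spread, e.g. near its centroid.

## Synthetic generators: what they emulate, and what they don't

All generators are pure functions of a truth object carrying its seed;
identical truth gives byte-identical outputs.

* **Dose–response** (`gen_dose_response`): 4PL single agents (bottom 0,
  top 1), constant-ratio combination anchored on drug A's grid at the
  EC50-ratio by default. Under `loewe_additive` the combination effect
  solves the Loewe equation exactly before noise; `synergy`/`antagonism`
  multiply/divide both effective doses by (1 + strength) — a potency-shift
  model that produces CI below/above 1 by construction without committing
  to a mechanism. Noise is multiplicative Gaussian (default 0). Not
  emulated: plate edge effects, heteroscedastic reader noise, off-ratio
  checkerboard designs.
* **Screen** (`gen_screen_counts`): every guide has expected abundance
  `depth` (500 at desk scale); essential genes (first 5% of genes, skipping
  planted modifiers) are shifted −1 log2 in all post-T0 samples; a death
  modifier with effect Δ is shifted ±Δ/2 between dead and live, so its
  dead-vs-live L2FC is Δ in expectation. Counts are NB with variance
  μ + φμ² (φ = 0.1 default); φ = 0 degenerates to the expectation exactly.
  A misassignment-rate parameter (default 0) mixes dead/live expectations,
  since real annexin-bead sorting purity is not characterized. Not
  emulated: guide-level abundance skew from library cloning, PCR jackpots,
  guide-efficacy variation, proliferation differences between knockouts.
  The desk scale (1,000 genes × 4 guides + 142 controls) is the default;
  `ScreenTruth.full_scale()` reproduces the printed genome-wide composition
  (70,948 targeting over 18,053 genes — distributed 16,789 × 4 + 1,264 × 3,
  since 18,053 × 4 exceeds the printed total — plus 142 controls = 71,090).
* **Death kinetics** (`gen_flick_plate`): total population grows
  exponentially (0.03/h ≈ 23 h doubling, typical of the assayed lines);
  LF follows the LED curve of the truth (onset 24 h, rate 0.1/h,
  LFmax 0.8, LF0 0.02 — a strong cytotoxic response); dead signal is
  dead count × signal-per-cell with multiplicative noise. The exponential
  total matches the extrapolation model by construction, so noiseless
  recovery tests isolate the fitting machinery; real totals decelerate as
  death progresses, which the paper-standard two-point calibration cannot
  see either. `gen_flick_dose_series` ties the asymptotic LF per dose to
  the same interaction surface as the viability generator, so LF-based and
  RV-based CI can be compared on matched truth.
* **Signatures** (`gen_signature_data`): five mechanism classes with
  hand-placed centroids ≥ 10 within-class SDs apart (SD 0.1, 4 replicates
  per class) — a deliberately well-separated reference emulating an
  established, validated set. Queries are drawn near a named centroid or,
  for "novel", far from all centroids. Not emulated: correlated hairpin
  noise, batch effects between reference and query assays.

Passing tests on these generators demonstrate that each stage recovers the
parameters of its own generating model under realistic noise; they do not
certify performance on real plates/screens, where the un-emulated effects
above (sorting impurity, guide efficacy, correlated noise) dominate the
error budget.

## Problem sizes and numerical defaults

The test suite and acceptance checks run at desk scale: 7-dose curves,
25-timepoint kinetics (0–72 h every 3 h), the 1,000-gene screen with
B = 2000 bootstrap draws, and 20-signature references with B = 999
permutations; the full suite completes in well under a minute of compute
per stage. Tolerances asserted: 4PL/median-effect noiseless recovery to
1e−6 relative; LED recovery within 1% (onset within one sampling interval,
2 h under 1% noise); stagewise screen oracle agreement to 1e−12; planted
effect rank recovery Spearman ≥ 0.95 and ±2-effect hit sensitivity ≥ 0.9 at
FDR < 0.1. Seeds fix all randomness; every CLI output directory carries a
manifest (tool version, config snapshot, input checksums, seed) sufficient
to reproduce the run.

## Known limitations

* The constant-ratio CI machinery requires a monotone response; m ≤ 0 is
  flagged, not repaired, and non-monotone (hormetic) curves are out of
  scope.
* GR uses the two-endpoint definition; time-resolved GR(t) is computed but
  its first timepoint is undefined (denominator zero) and returned as NaN.
* The LED model describes a single death wave; mixtures (biphasic death)
  will fit the dominant wave and inflate RSS.
* The KNN/LR/permutation definitions are this package's own concrete
  choices for a classifier family whose published descriptions defer to
  prior implementations; they satisfy the documented behavioral contract
  (LR ≤ 1 and p < 0.05 for confident calls, NEW_CLASS otherwise) and are
  isolated so alternatives can be swapped.
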