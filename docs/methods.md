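# Methods

## Representations

β-values and M-values are linked by the base-2 logit
`M = log2(β/(1−β))`, `β = 2^M/(2^M+1)`. β = 0 and β = 1 map to
infinite M, so matrix conversion clips β into `[eps, 1−eps]` first with
`eps = 1e−6` (configurable); the inverse is computed in a branch-free
logistic form that cannot overflow at extreme M and always returns a
value strictly inside (0, 1). Log base 2 is fixed throughout; there is
no natural-log option. Conversion applies to observed entries only —
missingness is representation-invariant. Round trips are exact to
< 1e−9 inside the clipped domain.

The intensity-level formulas clamp negative fluorescence to zero and
regularize with offsets α = 100 (β) and α = 1 (M); the offsets make the
two representations deviate slightly from the exact logit link, with a
perturbation that vanishes as intensities grow.

## Synthetic cohorts

The generator emulates the features of array β-matrices that the
benchmark's conclusions rest on, with one Beta observation model doing
most of the work:

1. Each CpG j draws a class — unmethylated / mid-range / methylated with
   proportions (0.38, 0.14, 0.48) and class means (0.08, 0.50, 0.92) —
   and a baseline mean μ_j from a logit-normal jitter (sd 0.6) around
   its class mean. This produces the bimodal marginal.
2. A rank-3 factor model on the logit scale (per-sample factors, CpG
   loadings with sd 0.35/√rank) perturbs μ_j per sample into μ_ij,
   inducing the strong inter-sample correlation that regression-based
   imputation exploits. Working on the logit scale keeps means inside
   (0, 1).
3. Observations are Beta(μ_ij·κ, (1−μ_ij)·κ). The shared concentration
   κ yields variance μ(1−μ)/(κ+1): maximal mid-range, compressed at the
   extremes — the heteroscedasticity of β-values — with a single
   dispersion knob. κ defaults to 60 (healthy) and 15 (disease); the
   disease value makes per-CpG noise roughly twice as large in standard
   deviation, which is enough to degrade every imputer without changing
   any other structure.
4. A fraction (0.11) of CpGs is designated high-propensity; they draw
   their class from mid-shifted proportions (0.15, 0.60, 0.25), so
   their β distribution concentrates in [0.4, 0.8] and thins below 0.2,
   and they carry a baseline-missingness weight 150× that of ordinary
   CpGs.

The propensity calibration was chosen analytically, before any
empirical tuning: at a 3% overall missing rate with 11% of CpGs
carrying weight 150, the per-entry missing probability of a
high-propensity CpG is 0.03·150/(0.89 + 0.11·150) ≈ 0.26, and with 100
samples P(Binomial(100, 0.26) > 20) ≈ 0.89, so the expected share of
CpGs missing in >20% of samples is ≈ 0.11·0.89 ≈ 10%, matching the
empirically observed ~11% within sampling error. Note an intrinsic
ceiling: with the overall rate fixed at 3%, even putting *all* the
missingness on the 11% subset caps their per-entry rate at 0.27, so
this statistic cannot exceed ≈ 10.3% at n = 100 — the calibration sits
as close to the empirical figure as the design allows.

The default cohort size is 50 samples × 1000 CpGs. The CpG count is a
deliberate choice: the methyLImp-style imputer trains, for each
missing-pattern group with missing CpG set M, only on samples that
observe all of M. Under 3% MCAR each sample is missing ~0.03·p CpGs,
and the probability that another sample observes all of them is
≈ 0.97^(0.03·p): ~0.40 at p = 1000 (≈ 20 usable training samples out of
50) but ~0.01 at p = 5000 (usually none). Real arrays escape this
because their missingness concentrates on a small CpG subset; pure MCAR
at large p is exactly the regime where pattern-complete-row regression
breaks down, so the default cohort is sized to represent the method's
intended operating range. Distribution-level checks (masking
statistics, per-bin error profiles, mechanism ordering) are run at
50 × 5000, where this does not matter.

What the generator does **not** model: probe-type chemistry and
dye-bias artefacts, batch effects, age/tissue covariate structure,
genuine biological differential methylation between groups, and
spatial/chromosomal correlation along the genome. Passing tests
therefore demonstrate that the pipeline reproduces the *statistical
mechanics* of the benchmark (who wins and why, as a function of noise
shape, correlation and missingness mechanism), not that any method will
achieve a particular accuracy on a given real dataset.

## Missingness simulation

The masked count is `round(f·n·p)` with f = 0.03, rounding half-up, and
counts *all* entries as the dataset size while drawing only from
observed entries (pre-existing missing entries count toward size but
are never re-masked). MCAR samples uniformly without replacement. MAR
samples positions with probability proportional to the CpG's propensity
weight, uniform across samples within a CpG (sample-level effects would
leak value information and make the mechanism MNAR-adjacent); weighted
sampling without replacement uses exponential keys
(Efraimidis–Spirakis), and weights can either come from the generator's
profile or be re-estimated from an observed mask as
`(missing count + 0.5)` per CpG, normalized. MNAR draws each position
from the in-range pool with probability 0.70 (per-draw probability, not
a fixed 70% quota — matching a sampled position *having* 70%
probability of being in range) and from the out-of-range pool
otherwise; when a pool empties, the remaining draws are forced from the
other pool and each increments a warning counter, keeping the masked
count exact rather than failing.

Ground truth is stored on the β scale at masking time, so β- and
M-pipelines of the same repetition score identical positions against
identical truth.

## Imputation

All methods use the internal orientation rows = samples, columns = CpG
variables, and never modify observed entries. Per-method guards mirror
the reference tools' failure modes: all-missing CpGs are unimputable
for every method; `iter_pca` drops zero-variance CpGs; `chained_reg`
drops single-observation CpGs; `methylimp` refuses matrices where every
CpG has a missing value. Dropped columns' missing entries are reported
as unimputable, and evaluation ignores them (with a count).

Numerical choices worth recording:

- **knn** (k = 10): CpG–CpG dissimilarity is the mean squared
  difference over jointly observed samples; neighbours must have an
  observed value at the target sample; contributions are weighted by
  1/(distance + 1e−12), so an exact twin dominates; ties break by CpG
  index (stable sort). When no neighbour qualifies the default fallback
  is the CpG mean (the reference tool's zero-fill is available behind a
  flag, plus a strict mode that reports the position unimputable).
- **svd_iter** (rank 5, tol 1e−5, max 100 iterations): mean-initialize,
  truncated-SVD reconstruct, overwrite missing entries; convergence is
  the relative Frobenius change *at the missing entries*.
- **soft_svd** (λ = 0.1·σ₁ of the initial fill, computed once then
  fixed): same loop with soft-thresholded singular values (σ−λ)₊. The
  fixed λ schedule biases the fill toward zero when λ is large; at the
  default λ-fraction this makes soft_svd the weakest completion method
  on β data, which is an honest property of the fixed-threshold
  variant.
- **iter_pca** (ncp = 5): EM-style — center columns, shrink the leading
  singular values by a noise-variance estimate taken from the mean of
  the trailing squared singular values ((s² − σ̂²)/s, floored at 0),
  reconstruct, re-add centers.
- **chained_reg** (missForest meta-algorithm, max 10 sweeps): visit
  CpGs by increasing missingness, regress each on all others over its
  observed rows, predict its missing rows. The stopping rule is
  missForest's: when the sweep-to-sweep change in imputed values first
  increases, return the previous sweep's fill; an additional
  stabilization cut-off (relative squared change < 1e−9) stops the loop
  once sweeps become no-ops. The linear learner is exact least squares:
  solved in the primal (design-matrix lstsq with intercept) when
  columns ≤ rows, and in the n×n dual Gram form — the minimum-norm
  solution, maintained incrementally across column updates — in the
  wide regime, where it costs O(n²) per column instead of O(n·p²). The
  forest learner delegates to scikit-learn's RandomForestRegressor,
  seeded per column from the task seed. A failed fit falls back to the
  column mean and is logged.
- **methylimp**: samples are grouped by their exact missing-CpG
  pattern (no pattern merging); for missing set M over rows R, training
  rows T are all samples observing every column of M, predictors are
  all fully observed CpG columns O, and the multi-output model is
  B = pinv(X[T,O])·X[T,M] — the Moore–Penrose minimum-norm solution
  when |O| > |T|. X[R,M] = X[R,O]·B; empty T leaves the pattern's
  positions unimputable (not an error). No correlation-based predictor
  pre-selection is performed. An open design point is whether a
  bounded (logit-link) regression would suit β data better than linear
  regression plus clipping; the implementation uses linear + clip.
- β-scale imputations are clipped to [0, 1]; M-scale outputs are
  unclipped (the scale is unbounded).

Hyperparameter defaults (k = 10, rank = 5, ncp = 5, λ-fraction = 0.1,
tol = 1e−5) are this package's own declarations; each is exposed in
`ImputerSpec`.

## Evaluation and comparison

MAE and RMSE are computed over scored positions on the β scale;
RMSE ≥ MAE by Jensen's inequality, and both lie in [0, 1] for β data.
Per-range profiles use ten equal-width bins on the **true** β value
(last bin right-closed); binning by the imputed value is the noted
alternative, but binning by truth keeps the bin populations identical
across methods. Aggregation over records weights bins by their counts
and pools RMSE as the square root of the count-weighted mean square.

Wilcoxon signed-rank tests are two-sided on paired per-repetition
average scores, zeros dropped, exact null up to 25 nonzero pairs and
normal approximation with continuity correction beyond; the winner of a
significant intra-method test is the scale with the smaller mean
(two-sided + smaller-mean keeps the rule symmetric where the direction
of the test is not specified a priori). The BH family is all
comparisons within one table stratum (mechanism × cohort status ×
metric); in-table marks use adjusted p-values, with raw p available.
The relaxed best set contains every cell never significantly beaten by
a cell with a smaller mean; rank-based verdicts can disagree with the
means (a few outliers move the mean but not the rank sum), and reports
print both without reconciling them. With fewer than five repetitions
no test is possible: summaries are still produced, no winner is
declared, and every cell trivially qualifies for the best set.

## Pipeline

Masking seeds derive from SHA-256 of (base seed, cohort, mechanism,
repetition) truncated to 31 bits, so all scales and methods of one
repetition share the identical mask, and reruns are bit-identical;
method-internal randomness derives a second seed from (mask seed,
method). With the default five mechanisms, two scales and 100
repetitions, each method performs 1000 imputation runs per dataset (500
per scale) — the counter is per method. Task failures are logged and
leave absent cells rather than aborting. Outputs are long-format
`scores.csv` + `bins.csv`, per-range `profile.csv`, and per-stratum
comparison tables (CSV/JSON/plain text); reruns resume by skipping
tasks already present in `scores.csv` when the stored config hash
matches.

Problem sizes used in the shipped checks: distributional statistics on
50 × 5000 cohorts (20 seeds) and 100 × 5000 (10 seeds); qualitative
method comparisons at 20 repetitions on 50 × 5000 cohorts, with the
regression-vs-mean comparison on the default 50 × 1000 cohort for the
reason given above.

## Known limitations

- Real-data preprocessing (IDAT parsing, detection p-values,
  normalization, probe-set intersection) is out of scope; inputs are
  β/M TSV matrices or synthetic cohorts.
- The MAR propensity profile is cohort-level; per-dataset propensities
  can be supplied through the `weights` argument but are not estimated
  jointly.
- The fixed-λ soft-threshold schedule and the declared defaults stand
  in for tool-specific defaults that are not reproducible here.
- Runtime/memory profiling of the methods is not a goal.
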