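# Methods

This note documents the models, defaults, and numerical choices behind
`estro`, and what the synthetic-data tests do and do not establish about
real data.

## Regulatory feature construction

Coordinates are 0-based half-open throughout; every overlap test means
≥ 1 bp intersection. Promoters are 500 bp windows centered on the single
TSS per gene (clipped at coordinate 0; multi-TSS resolution belongs to
annotation preparation, upstream of this package). Loops are kept when they
have ≥ 3 supporting reads **and** FDR < 0.05; both boundaries are sharp
(reads = 3 kept, FDR = 0.05 dropped). A gene's enhancers are the H3K27ac
peaks intersecting the partner anchor of any kept loop whose other anchor
intersects the promoter, deduplicated across loops, excluding peaks that
overlap the gene's own promoter (so promoter signal is never double-counted
as enhancer signal — the package's choice where conventions differ).

Integrated signal arrives as a region × assay count table; the package does
not quantify BAMs. Z-scores use the sample standard deviation (ddof = 1)
and are computed within role-specific universes — all promoters together,
all enhancers together, per assay and per cell context — because the two
region classes carry systematically different signal levels. The enhancer
score Σ log₂(s + 1) is undefined for Z-scores s ≤ −1; contributions are
clamped at s = −0.99 (a floor of log₂(0.01) ≈ −6.64). The clamp preserves
monotonicity in every sᵢ and additivity over disjoint enhancer subsets and
avoids discarding genes; the floor is configurable. Per-class promoter and
enhancer "axes" average the per-gene mean across confirmed features of that
role; enhancer/ERBS counts and gene length belong to neither axis.

## Expression dynamics

Cell QC bounds (total counts, detected genes) are inclusive; the
mitochondrial cutoff is strict (< 7% in the Ishikawa-style defaults).
Normalization is ln(1 + 10⁴·x/library size). The gene filter
"mean > 0.01 across all timepoints" is read per-timepoint — a gene must
exceed the cutoff within every timepoint — with a pooled-mean variant
behind a flag.

Differential calls are two-sided Wilcoxon rank-sum tests (normal
approximation with tie correction) on normalized values, each treated
timepoint against 0 h, without a fold-change cutoff. Genes constant across
both groups get p = 1. Multiple testing is corrected per timepoint;
Benjamini–Hochberg at α = 0.05 is the default (Bonferroni and uncorrected
are options) — the correction procedure is a documented choice, not a
published one. Early = significant at the first treated timepoint; Late =
first significant at a later timepoint, with the direction taken at that
first significant timepoint. Control genes are sampled (seeded) from the
unlabeled pool to match the regulated genes' counts within ten
equal-frequency mean bins. Mean-level classes cut the 0 h means at the
20th/80th percentiles with stable gene-id tie-breaking.

### Noise metric

CV is computed on normalized values over the 0 h cells (computing it on raw
counts is a flag away; the scale used in the original analysis is
unstated). The mean trend is removed with a Gaussian GAM of
y = log₂(CV + 1) on the mean: a cubic B-spline basis with df = 10,
quantile-spaced knots, an explicit unpenalized intercept, and a mild ridge
penalty α = 0.01. Generalized cross-validation on the study-condition data
selects an effectively unpenalized fit, so the default is nearly the
GCV-optimal smoothing; α is exposed for rougher data. Residuals are
back-transformed multiplicatively (2^r − 1), the exact inversion of the
modeled quantity; an additive variant (CV − fitted CV) is available. Noise
labels are the top/bottom 20% of adjusted CV within ten equal-frequency
mean bins; ties break by gene id for determinism.

## Feature ranking

`BorutaSelector` re-implements the shadow-feature algorithm: per iteration,
every surviving column gets an independently shuffled shadow; a 100-tree
random forest is fitted and a real feature scores a hit when its importance
exceeds the best shadow's. Hit counts are tested two-sided against
Binomial(n, ½) with Bonferroni correction over the currently undecided
features; significant excess → Confirmed, deficit → Rejected (rejected
columns and shadows leave the model). Tentative features at `max_iter`
(default 100) are reported as Tentative, never coerced.

The importance provider matters: the default is permutation importance on a
held-out third of the data. In-sample impurity (Gini) importance — offered
as a faster option — systematically re-rewards a noise feature's *fixed*
chance association with the labels every iteration while the re-shuffled
shadows redraw theirs, so features that survive the early rejections can be
falsely confirmed once the shadow pool shrinks. Held-out permutation
importance of such features is centered at zero, which keeps the
pure-noise false-confirmation rate at or below the nominal threshold.

The illustrative CART tree maps the rpart-style complexity parameter onto
scikit-learn as min_impurity_decrease = cp × root Gini impurity, with
minimum leaf size 50 and cp = 0.007 as defaults. The mapping is
approximate: rpart scales split improvements by the root risk, and on pure
noise rpart itself still emits a handful of chance splits at these
settings, so the meaningful guarantee is heavy pruning relative to cp = 0,
not a single-leaf tree. Reported trees are truncated to 4 levels.

Importance profiles across analyses (mean / trajectory / noise) are
compared by Pearson correlation of the mean-importance vectors over the
shared feature set and by PCA of the analyses in importance space
(components capped at n_analyses − 1).

## Perturbation timing

ΔΔCt: ΔCt = Ct(target) − Ct(reference); the baseline is the control
condition's mean ΔCt at 0 h, so fold changes are relative to the untreated
control. Fold change = 2^−ΔΔCt. Adding any constant to all Ct values of a
(condition, replicate, timepoint) block cancels exactly.

Loess uses local quadratic regression with tricube weights over the span
fraction (default 0.75) of nearest points, replicates entering as separate
points, evaluated on a 0.1 h grid covering the observed range only. Grid
points equidistant from two sampled times can leave fewer distinct x values
with nonzero weight than a quadratic needs; R's loess rescues these with a
pseudoinverse, and this implementation instead degrades the local degree
(quadratic → linear → weighted mean) at the affected grid point. On the
closed-form check (y = t/(t+2), 5 timepoints × 2 replicates) the curve
matches R's loess to the printed precision (max |fit − truth| = 0.0463).
If a window is genuinely singular the whole fit is retried once at
span = 1.0, then raised.

Time to half-max is the first grid time at which the fitted curve reaches
half of its **maximum fitted value** — no baseline subtraction, consistent
with defining half-max from the maximum at any timepoint (a
baseline-subtracted variant sits behind a flag; elevated baselines then
change the answer, which is why the default avoids it). A consequence worth
stating: for a saturating curve like y = t/(t+2) observed to T = 8 h, the
analytic half-max time under this rule is T·b/(T+2b) = 4/3 h, not the 2 h
at which the curve crosses half of its t→∞ asymptote. Slopes are central
differences of the fitted curve; group aggregation (targeted vs control)
reports per-grid-time means with normal-approximation 95% CIs, flagging
single-fit groups.

## Co-expression

Spearman correlations use average ranks and only the cells of one
timepoint. Pair sets are unordered and deduplicated; zero-variance genes
drop their pairs (counted, not fatal). The shuffled null permutes the
second pair members, rejecting self-pairs and re-creations of observed
pairs — preserving each gene's pair multiplicity; whether the original
analysis preserved degree is unstated, so this is a documented assumption.
Group comparisons are two-sided Wilcoxon rank-sum with Bonferroni
correction over the caller-supplied family of panel comparisons.
Correlation-extreme analysis pools the High- and Low-noise pair
correlations, cuts them into 10 equal-frequency bins (configurable), and
reports per-bin composition.

## Synthetic data: what it emulates

The generator plants a known truth and couples the architecture to it:

* **Annotation** — one TSS per gene in equal slots with ≥ 10 kb spacing on
  one synthetic chromosome; log-normal gene lengths (median 20 kb).
* **Classes** — 5% of genes per regulated trajectory class (EarlyUp,
  EarlyDown, LateUp, LateDown; 80% null), matching the observed scale of
  E2-responsive genes (hundreds out of ~12k expressed). Noise classes are
  20/60/20 (High/Mid/Low) with NB dispersions φ = 2.5/0.5/0.1, independent
  of trajectory and of the baseline mean. φ = 2.5 corresponds to a strongly
  bursty gene (extra-Poisson CV ≈ 1.6); the 25-fold High/Low separation
  keeps the dispersion classes recoverable from 500 cells while a 2-fold
  mean shift remains statistically detectable — the joint calibration the
  recovery checks presuppose.
* **Counts** — NB with gene dispersion φ, baseline means log-normal
  (median 0.5 counts/cell, σ = 1), log-normal library factors (sd 0.3 on
  the natural log). Early classes pulse: full log-fold-change at 2 h,
  linearly decaying to half by 8 h; Late classes ramp from 4 h to the full
  effect at 8 h; Down classes mirror Up. Default fold changes are 2.
* **Architecture** — enhancer counts are class-conditional Poisson (base
  rate 2; ×(1+c) for EarlyUp, ×(1+0.5c) for High noise at coupling c);
  ER-overlap probability 0.2 + 0.6c for EarlyUp enhancers; promoter SIN3A
  signal shifted +1.5c (log scale) for LateUp genes; promoter H3K27ac
  tracks the baseline mean and (negatively) the noise class. Every planted
  enhancer sits inside a loop anchor whose partner anchor covers its gene's
  promoter; a configurable fraction of loops carries < 3 reads or
  FDR ≥ 0.05 and is lost to the filter. Occasional shared enhancers and
  promoter–promoter loops make the co-expression pair sets non-trivial. At
  c = 0 every architecture feature is statistically independent of every
  planted class.
* **qPCR** — Ct tables constructed so that the ΔΔCt analysis recovers a
  specified relative-expression curve exactly at zero noise, with Gaussian
  Ct noise otherwise.
* **Co-expression module** — a dedicated generator gives each gene pair a
  shared per-cell latent factor with configurable loading on the NB
  log-mean (0.5 by default; 0 = null).

What the generator does **not** emulate: UMI chemistry and doublets,
dropout beyond what NB sampling implies, cell-cycle structure, batch
effects, correlated gene programs outside the explicit co-expression
module, and any dependence of dispersion on mean. Passing recovery tests
therefore shows the estimators are correct and calibrated under the stated
model, not that real hormone-response data satisfies that model.

## Problem sizes in the checks

The recovery checks run at 2,000–3,000 genes with 500 cells per timepoint,
Boruta at 1,000 instances with 25 features over 5 seeds, and the
co-expression null over 50 seeds of 50 pairs × 200 cells — sizes at which
every stage completes in a few minutes on one CPU while the planted effects
are comfortably inside the detectable regime.

## Known limitations

* The GAM penalty is fixed rather than REML/GCV-selected per dataset;
  on strongly different mean distributions the default may need adjusting.
* The Boruta decision rule tests cumulative hit counts repeatedly
  (sequential testing without alpha spending), like the reference
  algorithm; the binomial threshold is therefore approximate.
* rpart's cp semantics are emulated, not reproduced exactly.
* Wilcoxon p-values use the normal approximation; for very small cell
  numbers (< ~20 per group) an exact test would differ.
* `half_max_time` depends on the observed time range because the maximum
  is taken over the fitted grid; comparing conditions assumes a shared
  range (enforced by the shared grid in group aggregation).
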