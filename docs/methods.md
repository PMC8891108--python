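# Methods

This note documents the models implemented in `fibroscreen`, the defaults and
their rationale, what the synthetic-data generators emulate (and what they do
not), and the numerical choices a maintainer should know about. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Dose–response model

Well responses are modelled with the four-parameter logistic (4PL)

    y(d) = bottom + (top − bottom) / (1 + (d / EC50)^hill)

Inhibition curves use the convention `hill > 0` with the response falling
from `top` (vehicle plateau) to `bottom` as dose rises. Raw wells are first
normalized to the vehicle plateau ("TOP"): the vehicle-control mean maps
to 1, the blank-corrected zero to 0, so fitted tops sit near 1 and the bottom
is bounded at 0 by default (`bottom_min=0`, relaxable; the top is left free to
tolerate overshoot).

Numerical choices:

* The EC50 is optimized as log10(EC50), bounded to the tested dose range ± 2
  decades, and initialized from the dose bracketing the half-maximal mean
  response. This stabilizes an otherwise ill-conditioned fit; a fit whose
  log-EC50 lands on the search boundary is reported as non-converged.
* Least squares uses `scipy.optimize.curve_fit` (trust-region reflective)
  with tight tolerances (1e-14) so that noise-free data reproduce their
  generating parameters to ~1e-6 relative.
* Non-identifiability is reported, never silent: constant responses, optimizer
  failure, or a fitted dynamic range `|top − bottom|` below twice the residual
  SD all yield `converged=False` with a reason. The factor 2 is a pragmatic
  noise gate: a curve whose span is within noise carries no EC50 information.
* 95% CIs are asymptotic by default (curvature covariance, Student-t with
  n − 4 df; the EC50 interval is formed on the log scale and exponentiated).
  Whether the original analysis used profile or asymptotic intervals is not
  determinable; a case-resampling bootstrap is available via
  `ci_method="bootstrap"` and documented as the alternative.

`ec_f(fit, f)` evaluates the closed form `EC50 · (f/(100−f))^(1/hill)`; `f`
is interpreted as *relative* effect between the fitted plateaus (the
convention of the ECanything-style analysis this mirrors). An absolute
variant (f% suppression of the top plateau) sits behind `mode="absolute"`.
`working_dose` implements the follow-up dosing rule as a configurable
multiple of the fitted EC50 (default 10×).

The therapeutic index is `toxic EC50 / effective EC50`. When the toxicity fit
does not converge (no response up to the highest tested dose) or its EC50
exceeds the tested range, the index is the lower bound
`max_tested / effective EC50` with `censored=True`.

## Plate quality control

With μ±/σ± the control-group means and sample SDs (ddof = 1):

* `Z′ = 1 − 3(σ₊ + σ₋)/|μ₊ − μ₋|`
* `S:B = μ₊/μ₋`, `S:N = (μ₊ − μ₋)/σ₋`
* `SW = (|μ₊ − μ₋| − 3(σ₊/√n₊ + σ₋/√n₋)) / (σ₊/√n₊)` — the
  replicate-adjusted signal-window definition from the assay-validation QC
  literature; SW is named inconsistently across sources, so the formula is
  pinned here and the plain (non-√n) variant is available via
  `sw_replicate_adjusted=False`.

Control orientation (which role carries the maximum signal) is taken from the
plate map, never inferred; in an anti-proliferative absorbance screen the
vehicle ("negative") control is the maximum-signal group. Thresholds are
config defaults: plates are rejected at Z′ < 0.3 or SW < 1 (strict), the
screen is accepted at mean Z′ ≥ 0.5 and mean SW ≥ 2. Screen-level averaging
excludes rejected plates by default (`include_rejected_in_mean` reverses
this; the choice is a design decision, both are pure functions of the
metrics). Activity calls summarize per-repetition EC50s by geometric mean —
EC50s are log-distributed — and require ≥ 3 repetitions and summary
EC50 < 10 µM in both assays.

## ADMET scoring, ranking, similarity

Per-parameter scores live on the 0–30 scale directly (0 = negative/poor,
30 = positive/optimal); this makes the 0–30 range of the total score exact.
The alternative reading — unit scores rescaled at the end — would change
nothing structurally and is intentionally not implemented. Numeric parameters
interpolate linearly between rubric anchors and clip beyond them; categorical
parameters are looked up. The rubric is data, not code: a YAML-loadable,
versioned config. A documented default ships for common prediction outputs,
but tests and the acceptance script always pass explicit rubrics so results
are rubric-independent.

The prediction score is `Σ w_c · mean(scores in c) / Σ w_c` over the five
categories with default weights (2, 3, 2, 1, 1). Empty categories are an
error (averaging them is undefined). The score is monotone in every
parameter score and bounded in [0, 30].

Working-set selection: the published selection was visual (potency vs score);
the pinned operationalization is the rank product of the ascending-EC50 rank
and descending-score rank (average ranks on ties, tie-break by lower EC50,
then id). Being rank-based it is invariant to monotone transforms of either
axis. A Pareto-front ordering is available via `method="pareto"`.

Fingerprints hash all linear heavy-atom paths of 1–7 atoms from the SDF
connection table (canonical min of path string and its reverse, BLAKE2b,
folded to 1024 bits). The construction is pinned because the external tool
used for the published similarity dendrogram does not document its internals;
any precomputed fingerprint can be substituted (`Fingerprint.from_bits`).
Tanimoto similarity is `|A∩B|/|A∪B|`, defined as 0 for two empty
fingerprints.

## Migration

Fractional closure `c(t) = 1 − area(t)/area(t₀)`; the migrative index divides
by the mean vehicle-control closure at the same timepoint. The exact formula
in the method's external source is not reproducible from the screening
protocol text, so this normalized-closure definition is pinned as default and
the unnormalized closure is always reported alongside. Areas exceeding the
starting area are biologically impossible (segmentation jitter) and are
clamped to zero closure, with a warning beyond a 5% relative tolerance.

## Multiple testing

BH and BY adjusted values delegate to statsmodels. The two-stage adaptive
procedure (BKY) is implemented directly: stage 1 runs BH at `q′ = q/(1+q)`,
`m₀ = m − r₁` estimates the null count, stage 2 reruns BH at `q′·m/m₀`
(reject all if `m₀ = 0`). The returned "adjusted" values are
`BH_adjusted · (m₀/m) · (1+q)` clipped at 1, which reproduces the rejection
set exactly at level q; being adaptive they are specific to the target level.
Ties are handled by stable sort. A "Q value > 2" reading of discovery plots
is interpreted as −log10(q) > 2, i.e. q < 0.01, consistent with the 1% FDR
gate used throughout the miRNA stage.

The t-tests feeding these procedures are pooled-variance unpaired tests by
default (matching the defaults of the graphical analysis software this
mirrors); Welch is available via `equal_var=False`.

## miRNA stage

Features with cT above the detection ceiling (32 cycles) in more than one
replicate *within any treatment group* are excluded globally — a feature
unmeasurable in one arm cannot be compared across arms. The per-group
("all") variant of the rule sits behind `scope=`. Undetected reactions should
be encoded as ceiling + 1 before filtering. Samples are then centered on
their column means over retained features (idempotent, shift-invariant), and
treated-vs-control t-tests are BKY-flagged at q = 0.01. Fold-change follows
the qPCR convention: lower cT = higher expression, `log2FC = mean(control cT)
− mean(treated cT)`. Technical replicates are treated as test units by
default (the 2 × 3 design gives 6 units per arm); zero-variance features get
a documented pooled-SD floor (1e-9) and a flag. No relative-threshold
baseline correction is applied — the analysis operates on raw exported cT, by
design. Identifier-database version conversion is out of scope.

## Panel and RNA-seq stages

Reference-gene normalization scales each sample by the geometric mean of the
reference-gene counts, divided by the across-sample mean of those geometric
means; reference geometric means are exactly equalized afterwards. The vendor
formula the published analysis used is proprietary; this geometric-mean
scheme is the standard published approach and is pinned, not claimed
identical. Note that rescaling one sample changes the across-sample mean
slightly, so "normalize, then perturb one sample, then renormalize" agrees
with the unperturbed result up to one global factor — the invariant tests
check proportionality plus exact equality of the reference geometric means.

DEG calling transforms to `log2(x + 0.5)` (pseudocount pinned at 0.5) and
fits a per-gene linear model with intercept, treatment contrast and donor
indicator columns, vectorized across genes; donor indicators are per-donor
centering with the correct residual degrees of freedom, a transparent blocked
substitute for the vendor's covariate model (unblocked via `block=None`).
Each donor must contribute both conditions when blocking. A gene is a DEG
only if it passes both the FDR gate and the fold-change gate; the two gates
are recorded separately. The panel stage uses the adaptive two-stage FDR at
5% with log2 |FC| ≥ 1; RNA-seq uses BY at 5% with log2 |FC| ≥ 1.3 — the two
stages intentionally pin different adjustments, exactly as the source
protocols state them, despite the apparent inconsistency.

Shared-DEG sets: "all" = same-direction DEG in every treatment table,
"near" = same direction in ≥ `min_conditions` but not all; direction
conflicts are excluded from both and logged. Pathway signatures score a gene
set per condition as the mean over member genes of the gene's mean
expression, centered on the signature's across-condition mean (normalized
scores sum to zero over conditions by construction).

CPM filtering retains genes with CPM strictly above 0.25 in at least 3
samples. TMM follows the original description: reference sample by
upper-quartile proximity to the mean, per-gene M/A values on positive counts,
double trim (30% on M, 5% on A), inverse-variance (delta-method) weights,
factors normalized to geometric mean 1. With only three libraries per arm, a
donor-blocked RNA-seq test would leave two residual degrees of freedom, so
the RNA-seq test is unblocked by default (`block="donor"` re-enables it).

## Synthetic-data generators

All generators take an explicit integer seed through their truth objects and
draw from a local `numpy.random.default_rng`; identical truth gives
bit-identical output, and there is no global random state.

* **Screen** (`ScreenTruth`): each compound well equals its true 4PL value at
  the well's dose, scaled by the vehicle-control mean, times a
  mean-preserving multiplicative log-normal factor with the stated CV
  (plate-reader noise scales with signal; at CV = 0 wells sit exactly on the
  curve). Controls draw around their role means with the same model. The
  default design mirrors the screening campaign's scale: 7-point tenfold
  dilutions spanning 10 µM–10 pM, 6 technical replicates, 3 biological
  repetitions (one plate per repetition), 8 control wells per role placed in
  the edge columns — plate layouts are conventional assumptions, as no
  layout is prescribed by the protocol.
* **cT matrix** (`OmicsTruth`): expressed features draw baselines uniformly
  in 22–28 cycles; unexpressed features sit at 35 ± 1 cycles, above the
  detection ceiling with high probability; well noise is 0.5 cycles SD. A
  spiked log2FC lowers the treated-group mean cT by that many cycles.
  Effects on unexpressed features are rejected (spiked ⊆ expressed is an
  invariant). The preset matches the array scale: 754 features, 165
  expressed, 20 spiked at ±3 cycles, 6 replicates per treatment (2 technical
  × 3 passages treated as units).
* **Panel counts**: gamma-Poisson (negative binomial, Poisson at dispersion
  0) with log-linear treatment effects, gene-specific donor (lot) effects
  (SD 0.5 log2) and per-sample depth factors (SD 0.2 log2). Reference genes
  are high-expressed with zero treatment and donor effect, so they track
  depth only. Preset: 770 genes, 3 donors, 10 reference genes, 60 spiked at
  |log2FC| = 2, dispersion 0.02 (technical-replicate scale for a hybridization
  panel), and two replicate measurements per donor and condition — duplicate
  measurements mirror the duplicated design of the miRNA arm and keep the
  blocked model's residual degrees of freedom positive.
* **RNA-seq-like counts**: relative abundances pin the top transcripts to
  preset shares (default 3.3%, 2.0%, 1.3%, 1.3%, 1.2%, 1.0%, so the top 6
  exceed 10% of reads, matching the long-tailed profile of a fibroblast
  transcriptome) with a log-normal tail (σ = 1.8); 5,000 genes and 5 × 10⁶
  reads per library by default — a deliberately scaled-down deep-sequencing
  run, sized so that moderately expressed transcripts remain quantifiable at
  n = 3 per arm under the conservative BY gate. Spiked genes are drawn from
  the upper half of the tail abundance distribution: a spiked gene must be
  quantifiable to be recoverable (and must survive the CPM filter), so
  spiking unexpressed genes would measure filtering, not testing.

What the generators do **not** emulate: spatial plate artefacts (edge
effects, drift), probe-specific qPCR amplification efficiencies, count
zero-inflation, donor-by-treatment interactions, and library-preparation
batch structure beyond a scalar depth factor. Passing recovery tests on this
synthetic data therefore validates the *statistical machinery and rule
logic*, not robustness to those real-data artefacts.

## Known limitations

* The 4PL asymptotic CIs rely on local curvature; for very steep Hill slopes
  or sparse designs the bootstrap option is preferable.
* The blocked linear model assumes additive donor effects on the log scale;
  interaction structure is not modelled.
* The SDF reader handles V2000 atom/bond blocks only (no V3000, no
  properties); it is intentionally minimal because only connectivity feeds
  the fingerprint.
* Enrichment analysis, identifier conversion, descriptor computation and
  image segmentation are out of scope; their inputs/outputs cross this
  package's boundary as plain tables.
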