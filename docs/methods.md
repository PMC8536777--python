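# Methods

This note documents the models implemented in `chronode`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
benchmarks do and do not demonstrate.

## Study design being modelled

The pipeline targets dense, short-horizon bulk RNA-seq time courses with a
treatment arm and two control arms (here: spinal-cord transection vs sham
surgery vs uninjured tissue), sampled every 30 min over the first 2 h and
hourly to 21 h, in several partially overlapping series that all include
the 0 h point. Each series comes from a different animal batch, so series
identity doubles as the batch factor. There are no biological replicates in
the usual sense; temporal density takes their place, which drives most of
the methodological choices below.

## Synthetic data generator (`simdata`)

Counts are drawn as `K ~ NB(mu, phi)` with
`mu = libsize · 2^latent / Σ 2^latent`, where
`latent = baseline + condition-specific kinetic deviation + batch offset`
(log2 scale). Defaults:

- `nb_dispersion = 0.04` (BCV 0.2) — the biological coefficient of
  variation the no-replicate exact test itself assumes, a standard value
  for genetically identical model organisms.
- `batch_sd = 0.3` log2 for per-(gene, series) offsets — large enough to
  visibly degrade the agreement of 0 h anchor points across series, which
  is the observable the batch-correction stage exists to repair.
- Baseline log2 means ~ N(6, 2), truncated at 0; library sizes uniform in
  a configurable range.
- Kinetic profiles: zero before onset, a logistic ramp rescaled to hit 0
  at onset and the full amplitude at the peak, then (if transitory) an
  exponential decay that does not return to baseline within the window.
  Six default modules span the kinetic taxonomy: two early-up transitory
  modules (amplitudes 3.0 and 2.5 log2 — immediate-early-gene-scale
  induction, with fast 0.12/h and slow 0.04/h decay so one declines from
  ~2 h and the other from ~8 h), intermediate up/down sustained
  (amplitude ~2), late up/down sustained (onsets 11–11.5 h).
- The sham arm receives the injured deviation attenuated by 0.2
  (configurable): injury of adjacent tissue elicits a weak echo of the
  response, which is precisely why a dual-control intersection rule is
  needed.

A caveat discovered while validating the generator: because counts are
compositional (library-size scaling), a deviation planted in *all* genes
cancels out of the counts. Effect genes must be a minority, as they are in
real data; the benchmark designs respect this.

The generator does not emulate: gene-length or GC bias, count outliers
beyond NB, correlated noise between neighbouring time points, unbalanced
library-size failures, or homeolog structure. Passing benchmarks therefore
demonstrate correctness of the algorithms under NB noise with batch
structure — not robustness to every artefact of real libraries.

## Filtering, VST, consistency QC (`counts_io`)

A gene is detected if it has ≥ 5 counts at ≥ 4 distinct time points within
at least one condition ("detected" is read per-time-point; replicated time
points count once). The transform is a self-contained closed-form NB VST:
median-of-ratios size factors, a method-of-moments parametric
dispersion–mean trend `alpha(mu) = a1/mu + a0`, and
`vst(q) = log2((1 + a1 + 2 a0 q + 2 sqrt(a0 q (1 + a1 + a0 q)))/(4 a0))`.
This is not a bit-compatible port of any reference tool; what downstream
stages need — monotonicity in counts and variance flattening (the SD-mean
slope drops to ~1% of its raw value on simulated NB data) — is tested
directly. Spearman QC reports rank correlations for within-series
neighbouring time points, cross-series samples at the same condition and
time (overlap points), and same-series same-time samples (replicates).

## Batch adjustment (`batch`)

Classical parametric empirical-Bayes location–scale adjustment:
standardize per gene against a design of batch indicators plus protected
covariates, estimate per-(gene, batch) means and variances, shrink them
toward batch-level normal / inverse-gamma priors with method-of-moments
hyperparameters (iterative solution, relative tolerance 1e-4, ≤ 100
iterations), then remove and rescale. Two structural points:

- In the emulated design, series (batches) are nested within condition, so
  a condition covariate is exactly collinear with the batch indicators and
  cannot be protected; the pipeline protects what is identifiable — a
  cubic time trend, which varies within every series — and drops the rest,
  by rank check. When batch is fully aliased with condition (one series
  per condition), adjustment is skipped: removing "batch" would remove
  the biology.
- EB shrinkage is not a projection, so adjustment is only approximately
  idempotent: a second fit-and-adjust pass moves entries by a few percent
  of the first pass (the unshrunk residual), vanishing only as the
  shrinkage weight approaches 1. The tests assert this derivable bound
  rather than exact idempotence.

## GP differential expression (`gp`, `gp_tde`)

Squared-exponential kernel plus independent noise; exact marginal
likelihood via Cholesky with analytic gradients; L-BFGS-B in log-space
over bounds lengthscale ∈ [0.5, 50] h, variances ∈ [1e-6, 1e3], with a
moment-based initialization plus seeded log-uniform restarts (default 5).
Both hypotheses see the data on one pooled standardized scale. The BIC
penalty uses k = 3 (shared) vs k = 6 (separate) and the same N = total
observations, so the hypotheses are compared on identical data. Constant
input returns a noise-only fit with signal variance at its lower bound;
non-finite optimizations flag the gene rather than scoring it 0.

Calibration on the full NB→VST pipeline (22 hourly points per condition):
0% of 2,000 null genes reach score 10 (bound: 1%), and 98.5% of 200 genes
with a sustained 1.2-log2 divergence — four times the ~0.3 measured VST
noise SD — exceed it (bound: 95%). The kernel is a modelling choice, not
an identity with any upstream tool; the acceptance surface is this
calibration, not score equality.

## Network modules (`network`)

Biweight midcorrelation uses the standard 9·MAD weighting with a
max-outlier-proportion cap of 0.1 per side: without the cap, bimodal
profiles (a step between two expression regimes — exactly what sustained
injury-response genes look like) have the minority regime zero-weighted
because MAD collapses onto the majority level. Zero-MAD genes fall back to
Pearson and are flagged. Soft threshold: smallest power (grid 1–20) whose
signed scale-free fit R² ≥ 0.8, else the maximizer. TOM follows the
standard formula; module detection decomposes the average-linkage
dendrogram recursively, accepting a branch as a module when it has
≥ `min_module_size` (default 30) leaves and its mean internal
dissimilarity is ≤ 0.97× the matrix-wide median off-diagonal
dissimilarity. The margin form matters: unstructured genes have TOM ≈ 0,
so their dissimilarities compress against 1 with a long left tail, which
defeats additive or MAD-based thresholds but not a multiplicative one.
Leftover genes closer to a module than the threshold are attached to the
nearest module (a simplified analogue of the hybrid cut's assignment
stage). Labels are size-ordered; 0 = unassigned. Eigengenes are first
right-singular vectors of the standardized module submatrix, oriented
positively with the module mean; kME is each gene's bicor with its own
eigengene. Known limitation: kME inherits bicor's outlier treatment, so
step-like modules show kME ≈ 0.5–0.6 where Pearson would report ≈ 0.95;
the membership filter downstream should be read with this in mind.
Module merging by eigengene correlation is available conceptually but off
by default — the planted-recovery benchmarks did not require it.

## Change-point kinetics (`kinetics`)

Piecewise-constant Gaussian levels with conjugate normal–inverse-gamma
segment priors; evidence for m = 0, 1, 2 changes by exact enumeration over
ordered configurations (uniform within model, uniform over models).
Priors are empirical-Bayes-scaled to the series (`mu0 = mean`,
`beta0 = variance`, `kappa0 = 0.2`, `alpha0 = 1`), which makes the
posterior over configurations exactly invariant to adding a constant and
to positive rescaling — verified by test. A change between consecutive
observations is located at their midpoint; reporting the first point of
the new regime instead would bias onsets late by construction.
Classification: timing from the bin containing the MAP onset (early < 2 h,
intermediate 2–6 h, late 10–13 h — configuration, not estimation),
direction from the sign of the level change, transitory when an
opposite-signed second change carries model-averaged posterior support
≥ 0.5. The segment marginal has an independent closed form (multivariate
Student-t), used as the enumeration oracle. This is a deliberate
simplification of regime-switching approaches: only change-time locations
and their confidence feed the taxonomy, and exact enumeration is
oracle-verifiable. Profiles with more than two same-signed phases need
`max_changes` raised.

## Enrichment (`enrich`)

One-sided hypergeometric tail per term; membership filter kME ≥ 0.6;
p ≤ 0.01. Redundancy: keep terms with ≥ 5 module genes, or covering ≥ 15%
of the module, or containing ≥ 15% of the term's annotated background.
Semantic distance: `1 − [w·J_ancestors + (1−w)·J_genes]` with w = 0.5 —
ancestor-set Jaccard stands in for information-content similarity, which
would need a reference corpus; terms missing from the ontology contribute
J_ancestors = 0 and are flagged. DBSCAN (eps 0.7, minPts 2 — tuned on the
synthetic ontology benchmarks, not taken from any external source) with
noise promoted to singleton clusters so every enriched term survives.
ΣBIC sums, per term, the minimum of each member gene's two comparison
scores — the calling rule is an intersection, so the weaker comparison is
the binding one; `mean`, `vs_uninjured` or `vs_sham` are selectable.

## No-replicate exact test (`pairwise`)

Libraries are equalized to the geometric mean of their totals (half-even
rounding); the test conditions on the per-gene sum s and enumerates
`P(Y_A = a, Y_B = s − a)` for `Y ~ NB(s/2, phi)`, summing configurations
no more likely than the observed one (relative tie tolerance 1e-9). For
s > 1e6 a continuity-corrected normal approximation is used and flagged.
Fold changes add a prior count of 0.5; calls are inclusive at
|log2 FC| ≥ 1 and p ≤ 0.01. Measured type-I at nominal 0.01 is ≈ 0.01
(conservative-to-nominal, as expected for a discrete exact test). Simple
library-size scaling (not trimmed-mean) is used, so a large asymmetric
fraction of changed genes induces composition bias; the benchmarks keep
planted changes a small minority.

## Pipeline and determinism

Stages run in dependency order, validated statically before execution;
every stage writes outputs plus a manifest (parameters, input/output
hashes, seed). All randomness derives from the master seed through named
sub-seed derivation — no stage reads the clock — and a rerun with the same
config and seed is byte-identical (asserted at file-hash level in the
tests).

## Benchmark problem sizes

The shipped benchmarks use 2,000 + 2,000 genes for GP calibration (five
restarts), 700 genes × 10 simulations for module recovery (β = 15, the
kind of power such data support; β = 6 gives the same recovery), 100
replicates per planted onset for change-point recovery, and a 3,000-pair
mean grid for exact-test calibration — sizes chosen so the whole suite
runs in a few minutes on one CPU while keeping Monte-Carlo error well
below every asserted margin.
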