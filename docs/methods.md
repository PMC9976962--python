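# Methods

This note documents the models implemented in `crossmeth`, the synthetic
data they are validated on, the numerical choices, and the limits of what
the tests demonstrate.

## Scales and conversions

All modeling happens on M-values, m = log2(β/(1−β)), with Beta-values
β clamped to [ε, 1−ε] before the transform (default ε = 1e-6, chosen only
to keep the logit finite; results are insensitive to ε well below typical
assay noise). `m_to_beta` inverts the transform exactly inside the clamp.

## Synthetic compilations

`synth.generate_dataset` emulates the structure of a multi-study,
two-platform blood compilation. Per sample,

```
beta = inv_logit( logit( R·w  [with sex shift at planted DMPs] )
                  + study_offset + age_slope·(age − 40)
                  + loading1·ancestry_pc1 + loading2·ancestry_pc2
                  + noise ),  clamped to [1e-6, 1 − 1e-6]
```

where R is a six-cell-type reference panel and w a Dirichlet draw whose
concentration depends on the sample type: whole blood and cord blood are
granulocyte-dominant; PBMC granulocyte fractions are near zero
(Beta(1, 60), median ≈ 1.6%) with a configurable heavy contamination tail
(probability 0.15 of a U(0.05, 0.45) draw), so roughly the top 7% of PBMC
samples exceed the 0.25 granulocyte filter — matching the situation the
filter exists for. All other effects are additive on the logit scale;
study offsets are drawn per (probe, study) from N(0, study_offset_sd).

Defaults and why:

- `study_offset_sd = 0.5` (logit): strong study-level bias, large enough
  that the study label dominates unadjusted variance partitions, as it
  does in real pooled compilations.
- `noise_sd = 0.6` (logit, ≈ 0.10–0.13 Beta-scale SD at mid-range means):
  cross-study residual dispersion. Single-study blood probe SDs are
  typically a few percent; pooling dozens of studies inflates them, and
  this value reproduces that regime.
- `sex_effect_delta = 0.1` (Beta scale): a moderate DMP effect, in the
  middle of the δ grid used by the power analyses. The delta is specified
  on the Beta scale (what array studies report) and converted per probe
  to the equivalent logit shift, applied as ±δ/2 by sex before the other
  logit-scale effects; planted DMPs live only on shared, autosomal,
  unflagged probes so standard probe filters never remove the signal.
- `age_slope_sd = 0.002`/year and `ancestry_loading_sd = 0.05` (logit):
  small per-probe demographic effects, an order of magnitude below the
  study offsets, matching their relative FEV magnitudes.
- Platform is a per-study label (studies alternate HM450K/EPIC) plus a
  10% probe block exclusive to the EPIC platform; HM450K samples carry
  NaN there and `SyntheticDataset.shared_beta()` mirrors the
  merge-on-shared-probes step all analyses start from.
- Metadata cell fractions are the true mixing weights plus N(0, 0.01)
  estimation noise, un-renormalized: the recorded fields emulate
  deconvolution *predictions*. (Exact weights sum to 1 and would make the
  sixth fraction a linear combination of the intercept and the other
  five; predictions do not.) The exact weights remain in
  `truth.cell_fractions`.
- Sample types are drawn per sample (not per study). Real studies are
  more type-homogeneous; drawing per sample keeps sample type
  identifiable alongside study ID in a single model, which is what the
  variance analyses need.
- QC metrics are generated directly (signal medians ~N(11.5, 0.7), a
  1.5% low-signal contingent at ~N(9.3, 0.4), a 1% BeadArray-failure
  contingent): the five BeadArray metrics are defined on raw two-channel
  intensities, which the generator deliberately does not simulate.

What the generator does **not** emulate: probe-level spatial/chemistry
artifacts, type-I/type-II probe design differences, raw-intensity
normalization, per-study sample-size skew, correlated probe blocks, and
nucleated red blood cells in cord blood. Tests passing on this generator
therefore validate the statistical machinery — estimators recover planted
truth under the stated model — not robustness to every artifact of real
arrays.

## QC filters

Removal rules: (i) both log2 median methylated and unmethylated signal
< 10; (ii) ≥ 2 of 5 BeadArray metric failures; (iii) PBMC with estimated
granulocyte fraction ≥ 0.25 (inclusive). Reason codes distinguish the
rules; samples with missing metrics are excluded with a `missing` code.
The granulocyte cutoff is a parameter rather than a recomputed quantile:
the published value came from the 93rd percentile of a specific
compilation's distribution, which is data-dependent.

## Deconvolution

Constrained least squares min‖b − Rw‖², w ≥ 0, Σw ≤ 1, solved by SLSQP
followed by an active-set polish (exact least squares on the detected
support, accepted when feasible), giving answers at 1e-6-level accuracy
on noiseless mixtures. The Σw ≤ 1 convention (rather than Σw = 1) follows
the constrained-projection formulation of reference-based blood
deconvolution; 1 − Σw is reported as unexplained mass, and fractions are
not renormalized. A rank-deficient reference raises an error naming the
collinear columns. Duplicating every probe leaves the solution unchanged
(the objective scales by a constant).

## Study-bias adjustment

Per probe, M ~ intercept + covariates + batch, with the batch factor in
sum-to-zero coding and all probes fit in one least-squares pass; only the
fitted batch term is subtracted. With sum-to-zero coding the unweighted
mean of level effects is zero, so the grand mean is preserved exactly in
balanced designs and the unweighted level-mean in unbalanced ones —
matching the behavior of the standard linear batch-removal routine.
Perfect confounding between batch and a preserved covariate raises an
error naming the pair. The operation is a linear projection, hence
idempotent (verified to 1e-10).

Two strategies are exposed:

- `all_batches`: every study label is a batch level (used for "uniform
  adjustment" across the drawn studies).
- `subset_batches`: only listed studies are distinct levels; the rest
  collapse into one pooled reference level. Offsets *among* pooled
  studies survive by construction.

**Design choice (adjustment 2 in the bias simulation).** The phrase
"exact adjustment on 2–4 randomly selected studies" admits two readings:
(a) subset-coded batch levels against a pooled reference, or (b)
restricting the analysis to the 2–4 drawn studies and adjusting fully
there. Under (a) the pooled studies' mutual offsets survive, so the study
FEV can only drop a few-fold — which contradicts the observed behavior
that either strategy collapses study FEV by orders of magnitude with
near-identical variance reductions. The simulation therefore implements
(b); interpretation (a) remains available as
`AdjustmentSpec(strategy="subset_batches")` for comparison experiments.

## Variance partitioning

Sequential (type-I) ANOVA with fixed order technical → demographic →
biological: platform, study, then age, sex, two ancestry scores, then
sample type and six cell fractions. Age and ancestry enter linearly; sex,
platform, study and sample type as factors. Entering study early is
conservative for any claim about how much variance the study label
explains (it absorbs shared variance first). The decomposition is
computed by incremental orthogonalization (two-pass Gram–Schmidt against
the accumulated basis, SVD rank decision at relative tolerance 1e-8),
which evaluates per-probe FEV for hundreds of probes as a single pass of
matrix products. FEV + residual sums to 1 by construction; tiny negative
rounding is clipped.

Degenerate designs: a variable constant in the analyzed subset
contributes FEV 0 (it lies in the intercept span — common when the
simulation subsamples studies); a non-constant variable fully aliased
with earlier ones raises by default, but callers can request
`on_aliased="zero"`, the natural convention for nested factors (e.g.
study within platform when only two studies are drawn). The bias
simulation uses that convention. In the per-probe DMP regressions the
analogous situation (platform nested in study) is handled by lm-style
left-to-right alias dropping; the sex contrast is never droppable.

The bias simulation draws 500 probes and 5 studies per repetition
(without replacement; studies with < 2 samples are re-drawn with a
warning), computes the three model variants, aggregates FEV per variable
as the median across probes, and summarizes across repetitions by the
median again. Non-residual variance ratios are medians of per-probe
ratios, with each adjusted model compared against the unadjusted model
fit on the same samples.

PCA of hashed profiles uses a centered SVD; constant hashed columns are
dropped with a warning; per-component FEV applies the same sequential
ANOVA to the component scores, and category sums aggregate
member-variable FEVs.

## Feature hashing and search

Bucket(p) = murmur3_32(probe_id, seed) mod dim; sign(p) from one bit of
an independently seeded hash. The signed variant makes hashed inner
products unbiased estimators of probe-space inner products; dim = 1000 by
default. The murmur3 implementation is verified against the published
test vector ("hello", 0) → 0x248bfa47, and hashing parameters are stored
as HDF5 attributes so that indexes are reproducible and query/index
parameter mismatches are detectable (they raise, by design).

The kNN index performs exact search (scikit-learn brute-force backend)
under euclidean (default) or cosine distance; small-world graph
parameters (M = 16, construction beam 200, query beam 300) are accepted
and persisted for configuration portability. An independent quadratic-
scan oracle with deterministic tie-breaking (ascending distance, then
lexicographic sample id) backs the recall tests; with an exact backend
the recall contract (≥ 0.9 recall@10) holds with recall 1 up to
tie-ordering.

## Power simulation

Per (N, δ) grid point and simulation: two groups of ⌊N/2⌋/⌈N/2⌉ samples;
500 target probes drawn without replacement; per target a shift
~N(δ, τ²) (τ = 0.01) with random sign, re-drawn while the shifted mean
leaves (0, 1); Beta-distributed draws per probe matched to the reference
(mean, variance) by moments, variances clipped into the feasible region
v < m(1−m); Welch's t per probe on M-values (zero-variance probes get
p = 1); BH at FDR 5%; marginal power = discovered detectable targets /
detectable targets, a target being detectable when its |shift| exceeds
the technical detection limit 0.01. Power is undefined (NaN) when no
target is detectable. The reference distribution is estimated from a
compilation's per-probe empirical means and population variances
(ddof = 0, documented convention).

The minimum-N search returns the smallest grid N with mean power ≥ 80%
and, separately, a linear interpolation between the bracketing grid
points. Published absolute minimum-N values depend on the reference
tissue's dispersion profile, so only orderings (smaller δ needs more
samples) and monotonicity in N are asserted; the acceptance script
reports the grid values computed for its synthetic whole-blood reference
(grid 50–400 in steps of 50, 20 simulations per point — sizes chosen so
the full grid completes in well under a minute while Monte-Carlo SEs stay
small relative to the 80% threshold crossings).

## Sex-DMP replication

Per probe OLS of M on sex (male = 1) + six cell fractions + age +
platform + study + optional surrogate variables; two-sided t p-values for
the sex coefficient; Bonferroni adjustment by default with BH available.
Surrogate variables are the top left singular vectors of the M matrix
residualized against the known design — a deliberately simple stand-in
for full surrogate-variable analysis (no iterative reweighting), with
k = 2 by default; k = 0 disables them.

Top-k selection ranks by ascending p, ties by |effect| descending then
probe id. Concordance at the top is the cumulative overlap of the ranked
list with the discovery set. The replication summary partitions discovery
probes into only-tissue-1 / only-tissue-2 / both; the integer percent is
truncated (112/292 → 38) to match the printed-rate convention, with the
exact fraction alongside. Direction agreement is computed over
(replicated probe, tissue) pairs with signs available in both the
compilation result and the discovery set. Island proximity counts
island + shore relations by default.

The cell-fraction sex comparison is a Welch t-test per cell type with BH
adjustment across the six tests, reporting signed male − female mean
differences.

## Problem sizes in the test and acceptance runs

Synthetic compilations of 300–20,000 probes and 120–400 samples; the
bias simulation at 500 probes × 5 studies × 20 repetitions; power grids
of 8 N-values × 3 δ-values × 20 simulations; the end-to-end DMP check on
a 2-study, 2-platform compilation of 20,000 probes × 400 samples with 300
planted DMPs. These sizes keep the whole suite under a minute while
leaving Monte-Carlo error far from every asserted margin.

## Known limitations

- The exact-search backend makes index build O(1) and queries O(n·dim);
  for compilations of ~10^4 samples this is entirely adequate, but the
  module does not provide sublinear approximate search.
- Surrogate variables are a residual-SVD approximation, not full SVA.
- The power model treats probes independently; correlated probe blocks
  would widen the Monte-Carlo spread of realized FDR and power.
- Deconvolution assumes the reference panel's cell types span the
  sample's composition; unmodeled cell types load onto the unexplained
  mass 1 − Σw.
- Absolute power/minimum-N numbers are functions of the chosen reference
  distribution and transfer to real compilations only insofar as the
  dispersion profile matches.
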