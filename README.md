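# crossmeth

Cross-study analysis of blood DNA methylation (DNAm) array data, for
epigenomics researchers who work with multi-study HM450K/EPIC
compilations: planning sample sizes for an EWAS, correcting study-level
batch bias before pooling public samples, searching a compilation for
samples that resemble a query profile, and independently validating
published differentially methylated probes (DMPs).

Public blood DNAm compilations pool thousands of samples from dozens of
GEO studies and two array platforms. Before they can answer biological
questions, several entangled problems must be handled: per-sample and
per-probe quality control, cell-composition heterogeneity, and strong
study-level technical bias. `crossmeth` implements that full stack as a
tested library plus CLI, together with a synthetic-compilation generator
that plants known effects so every stage can be validated against ground
truth.

## What it computes

**Beta/M scales.** A probe's Beta-value is the methylated fraction
β = M/(M+U) ∈ [0, 1]; linear modeling uses the M-value
m = log2(β/(1−β)). Effects in the synthetic generator are additive on the
logit scale and mapped back, so the generated data match the modeling
assumptions downstream.

**QC.** A sample is removed when its log2 median methylated and
unmethylated signals are both < 10, or when it fails ≥ 2 of 5 BeadArray
quality metrics; PBMC samples with estimated granulocyte fraction ≥ 0.25
are removed (granulocytes are depleted during PBMC preparation). Probe
filters drop sex-chromosome, cross-reactive and (optionally)
SNP-overlapping probes.

**Cell-type deconvolution.** Per sample, the six leukocyte fractions
w (CD4T, CD8T, NK, B cell, monocyte, granulocyte) solve the constrained
least squares min‖b − Rw‖² s.t. w ≥ 0, Σw ≤ 1 over a reference panel R of
cell-type mean profiles; 1 − Σw is reported as unexplained mass.

**Study-bias adjustment.** Per probe, M-values are regressed jointly on
the covariates to preserve and sum-to-zero-coded study indicators; the
fitted study term is subtracted (the linear removeBatchEffect model).

**Variance partitioning (FEV).** The fraction of explained variance of
each of 13 variables — technical (platform, study), demographic (age,
sex, two genetic-ancestry scores), biological (sample type, six cell
fractions) — is FEV_v = SS_v/SS_total from a sequential (type-I) ANOVA
with technical variables entered first. A simulation repeatedly draws
500 probes and 5 studies, applies two adjustment strategies, and compares
the three models' FEV distributions and non-residual variance ratios.

**Feature hashing + sample search.** Probe vectors are reduced to a fixed
dimension by the hashing trick (seeded murmur3 bucket + sign hashes, so
inner products are preserved in expectation), then indexed for k-nearest-
neighbor search with an exact brute-force oracle and neighbor-label
profiling.

**EWAS power.** Two-group simulations draw Beta-distributed samples from
a per-probe (mean, dispersion) reference, plant ~500 DMPs with target
mean difference δ, test per probe with Welch's t on M-values, control FDR
with Benjamini–Hochberg at 5%, and report marginal power versus total
sample size N, plus the minimal N reaching 80% power per δ.

**DMP replication.** Sex DMPs are called per probe by OLS of M-values on
sex + cell fractions + age + platform + study (+ optional surrogate
variables from the residual SVD); replication against a discovery set is
summarized by concordance-at-the-top curves, a two-tissue partition with
truncated integer percent, direction agreement of effect signs, and
CpG-island proximity.

## Worked example

```python
import warnings
import numpy as np
from crossmeth.synth import (GeneratorConfig, generate_reference_profiles,
                             generate_dataset)
from crossmeth.variance_fev import run_bias_simulation
from crossmeth.preprocess import deconvolve_cell_fractions

reference = generate_reference_profiles(n_probes=600, seed=1)
config = GeneratorConfig(n_probes=600, n_studies=8, samples_per_study=40,
                         n_sex_dmps=60, seed=1)
dataset = generate_dataset(config, reference)

sim = run_bias_simulation(dataset, n_probes=200, n_studies=5,
                          n_reps=10, seed=2)
summary = sim.summary()
print(summary.loc[["study_id", "platform", "sex", "CD4T", "residual"]].round(4))
print("median non-residual variance ratios:",
      {k: round(v, 3) for k, v in sim.median_nonresidual_ratio().items()})
```

prints

```
          unadjusted  adjustment1  adjustment2
study_id      0.2086       0.0014       0.0011
platform      0.0423       0.0003       0.0006
sex           0.0022       0.0033       0.0051
CD4T          0.0017       0.0025       0.0043
residual      0.5807       0.8986       0.8542

median non-residual variance ratios: {'adjustment1': 0.289, 'adjustment2': 0.473}
```

Reading: on this synthetic compilation the study label is the dominant
explained-variance source before correction (median FEV 0.21); after
either adjustment strategy its median FEV collapses by two orders of
magnitude while the biological and demographic variables' FEV increases
(e.g. sex 0.0022 → 0.0033/0.0051), and the non-residual variance ratio is
below 1 because the adjustment removes study-driven variance.

Deconvolving a noisy 60%-granulocyte mixture on the reference's
discriminating probes:

```python
disc = reference.discriminating_subset()
w_true = np.array([0.15, 0.08, 0.05, 0.05, 0.07, 0.60])
b = disc.profiles @ w_true \
    + np.random.default_rng(3).normal(0, 0.02, disc.n_probes)
print(deconvolve_cell_fractions(np.clip(b, 0, 1), disc).round(3).to_string(index=False))
```

```
 CD4T  CD8T    NK  Bcell  Mono  Gran
0.143 0.091 0.045  0.056 0.059 0.602
```

The CLI runs the full pipeline from a YAML config
(`crossmeth run --config pipeline.yaml`) and exposes per-stage
subcommands (`synth`, `qc`, `adjust`, `index build|query`, `power`,
`dmp call|replicate`, `report`); every run writes a manifest with sha256
checksums of all outputs.

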