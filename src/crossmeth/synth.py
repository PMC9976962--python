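"""Synthetic blood methylation compilations with full ground truth.

Emulates the structure of multi-study HM450K/EPIC blood compilations:
several studies with additive study offsets on the logit (M-value) scale,
two platforms sharing most probes, three named blood sample types plus an
"other" class, six-cell-type composition mixtures, sex/age/ancestry-driven
methylation effects, planted sex DMPs, and per-sample QC metrics.

All effects are additive on the logit scale and mapped back through the
inverse logit, so downstream linear modeling of M-values matches the
generating process. Beta-values are clamped to [1e-6, 1 - 1e-6] to keep
the logit finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    BetaMatrix,
    CELL_TYPES,
    CHROMOSOMES,
    SAMPLE_TYPES,
    validate_annotation,
    validate_metadata,
)
from . import io as cmio

_CLAMP = 1e-6


def _logit(b: np.ndarray) -> np.ndarray:
    b = np.clip(b, _CLAMP, 1.0 - _CLAMP)
    return np.log(b / (1.0 - b))


def _inv_logit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class CellTypeReference:
    """Reference mean Beta profiles for the six blood leukocyte types.

    A designated subset of probes discriminates the types: at each
    discriminating probe one cell type has a reference mean separated from
    every other type by a wide gap, which makes constrained-least-squares
    deconvolution identifiable.
    """

    probe_ids: np.ndarray
    profiles: np.ndarray  # probes x 6, Beta means in [0, 1]
    cell_names: tuple[str, ...] = CELL_TYPES
    discriminating_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.profiles = np.asarray(self.profiles, dtype=float)
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("duplicate probe ids in reference")
        if self.profiles.shape != (len(self.probe_ids), 6):
            raise ValueError("profiles must be n_probes x 6")
        if self.profiles.min() < 0 or self.profiles.max() > 1:
            raise ValueError("reference means must lie in [0, 1]")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def discriminating_subset(self) -> "CellTypeReference":
        idx = pd.Index(self.probe_ids).get_indexer(self.discriminating_ids)
        return CellTypeReference(self.discriminating_ids, self.profiles[idx],
                                 self.cell_names, self.discriminating_ids)


def generate_reference_profiles(n_probes: int, seed: int,
                                n_discriminating_per_type: int | None = None
                                ) -> CellTypeReference:
    """Build a deterministic six-cell-type reference panel.

    Discriminating probes are allocated evenly across the types; at each,
    the target type's mean is drawn from U(0.75, 0.95) and the remaining
    types from U(0.05, 0.35), guaranteeing a gap >= 0.4. Non-discriminating
    probes share a common mean with small per-type jitter.
    """
    if n_probes < 6:
        raise ValueError("n_probes must be >= 6 (one probe per cell type)")
    rng = np.random.default_rng(seed)
    if n_discriminating_per_type is None:
        n_discriminating_per_type = max(1, n_probes // 40)
    n_disc = 6 * n_discriminating_per_type
    if n_disc > n_probes:
        raise ValueError("too many discriminating probes for n_probes")

    probe_ids = np.array([f"cg{i:08d}" for i in range(n_probes)], dtype=object)
    base = rng.uniform(0.05, 0.95, size=n_probes)
    profiles = np.clip(base[:, None] + rng.normal(0, 0.03, size=(n_probes, 6)),
                       0.01, 0.99)
    for c in range(6):
        rows = np.arange(c * n_discriminating_per_type,
                         (c + 1) * n_discriminating_per_type)
        profiles[rows, :] = rng.uniform(0.05, 0.35, size=(len(rows), 6))
        profiles[rows, c] = rng.uniform(0.75, 0.95, size=len(rows))
    return CellTypeReference(probe_ids, profiles, CELL_TYPES,
                             discriminating_ids=probe_ids[:n_disc])


# Dirichlet concentrations per sample type over (CD4T, CD8T, NK, Bcell,
# Mono, Gran). Whole blood and cord blood are granulocyte-dominant; the
# PBMC granulocyte fraction is handled separately (removed during PBMC
# preparation, so near zero with an occasional contaminated tail).
DEFAULT_DIRICHLET_ALPHA: dict[str, tuple[float, ...]] = {
    "whole_blood": (4.5, 2.4, 1.5, 1.5, 2.4, 18.0),
    "cord_blood": (4.0, 2.0, 2.0, 2.0, 2.0, 15.0),
    "pbmc": (12.0, 7.0, 4.0, 4.0, 5.0, 0.0),  # Gran slot ignored, see tail
    "other": (5.0, 3.0, 2.0, 2.0, 3.0, 10.0),
}

DEFAULT_SAMPLE_TYPE_PROPS: dict[str, float] = {
    "whole_blood": 0.55, "cord_blood": 0.15, "pbmc": 0.20, "other": 0.10,
}


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic compilation generator.

    Scales are logit (M-value-like) unless stated otherwise;
    ``sex_effect_delta`` is a Beta-scale group mean difference.
    """

    n_probes: int = 2000
    n_studies: int = 8
    samples_per_study: int = 40
    study_offset_sd: float = 0.5
    shared_probe_fraction: float = 0.9
    sample_type_props: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SAMPLE_TYPE_PROPS))
    dirichlet_alpha: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_DIRICHLET_ALPHA))
    n_sex_dmps: int = 50
    sex_effect_delta: float = 0.1
    age_slope_sd: float = 0.002
    ancestry_loading_sd: float = 0.05
    noise_sd: float = 0.6
    fraction_noise_sd: float = 0.01
    pbmc_gran_tail_prob: float = 0.15
    qc_signal_fail_rate: float = 0.015
    qc_beadarray_fail_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_probes", "n_studies", "samples_per_study"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_sex_dmps and not 0 < self.sex_effect_delta < 1:
            raise ValueError("sex_effect_delta must lie in (0, 1)")
        total = sum(self.sample_type_props.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("sample_type proportions must sum to 1")
        if set(self.sample_type_props) - set(SAMPLE_TYPES):
            raise ValueError("unknown sample type in proportions")
        if not 0 < self.shared_probe_fraction <= 1:
            raise ValueError("shared_probe_fraction must lie in (0, 1]")
        for sd in (self.study_offset_sd, self.age_slope_sd,
                   self.ancestry_loading_sd, self.noise_sd):
            if sd < 0:
                raise ValueError("scale parameters must be non-negative")


@dataclass
class TruthInfo:
    """Ground truth planted by the generator."""

    dmp_probe_ids: np.ndarray          # planted sex DMPs
    dmp_deltas: np.ndarray             # signed Beta-scale male - female shifts
    cell_fractions: pd.DataFrame       # samples x 6 true mixing weights
    study_offsets: pd.DataFrame        # probes x studies logit offsets


@dataclass
class SyntheticDataset:
    """A generated compilation: Beta matrix + metadata + annotation + truth."""

    beta: BetaMatrix
    metadata: pd.DataFrame             # indexed by sample_id
    annotation: pd.DataFrame           # indexed by probe_id
    qc: pd.DataFrame                   # per-sample QC metrics
    truth: TruthInfo

    def __post_init__(self) -> None:
        if list(self.metadata.index) != list(self.beta.sample_ids):
            raise ValueError("metadata index must match beta sample ids")
        if list(self.annotation.index) != list(self.beta.probe_ids):
            raise ValueError("annotation index must match beta probe ids")
        unknown = set(self.truth.dmp_probe_ids) - set(self.beta.probe_ids)
        if unknown:
            raise ValueError("truth DMP ids must be a subset of probe ids")
        validate_metadata(self.metadata)
        validate_annotation(self.annotation)

    def shared_beta(self) -> BetaMatrix:
        """Subset to platform-shared probes (drops the EPIC-only block)."""
        shared = self.annotation.index[~self.annotation["epic_only"]]
        return self.beta.subset_probes(np.asarray(shared, dtype=object))


def _draw_cell_fractions(rng, sample_types: np.ndarray,
                         alphas: dict, tail_prob: float) -> np.ndarray:
    n = len(sample_types)
    W = np.empty((n, 6))
    for st in np.unique(sample_types):
        mask = sample_types == st
        m = int(mask.sum())
        if st == "pbmc":
            # PBMC preparation removes granulocytes: Gran near zero with a
            # configurable heavy contamination tail.
            gran = rng.beta(1.0, 60.0, size=m)
            tail = rng.random(m) < tail_prob
            gran[tail] = rng.uniform(0.05, 0.45, size=int(tail.sum()))
            alpha5 = np.asarray(alphas[st][:5], dtype=float)
            mono5 = rng.dirichlet(alpha5, size=m)
            W[mask, :5] = mono5 * (1.0 - gran)[:, None]
            W[mask, 5] = gran
        else:
            W[mask] = rng.dirichlet(np.asarray(alphas[st], dtype=float), size=m)
    return W


def _annotate_probes(rng, probe_ids: np.ndarray, shared_fraction: float
                     ) -> pd.DataFrame:
    n = len(probe_ids)
    chrom_p = np.full(24, 0.94 / 22)
    chrom_p[22] = 0.04   # chrX
    chrom_p[23] = 0.02   # chrY
    chromosome = rng.choice(np.asarray(CHROMOSOMES, dtype=object), size=n, p=chrom_p)
    island = rng.choice(np.asarray(["island", "shore", "shelf", "open_sea"],
                                   dtype=object),
                        size=n, p=[0.30, 0.25, 0.15, 0.30])
    cross = rng.random(n) < 0.05
    snp = rng.random(n) < 0.05
    epic_only = np.zeros(n, dtype=bool)
    n_excl = int(round((1.0 - shared_fraction) * n))
    if n_excl:
        epic_only[rng.choice(n, size=n_excl, replace=False)] = True
    return pd.DataFrame(
        {"chromosome": chromosome, "island_relation": island,
         "cross_reactive": cross, "snp_overlap": snp, "epic_only": epic_only},
        index=pd.Index(probe_ids, name="probe_id"))


def generate_dataset(config: GeneratorConfig,
                     reference: CellTypeReference) -> SyntheticDataset:
    """Generate a full synthetic compilation from a cell-type reference.

    Per sample, Beta = inv_logit( logit(mixture of reference profiles by
    Dirichlet cell fractions, with the sex shift applied at planted DMPs)
    + study offset + age*slope + ancestry*loading + Gaussian noise ),
    clamped to (0, 1). The sex shift is specified on the Beta scale and
    converted to the equivalent logit shift probe by probe.
    """
    if reference.n_probes != config.n_probes:
        raise ValueError("reference probe count must equal config.n_probes")
    rng = np.random.default_rng(config.seed)
    n_probes = config.n_probes
    n_samples = config.n_studies * config.samples_per_study

    probe_ids = reference.probe_ids
    sample_ids = np.array([f"s{i:05d}" for i in range(n_samples)], dtype=object)
    study_ids = np.array([f"study{j:02d}" for j in range(config.n_studies)],
                         dtype=object)
    study_of = np.repeat(np.arange(config.n_studies), config.samples_per_study)
    platform_of_study = np.array(
        ["hm450k" if j % 2 == 0 else "epic" for j in range(config.n_studies)],
        dtype=object)

    # covariates
    type_names = np.asarray(list(config.sample_type_props), dtype=object)
    type_p = np.asarray(list(config.sample_type_props.values()))
    sample_type = rng.choice(type_names, size=n_samples, p=type_p)
    sex = rng.choice(np.asarray(["female", "male"], dtype=object), size=n_samples)
    age = np.clip(rng.normal(40.0, 15.0, size=n_samples), 1.0, 90.0)
    age[sample_type == "cord_blood"] = 0.0
    pc1 = rng.normal(0.0, 1.0, size=n_samples)
    pc2 = rng.normal(0.0, 1.0, size=n_samples)
    W = _draw_cell_fractions(rng, sample_type, config.dirichlet_alpha,
                             config.pbmc_gran_tail_prob)

    annotation = _annotate_probes(rng, probe_ids, config.shared_probe_fraction)

    # planted sex DMPs: autosomal, shared, unflagged probes only, so the
    # standard probe filters never discard the planted signal
    eligible = annotation.index[
        (~annotation["chromosome"].isin(["chrX", "chrY"]))
        & ~annotation["cross_reactive"] & ~annotation["snp_overlap"]
        & ~annotation["epic_only"]].to_numpy(dtype=object)
    if config.n_sex_dmps > len(eligible):
        raise ValueError("n_sex_dmps exceeds eligible autosomal shared probes")
    dmp_ids = rng.choice(eligible, size=config.n_sex_dmps, replace=False)
    dmp_idx = pd.Index(probe_ids).get_indexer(dmp_ids)
    dmp_sign = rng.choice([-1.0, 1.0], size=config.n_sex_dmps)
    dmp_delta = dmp_sign * config.sex_effect_delta   # male - female, Beta scale

    # per-probe effect loadings
    offsets = rng.normal(0.0, config.study_offset_sd,
                         size=(n_probes, config.n_studies))
    age_slope = rng.normal(0.0, config.age_slope_sd, size=n_probes)
    load1 = rng.normal(0.0, config.ancestry_loading_sd, size=n_probes)
    load2 = rng.normal(0.0, config.ancestry_loading_sd, size=n_probes)

    # base mixture and sex shift on the Beta scale
    B0 = reference.profiles @ W.T                     # probes x samples
    is_male = (sex == "male").astype(float)
    half = np.clip(dmp_delta, -1, 1)[:, None] / 2.0
    B0[dmp_idx, :] = np.clip(
        B0[dmp_idx, :] + half * np.where(is_male[None, :] > 0, 1.0, -1.0),
        _CLAMP, 1.0 - _CLAMP)

    L = _logit(B0)
    L += offsets[:, study_of]
    L += age_slope[:, None] * (age - 40.0)[None, :]
    L += load1[:, None] * pc1[None, :] + load2[:, None] * pc2[None, :]
    if config.noise_sd > 0:
        L += rng.normal(0.0, config.noise_sd, size=L.shape)
    beta_values = np.clip(_inv_logit(L), _CLAMP, 1.0 - _CLAMP)

    # platform-exclusive probes are missing on the HM450K platform
    platform = platform_of_study[study_of]
    epic_only_mask = annotation["epic_only"].to_numpy()
    if epic_only_mask.any():
        beta_values[np.ix_(epic_only_mask, platform == "hm450k")] = np.nan

    # recorded fractions emulate deconvolution *predictions*: the true
    # mixing weights plus small estimation error, not renormalized (so the
    # six columns are not exactly collinear, as in real predicted fractions)
    W_pred = np.clip(
        W + rng.normal(0.0, config.fraction_noise_sd, size=W.shape), 0.0, 1.0)
    metadata = pd.DataFrame(
        {"study_id": study_ids[study_of], "platform": platform,
         "sample_type": sample_type, "sex": sex, "age": age,
         "ancestry_pc1": pc1, "ancestry_pc2": pc2,
         **{ct: W_pred[:, k] for k, ct in enumerate(CELL_TYPES)}},
        index=pd.Index(sample_ids, name="sample_id"))

    # per-sample QC metrics (signal medians and BeadArray failure counts)
    m_sig = rng.normal(11.5, 0.7, size=n_samples)
    u_sig = rng.normal(11.5, 0.7, size=n_samples)
    bad_signal = rng.random(n_samples) < config.qc_signal_fail_rate
    m_sig[bad_signal] = rng.normal(9.3, 0.4, size=int(bad_signal.sum()))
    u_sig[bad_signal] = rng.normal(9.3, 0.4, size=int(bad_signal.sum()))
    failures = (rng.random((n_samples, 5)) < 0.01).sum(axis=1)
    bad_bead = rng.random(n_samples) < config.qc_beadarray_fail_rate
    failures[bad_bead] = rng.integers(2, 6, size=int(bad_bead.sum()))
    qc = pd.DataFrame(
        {"log2_median_M": m_sig, "log2_median_U": u_sig,
         "beadarray_failures": failures},
        index=pd.Index(sample_ids, name="sample_id"))

    truth = TruthInfo(
        dmp_probe_ids=np.asarray(dmp_ids, dtype=object),
        dmp_deltas=dmp_delta,
        cell_fractions=pd.DataFrame(W, index=metadata.index,
                                    columns=list(CELL_TYPES)),
        study_offsets=pd.DataFrame(offsets,
                                   index=pd.Index(probe_ids, name="probe_id"),
                                   columns=study_ids))
    beta = BetaMatrix(beta_values, probe_ids, sample_ids)
    return SyntheticDataset(beta, metadata, annotation, qc, truth)


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, str]:
    """Write a dataset to ``outdir``: HDF5 Beta matrix plus TSV tables."""
    out = cmio.ensure_dir(outdir)
    paths = {
        "beta": str(out / "beta.h5"),
        "metadata": str(out / "metadata.tsv"),
        "annotation": str(out / "annotation.tsv"),
        "qc": str(out / "qc.tsv"),
        "truth_dmps": str(out / "truth_dmps.tsv"),
        "truth_fractions": str(out / "truth_cell_fractions.tsv"),
        "truth_offsets": str(out / "truth_study_offsets.tsv"),
    }
    cmio.write_beta_h5(paths["beta"], dataset.beta)
    cmio.write_table(paths["metadata"], dataset.metadata, "sample_id")
    cmio.write_table(paths["annotation"], dataset.annotation, "probe_id")
    cmio.write_table(paths["qc"], dataset.qc, "sample_id")
    dmps = pd.DataFrame({"delta": dataset.truth.dmp_deltas},
                        index=pd.Index(dataset.truth.dmp_probe_ids,
                                       name="probe_id"))
    cmio.write_table(paths["truth_dmps"], dmps, "probe_id")
    cmio.write_table(paths["truth_fractions"], dataset.truth.cell_fractions,
                     "sample_id")
    cmio.write_table(paths["truth_offsets"], dataset.truth.study_offsets,
                     "probe_id")
    return paths


def read_dataset(indir) -> SyntheticDataset:
    """Round-trip reader for :func:`write_dataset` output."""
    from pathlib import Path
    p = Path(indir)
    beta = cmio.read_beta_h5(p / "beta.h5")
    metadata = cmio.read_table(p / "metadata.tsv")
    annotation = cmio.read_table(p / "annotation.tsv")
    qc = cmio.read_table(p / "qc.tsv")
    dmps = cmio.read_table(p / "truth_dmps.tsv")
    fractions = cmio.read_table(p / "truth_cell_fractions.tsv")
    offsets = cmio.read_table(p / "truth_offsets.tsv"
                              if (p / "truth_offsets.tsv").exists()
                              else p / "truth_study_offsets.tsv")
    truth = TruthInfo(dmps.index.to_numpy(dtype=object),
                      dmps["delta"].to_numpy(), fractions, offsets)
    annotation.index = annotation.index.astype(object)
    metadata.index = metadata.index.astype(object)
    return SyntheticDataset(beta, metadata, annotation, qc, truth)
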