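"""Core in-memory containers shared across the pipeline.

The universal currency is a probes-by-samples matrix of Beta-values
(methylation fractions in [0, 1]) or M-values (logit2-scale methylation),
paired with a sample-metadata table and a probe-annotation table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: the six deconvoluted leukocyte types, in canonical column order
CELL_TYPES = ("CD4T", "CD8T", "NK", "Bcell", "Mono", "Gran")

#: controlled vocabulary for harmonized blood sample types
SAMPLE_TYPES = ("whole_blood", "cord_blood", "pbmc", "other")

#: array platforms
PLATFORMS = ("hm450k", "epic")

#: chromosome vocabulary for probe annotation
CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX", "chrY")

#: the 13 modeling variables, grouped the way the variance analyses group them
VARIABLE_CATEGORIES: dict[str, str] = {
    "platform": "technical",
    "study_id": "technical",
    "age": "demographic",
    "sex": "demographic",
    "ancestry_pc1": "demographic",
    "ancestry_pc2": "demographic",
    "sample_type": "biological",
    **{ct: "biological" for ct in CELL_TYPES},
}

#: fixed modeling order: technical, then demographic, then biological
MODEL_VARIABLES = tuple(VARIABLE_CATEGORIES)

#: variables treated as categorical factors in linear models
CATEGORICAL_VARIABLES = frozenset({"platform", "study_id", "sex", "sample_type"})


def _check_ids(ids: np.ndarray, what: str) -> np.ndarray:
    ids = np.asarray(ids, dtype=object)
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} ids")
    return ids


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation fractions in [0, 1].

    NaN entries are allowed only to mark probes absent from a sample's
    platform; all analysis stages operate on the platform-shared subset.
    """

    values: np.ndarray
    probe_ids: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.probe_ids = _check_ids(self.probe_ids, "probe")
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("Beta-values must lie in [0, 1]")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        idx = pd.Index(self.probe_ids).get_indexer(probe_ids)
        if (idx < 0).any():
            missing = np.asarray(probe_ids)[idx < 0][:5]
            raise KeyError(f"unknown probe ids, e.g. {list(missing)}")
        return BetaMatrix(self.values[idx], np.asarray(probe_ids, dtype=object),
                          self.sample_ids.copy())

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        idx = pd.Index(self.sample_ids).get_indexer(sample_ids)
        if (idx < 0).any():
            missing = np.asarray(sample_ids)[idx < 0][:5]
            raise KeyError(f"unknown sample ids, e.g. {list(missing)}")
        return BetaMatrix(self.values[:, idx], self.probe_ids.copy(),
                          np.asarray(sample_ids, dtype=object))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids,
                            columns=self.sample_ids)


@dataclass
class MValueMatrix:
    """Probes x samples matrix of M-values, M = log2(beta / (1 - beta))."""

    values: np.ndarray
    probe_ids: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.probe_ids = _check_ids(self.probe_ids, "probe")
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError("values shape inconsistent with ids")
        if not np.isfinite(self.values).all():
            raise ValueError("M-values must be finite")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Check a sample-metadata table carries the 13 modeling variables.

    Expected columns: study_id, platform, sample_type, sex, age,
    ancestry_pc1, ancestry_pc2 and the six cell-fraction columns.
    """
    required = ["study_id", "platform", "sample_type", "sex", "age",
                "ancestry_pc1", "ancestry_pc2", *CELL_TYPES]
    missing = [c for c in required if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    bad_platform = set(metadata["platform"]) - set(PLATFORMS)
    if bad_platform:
        raise ValueError(f"unknown platform labels: {sorted(bad_platform)}")
    bad_type = set(metadata["sample_type"]) - set(SAMPLE_TYPES)
    if bad_type:
        raise ValueError(f"unknown sample_type labels: {sorted(bad_type)}")
    return metadata


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Check a probe-annotation table (chromosome, island relation, flags)."""
    required = ["chromosome", "island_relation", "cross_reactive", "snp_overlap"]
    missing = [c for c in required if c not in annotation.columns]
    if missing:
        raise ValueError(f"annotation missing columns: {missing}")
    bad_chrom = set(annotation["chromosome"]) - set(CHROMOSOMES)
    if bad_chrom:
        raise ValueError(f"unknown chromosome labels: {sorted(bad_chrom)}")
    return annotation
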