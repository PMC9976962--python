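"""Removal of additive study-ID effects from M-values.

Per probe, M-values are jointly regressed on the covariates to preserve
and on sum-to-zero-coded study indicators; only the fitted study term is
subtracted, so covariate-driven variation survives the adjustment and the
(unweighted) grand mean is untouched.

Two strategies mirror the two compilation adjustment modes:

- ``all_batches``: every study label in the data is a distinct batch level.
- ``subset_batches``: only the listed studies are distinct batch levels;
  all remaining studies collapse into a single reference level before
  coding, so only the listed studies' offsets are estimated and removed
  relative to that pooled reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._design import sum_to_zero_batch, variable_block
from .containers import MValueMatrix

#: the 11 non-technical modeling variables, preserved by default
DEFAULT_PRESERVE = ("sample_type", "sex", "age", "ancestry_pc1", "ancestry_pc2",
                    "CD4T", "CD8T", "NK", "Bcell", "Mono", "Gran")


@dataclass
class AdjustmentSpec:
    """Configuration of one study-bias adjustment."""

    batch_variable: str = "study_id"
    covariates_to_preserve: tuple[str, ...] = DEFAULT_PRESERVE
    strategy: str = "all_batches"
    subset: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.strategy not in ("all_batches", "subset_batches"):
            raise ValueError(f"unknown strategy: {self.strategy!r}")
        if self.strategy == "subset_batches":
            if not self.subset:
                raise ValueError("subset_batches requires a non-empty subset")
            if len(set(self.subset)) < 2:
                raise ValueError("subset must contain >= 2 distinct studies")
        elif self.subset:
            raise ValueError("subset given but strategy is all_batches")


def _batch_labels(metadata: pd.DataFrame, spec: AdjustmentSpec) -> pd.Series:
    labels = metadata[spec.batch_variable].astype(str)
    if spec.strategy == "subset_batches":
        subset = set(map(str, spec.subset))
        unknown = subset - set(labels)
        if unknown:
            raise ValueError(f"subset studies not present: {sorted(unknown)}")
        labels = labels.where(labels.isin(subset), other="~pooled_reference")
    return labels


def _check_confounding(X: np.ndarray, B: np.ndarray, cov_names,
                       cov_blocks, batch_name: str) -> None:
    """Raise when a batch column is perfectly explained by covariates or
    a covariate block is perfectly explained by batch indicators."""
    n = B.shape[0]
    ones = np.ones((n, 1))
    XI = np.column_stack([ones, X]) if X.size else ones
    # residual of B after projecting on intercept + covariates
    coef, *_ = np.linalg.lstsq(XI, B, rcond=None)
    resid = B - XI @ coef
    dropped = np.linalg.matrix_rank(np.column_stack([XI, B])) - \
        np.linalg.matrix_rank(XI)
    if dropped < B.shape[1] or (B.size and
                                (np.linalg.norm(resid, axis=0)
                                 < 1e-8 * (1 + np.linalg.norm(B, axis=0))).any()):
        BI = np.column_stack([ones, B])
        offenders = []
        for name, blk in zip(cov_names, cov_blocks):
            if not blk.shape[1]:
                continue
            c, *_ = np.linalg.lstsq(BI, blk, rcond=None)
            r = blk - BI @ c
            if (np.linalg.norm(r, axis=0)
                    < 1e-8 * (1 + np.linalg.norm(blk, axis=0))).all():
                offenders.append(name)
        raise ValueError(
            f"batch variable {batch_name!r} is perfectly confounded with "
            f"preserved covariate(s): {offenders or 'unidentified combination'}")


def remove_study_effects(M: MValueMatrix, metadata: pd.DataFrame,
                         spec: AdjustmentSpec) -> MValueMatrix:
    """Subtract fitted per-probe study effects while preserving covariates."""
    meta = metadata.loc[list(M.sample_ids)]
    labels = _batch_labels(meta, spec)
    B, levels = sum_to_zero_batch(labels)
    if B.shape[1] == 0:   # single batch level: nothing estimable
        return MValueMatrix(M.values.copy(), M.probe_ids.copy(),
                            M.sample_ids.copy())

    cov_blocks = [variable_block(meta, v) for v in spec.covariates_to_preserve]
    X = (np.column_stack([b for b in cov_blocks if b.shape[1]])
         if any(b.shape[1] for b in cov_blocks)
         else np.empty((len(meta), 0)))
    _check_confounding(X, B, spec.covariates_to_preserve, cov_blocks,
                       spec.batch_variable)

    n = len(meta)
    D = np.column_stack([np.ones(n), X, B])
    coef, *_ = np.linalg.lstsq(D, M.values.T, rcond=None)
    gamma = coef[1 + X.shape[1]:, :]           # (g-1) x probes
    batch_effect = B @ gamma                   # samples x probes
    return MValueMatrix(M.values - batch_effect.T, M.probe_ids.copy(),
                        M.sample_ids.copy())
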