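"""Design-matrix helpers shared by the batch-adjustment and ANOVA modules."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CATEGORICAL_VARIABLES


def variable_block(metadata: pd.DataFrame, name: str) -> np.ndarray:
    """Columns encoding one modeling variable (no intercept column).

    Categorical variables are dummy-coded with the first (sorted) level as
    reference; numeric variables enter as a single column.
    """
    col = metadata[name]
    if name in CATEGORICAL_VARIABLES or col.dtype == object or isinstance(
            col.dtype, pd.CategoricalDtype):
        levels = sorted(pd.unique(col.astype(str)))
        if len(levels) < 2:
            return np.empty((len(col), 0))
        return np.column_stack([(col.astype(str) == lv).to_numpy(float)
                                for lv in levels[1:]])
    return np.asarray(col, dtype=float)[:, None]


def covariate_matrix(metadata: pd.DataFrame, variables) -> np.ndarray:
    blocks = [variable_block(metadata, v) for v in variables]
    blocks = [b for b in blocks if b.shape[1]]
    if not blocks:
        return np.empty((len(metadata), 0))
    return np.column_stack(blocks)


def sum_to_zero_batch(labels: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Sum-to-zero (deviation) coding of a batch factor.

    Returns an n x (g - 1) matrix where the last sorted level carries -1 in
    every column, so coefficients are deviations from the unweighted mean of
    level effects and the fitted batch term sums to zero over levels.
    """
    levels = sorted(pd.unique(labels.astype(str)))
    g = len(levels)
    if g < 2:
        return np.empty((len(labels), 0)), levels
    B = np.zeros((len(labels), g - 1))
    lab = labels.astype(str).to_numpy()
    for j, lv in enumerate(levels[:-1]):
        B[lab == lv, j] = 1.0
    B[lab == levels[-1], :] = -1.0
    return B, levels
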