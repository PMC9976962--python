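"""Sample and probe QC, Beta/M conversion, sample-type harmonization and
reference-based cell-type deconvolution.

Sample removal rules follow the compilation QC convention: a sample is
dropped when its log2 median methylated and unmethylated signals are both
below 10, or when it fails at least 2 of the 5 most informative BeadArray
quality metrics. PBMC samples with an estimated granulocyte fraction of
0.25 or more are additionally removed (granulocytes are depleted during
PBMC preparation, so a high fraction indicates contamination or
mislabeling).
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd
from scipy import optimize

from .containers import BetaMatrix, CELL_TYPES, CHROMOSOMES, MValueMatrix
from .synth import CellTypeReference

DEFAULT_EPSILON = 1e-6
GRAN_THRESHOLD = 0.25
SIGNAL_CUTOFF = 10.0
BEADARRAY_MAX_FAILURES = 2


def beta_to_m(beta: BetaMatrix, epsilon: float = DEFAULT_EPSILON) -> MValueMatrix:
    """M = log2(b / (1 - b)) after clamping b to [epsilon, 1 - epsilon]."""
    if not 0 < epsilon < 0.5:
        raise ValueError("epsilon must lie in (0, 0.5)")
    b = np.clip(beta.values, epsilon, 1.0 - epsilon)
    return MValueMatrix(np.log2(b / (1.0 - b)), beta.probe_ids.copy(),
                        beta.sample_ids.copy())


def m_to_beta(m: MValueMatrix) -> BetaMatrix:
    """Inverse of :func:`beta_to_m` (up to the clamp)."""
    two_m = np.exp2(m.values)
    return BetaMatrix(two_m / (1.0 + two_m), m.probe_ids.copy(),
                      m.sample_ids.copy())


def qc_filter_samples(qc: pd.DataFrame) -> pd.DataFrame:
    """Per-sample keep/remove decisions with reason codes.

    Removal reasons: ``signal`` (both log2 median signals < 10),
    ``beadarray`` (>= 2/5 failed metrics; takes precedence is not needed,
    both reasons can be recorded joined by '+'), ``missing`` (a metric is
    absent). Returns a table with columns keep (bool) and reason (str).
    """
    required = ["log2_median_M", "log2_median_U", "beadarray_failures"]
    missing_cols = [c for c in required if c not in qc.columns]
    if missing_cols:
        raise ValueError(f"QC metrics missing columns: {missing_cols}")
    out = pd.DataFrame(index=qc.index.copy())
    missing = qc[required].isna().any(axis=1)
    failures = qc["beadarray_failures"]
    if ((failures.dropna() < 0) | (failures.dropna() > 5)).any():
        raise ValueError("beadarray_failures must lie in [0, 5]")
    low_signal = ((qc["log2_median_M"] < SIGNAL_CUTOFF)
                  & (qc["log2_median_U"] < SIGNAL_CUTOFF)) & ~missing
    bead = (failures >= BEADARRAY_MAX_FAILURES) & ~missing
    reason = np.where(missing, "missing", "")
    reason = np.where(low_signal & bead, "signal+beadarray", reason)
    reason = np.where(low_signal & ~bead, "signal", reason)
    reason = np.where(~low_signal & bead, "beadarray", reason)
    out["keep"] = ~(missing | low_signal | bead)
    out["reason"] = reason
    return out


def filter_granulocytes(fractions: pd.DataFrame, sample_type: pd.Series,
                        threshold: float = GRAN_THRESHOLD) -> pd.DataFrame:
    """Remove PBMC samples with granulocyte fraction >= threshold (inclusive)."""
    gran = fractions["Gran"]
    if ((gran < 0) | (gran > 1)).any():
        raise ValueError("cell fractions must lie in [0, 1]")
    st = sample_type.reindex(gran.index)
    remove = (st == "pbmc") & (gran >= threshold)
    return pd.DataFrame({"keep": ~remove,
                         "reason": np.where(remove, "pbmc_granulocyte", "")},
                        index=gran.index)


def filter_probes(annotation: pd.DataFrame, drop_sex_chrom: bool = True,
                  drop_cross_reactive: bool = True,
                  drop_snp: bool = False) -> pd.Series:
    """Order-preserving probe keep-mask from annotation switches."""
    unknown = set(annotation["chromosome"]) - set(CHROMOSOMES)
    if unknown:
        raise ValueError(f"unknown chromosome labels: {sorted(unknown)}")
    keep = pd.Series(True, index=annotation.index)
    if drop_sex_chrom:
        keep &= ~annotation["chromosome"].isin(["chrX", "chrY"])
    if drop_cross_reactive:
        keep &= ~annotation["cross_reactive"].astype(bool)
    if drop_snp:
        keep &= ~annotation["snp_overlap"].astype(bool)
    return keep


# ordered rule table; first match wins, matching is case-insensitive
_SAMPLE_TYPE_RULES: tuple[tuple[str, str], ...] = (
    (r"cord\s*blood|umbilical", "cord_blood"),
    (r"pbmc|peripheral\s+blood\s+mononuclear|mononuclear\s+cell", "pbmc"),
    (r"whole\s*blood|peripheral\s+blood(?!\s+mononuclear)|venous\s+blood",
     "whole_blood"),
)


def harmonize_sample_type(free_text_label: str) -> str:
    """Map a free-text specimen description to the controlled vocabulary."""
    if not isinstance(free_text_label, str) or not free_text_label.strip():
        raise ValueError("label must be a non-empty string")
    for pattern, target in _SAMPLE_TYPE_RULES:
        if re.search(pattern, free_text_label, flags=re.IGNORECASE):
            return target
    return "other"


def _check_reference_rank(R: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(R)
    if rank < R.shape[1]:
        # identify (nearly) collinear columns via correlation of profiles
        corr = np.corrcoef(R.T)
        pairs = [(names[i], names[j])
                 for i in range(len(names)) for j in range(i + 1, len(names))
                 if abs(corr[i, j]) > 1 - 1e-10]
        raise ValueError(f"rank-deficient reference; collinear columns: {pairs}")


def _solve_fractions(R: np.ndarray, b: np.ndarray) -> np.ndarray:
    """min ||R w - b||^2 s.t. w >= 0, sum(w) <= 1, via SLSQP + active-set polish."""
    k = R.shape[1]
    RtR = R.T @ R
    Rtb = R.T @ b

    def objective(w):
        r = R @ w - b
        return 0.5 * float(r @ r)

    def grad(w):
        return RtR @ w - Rtb

    w0 = np.full(k, 1.0 / (k + 1))
    res = optimize.minimize(
        objective, w0, jac=grad, method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "ineq", "fun": lambda w: 1.0 - w.sum(),
                      "jac": lambda w: -np.ones_like(w)}],
        options={"maxiter": 200, "ftol": 1e-14})
    w = np.clip(res.x, 0.0, None)

    # active-set polish: refit exactly on the detected support
    support = w > 1e-7
    if support.any():
        Rs = R[:, support]
        ws, *_ = np.linalg.lstsq(Rs, b, rcond=None)
        if (ws >= -1e-12).all() and ws.sum() <= 1.0 + 1e-12:
            w = np.zeros(k)
            w[support] = np.clip(ws, 0.0, None)
            if w.sum() > 1.0:
                w *= 1.0 / w.sum()
    return w


def deconvolve_cell_fractions(beta_values, reference: CellTypeReference
                              ) -> pd.DataFrame:
    """Estimate six cell-type fractions by constrained least squares.

    Solves min ||b - R w||^2 subject to w >= 0 and sum(w) <= 1 per sample,
    on the reference's discriminating probes. The reported fractions are w
    itself (not renormalized); 1 - sum(w) is the unexplained residual mass.

    Parameters
    ----------
    beta_values : array, shape (n_probes,) or (n_probes, n_samples)
        Beta-values restricted to (and ordered like) the reference probes.
    reference : CellTypeReference
    """
    R = reference.profiles
    _check_reference_rank(R, reference.cell_names)
    B = np.atleast_2d(np.asarray(beta_values, dtype=float).T).T
    if B.shape[0] != R.shape[0]:
        raise ValueError("beta rows must match reference probes")
    W = np.stack([_solve_fractions(R, B[:, j]) for j in range(B.shape[1])])
    return pd.DataFrame(W, columns=list(reference.cell_names))
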