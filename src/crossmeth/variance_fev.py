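"""ANOVA fraction-of-explained-variance (FEV) machinery.

FEV_v = SS_v / SS_total from a sequential (type-I) decomposition with a
fixed variable order: technical (platform, study), then demographic (age,
sex, ancestry), then biological (sample type, cell fractions). Putting
study-ID absorption first is conservative for claims about how much
variance the study label explains. The decomposition is computed by
incremental orthogonalization, which makes per-probe FEV over hundreds of
probes a single pass of matrix products.

The study-bias simulation repeats, per repetition: draw probes and
studies at random, compute M-values, adjust study ID either across all
drawn studies ("adjustment 1") or an exact subset of 2-4 ("adjustment 2"),
run the sequential ANOVA for the three model variants, and report the
per-variable median FEV across the drawn probes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._design import variable_block
from .batch_adjust import AdjustmentSpec, remove_study_effects
from .containers import MODEL_VARIABLES, MValueMatrix, VARIABLE_CATEGORIES
from .feature_hash import HashedProfiles
from .preprocess import beta_to_m

_RANK_TOL = 1e-8


@dataclass
class FEVTable:
    """Per-variable FEV plus the residual fraction; sums to 1."""

    fev: pd.Series
    residual: float
    category: pd.Series

    def __post_init__(self) -> None:
        if (self.fev < -1e-12).any() or self.residual < -1e-12:
            raise ValueError("FEV entries must be non-negative")
        total = float(self.fev.sum()) + self.residual
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"FEV + residual must sum to 1, got {total}")

    def nonresidual(self) -> float:
        return 1.0 - self.residual

    def category_sums(self) -> pd.Series:
        return self.fev.groupby(self.category).sum()

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"fev": self.fev, "category": self.category})
        out.loc["residual"] = [self.residual, "residual"]
        return out


def _categories_for(variables) -> pd.Series:
    return pd.Series({v: VARIABLE_CATEGORIES.get(v, "other")
                      for v in variables})


def sequential_fev(Y: np.ndarray, metadata: pd.DataFrame, variables,
                   on_aliased: str = "error"
                   ) -> tuple[pd.DataFrame, np.ndarray]:
    """Type-I FEV of each column of ``Y`` (n_samples x n_responses).

    Returns (fev table responses x variables, residual fraction array).
    A variable that is constant in the data contributes FEV 0. A
    non-constant variable fully aliased with earlier ones raises when
    ``on_aliased="error"``; with ``on_aliased="zero"`` it contributes FEV
    0 (the earlier variables already absorbed its span - the natural
    reading for nested factors such as platform within study).
    """
    if on_aliased not in ("error", "zero"):
        raise ValueError("on_aliased must be 'error' or 'zero'")
    Y = np.atleast_2d(np.asarray(Y, dtype=float).T).T
    n = Y.shape[0]
    if len(metadata) != n:
        raise ValueError("metadata rows must match response length")
    Yc = Y - Y.mean(axis=0)
    ss_total = (Yc ** 2).sum(axis=0)
    zero_var = ss_total <= 0

    Q = np.ones((n, 1)) / np.sqrt(n)
    ss = {}
    for var in variables:
        X = variable_block(metadata, var)
        if X.shape[1] == 0:       # constant categorical: lies in intercept span
            ss[var] = np.zeros(Y.shape[1])
            continue
        Xr = X - Q @ (Q.T @ X)
        Xr = Xr - Q @ (Q.T @ Xr)  # second pass for numerical orthogonality
        U, s, _ = np.linalg.svd(Xr, full_matrices=False)
        scale = np.linalg.norm(X, axis=0).max()
        keep = s > _RANK_TOL * max(scale, 1.0) * np.sqrt(n)
        if not keep.any():
            centered = X - X.mean(axis=0)
            nonconstant = np.linalg.norm(centered) > \
                _RANK_TOL * max(scale, 1.0) * np.sqrt(n)
            if nonconstant and on_aliased == "error":
                raise ValueError(
                    f"singular design: variable {var!r} is aliased with "
                    f"earlier variables")
            ss[var] = np.zeros(Y.shape[1])
            continue
        Qv = U[:, keep]
        proj = Qv.T @ Y
        ss[var] = (proj ** 2).sum(axis=0)
        Q = np.column_stack([Q, Qv])

    fev = pd.DataFrame(ss, columns=list(variables))
    with np.errstate(invalid="ignore", divide="ignore"):
        fev = fev.div(np.where(zero_var, np.nan, ss_total), axis=0)
    fev = fev.clip(lower=0.0)
    residual = np.clip(1.0 - fev.sum(axis=1).to_numpy(), 0.0, 1.0)
    residual[zero_var] = np.nan
    return fev, residual


def anova_fev(response, metadata: pd.DataFrame,
              variables=MODEL_VARIABLES) -> FEVTable:
    """Sequential ANOVA FEV of a single per-sample response."""
    response = np.asarray(response, dtype=float)
    fev, residual = sequential_fev(response[:, None], metadata, variables)
    return FEVTable(fev.iloc[0], float(residual[0]), _categories_for(variables))


def nonresidual_ratio(adjusted: FEVTable, unadjusted: FEVTable) -> float:
    """(1 - residual_adj) / (1 - residual_unadj); NaN when undefined."""
    denom = unadjusted.nonresidual()
    if denom <= 0:
        return float("nan")
    return adjusted.nonresidual() / denom


@dataclass
class RepetitionResult:
    """One repetition of the study-bias simulation."""

    probe_ids: np.ndarray
    study_ids: np.ndarray
    subset: np.ndarray                      # studies used by adjustment 2
    median_fev: pd.DataFrame                # (variables + residual) x variants
    nonresidual_ratio: dict[str, float]     # per adjusted variant


@dataclass
class BiasSimulationResult:
    repetitions: list[RepetitionResult] = field(default_factory=list)

    VARIANTS = ("unadjusted", "adjustment1", "adjustment2")

    def summary(self) -> pd.DataFrame:
        """Median across repetitions of the per-repetition median FEVs."""
        stacked = pd.concat([r.median_fev for r in self.repetitions],
                            keys=range(len(self.repetitions)))
        return stacked.groupby(level=1, sort=False).median()

    def median_nonresidual_ratio(self) -> dict[str, float]:
        return {v: float(np.nanmedian([r.nonresidual_ratio[v]
                                       for r in self.repetitions]))
                for v in ("adjustment1", "adjustment2")}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, rep in enumerate(self.repetitions):
            for variant in rep.median_fev.columns:
                for var, val in rep.median_fev[variant].items():
                    rows.append({"repetition": i, "variant": variant,
                                 "variable": var, "median_fev": val})
        return pd.DataFrame(rows)


def _median_fev_frame(fev: pd.DataFrame, residual: np.ndarray) -> pd.Series:
    med = fev.median(axis=0)
    med.loc["residual"] = float(np.nanmedian(residual))
    return med


def run_bias_simulation(dataset, n_probes: int = 500, n_studies: int = 5,
                        n_reps: int = 20, seed: int = 0,
                        variables=MODEL_VARIABLES) -> BiasSimulationResult:
    """Study-bias adjustment simulation on a (synthetic) compilation.

    Per repetition: (i) M-values from ``n_probes`` probes and ``n_studies``
    studies drawn at random; (ii) study-ID adjustment across all drawn
    studies (adjustment 1) or a uniform-random subset of 2-4 (adjustment
    2); (iii) sequential ANOVA per probe for the three variants; (iv)
    median FEV per variable across probes, plus the median per-probe
    non-residual variance ratio of each adjusted variant over unadjusted.
    """
    beta = dataset.shared_beta()
    metadata = dataset.metadata
    rng = np.random.default_rng(seed)
    all_studies = np.asarray(sorted(metadata["study_id"].unique()), dtype=object)
    if len(all_studies) < n_studies:
        raise ValueError("dataset has fewer studies than n_studies")
    if beta.n_probes < n_probes:
        raise ValueError("dataset has fewer probes than n_probes")

    result = BiasSimulationResult()
    for _ in range(n_reps):
        for _attempt in range(100):
            studies = rng.choice(all_studies, size=n_studies, replace=False)
            counts = metadata["study_id"].value_counts()
            if all(counts.get(s, 0) >= 2 for s in studies):
                break
            warnings.warn("resampling studies: a drawn study has < 2 samples",
                          stacklevel=2)
        probes = rng.choice(beta.probe_ids, size=n_probes, replace=False)
        sample_mask = metadata["study_id"].isin(studies).to_numpy()
        sample_ids = np.asarray(metadata.index[sample_mask], dtype=object)
        meta_sub = metadata.loc[sample_ids]
        M = beta_to_m(beta.subset_probes(probes).subset_samples(sample_ids))

        subset_size = int(rng.integers(2, min(4, n_studies) + 1))
        subset = rng.choice(studies, size=subset_size, replace=False)
        # adjustment 1: uniform adjustment across all drawn studies
        adj1 = remove_study_effects(M, meta_sub, AdjustmentSpec())
        # adjustment 2: exact adjustment on the 2-4 drawn studies - the
        # analysis is restricted to their samples and study ID is adjusted
        # fully there, so both strategies collapse the study effect
        sub_ids = np.asarray(
            meta_sub.index[meta_sub["study_id"].isin(subset)], dtype=object)
        meta2 = meta_sub.loc[sub_ids]
        M2 = MValueMatrix(M.values[:, pd.Index(M.sample_ids)
                                   .get_indexer(sub_ids)],
                          M.probe_ids, sub_ids)
        adj2 = remove_study_effects(M2, meta2, AdjustmentSpec())

        med, ratios, nonres = {}, {}, {}
        for name, mat, meta_m in (("unadjusted", M, meta_sub),
                                  ("adjustment1", adj1, meta_sub),
                                  ("adjustment2", adj2, meta2)):
            fev, residual = sequential_fev(mat.values.T, meta_m, variables,
                                           on_aliased="zero")
            med[name] = _median_fev_frame(fev, residual)
            nonres[name] = 1.0 - residual
        # ratios compare each adjusted model to the unadjusted model fit on
        # the same samples
        fev_u2, resid_u2 = sequential_fev(M2.values.T, meta2, variables,
                                          on_aliased="zero")
        nonres_u2 = 1.0 - resid_u2
        for name, adj_nonres, unadj_nonres in (
                ("adjustment1", nonres["adjustment1"], nonres["unadjusted"]),
                ("adjustment2", nonres["adjustment2"], nonres_u2)):
            with np.errstate(invalid="ignore", divide="ignore"):
                per_probe = adj_nonres / unadj_nonres
            ratios[name] = float(np.nanmedian(per_probe))
        result.repetitions.append(RepetitionResult(
            probe_ids=probes, study_ids=studies, subset=subset,
            median_fev=pd.DataFrame(med), nonresidual_ratio=ratios))
    return result


@dataclass
class PcaFevResult:
    """Top principal components of hashed profiles with per-component FEV."""

    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    fev_by_variable: pd.DataFrame        # components x (variables + residual)
    category_sums: pd.DataFrame          # components x categories

    def __post_init__(self) -> None:
        if np.any(np.diff(self.eigenvalues) > 1e-9 * self.eigenvalues[0]):
            raise ValueError("eigenvalues must be non-increasing")
        if self.percent_variance.sum() > 100.0 + 1e-6:
            raise ValueError("percent variance cannot exceed 100")


def pca_fev(hashed: HashedProfiles, metadata: pd.DataFrame,
            n_components: int = 10,
            variables=MODEL_VARIABLES) -> PcaFevResult:
    """Centered PCA of hashed profiles, then sequential ANOVA per component."""
    X = hashed.values
    n = X.shape[0]
    if n < n_components:
        raise ValueError("need at least n_components samples")
    meta = metadata.loc[list(hashed.sample_ids)]
    Xc = X - X.mean(axis=0)
    const = Xc.std(axis=0) == 0
    if const.any():
        warnings.warn(f"dropping {int(const.sum())} constant hashed columns",
                      stacklevel=2)
        Xc = Xc[:, ~const]
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, (s > 0).sum())
    eigenvalues = (s ** 2) / (n - 1)
    total_var = eigenvalues.sum()
    scores = U[:, :k] * s[:k]

    rows, cats = [], []
    for j in range(k):
        table = anova_fev(scores[:, j], meta, variables)
        row = table.fev.copy()
        row.loc["residual"] = table.residual
        rows.append(row)
        cats.append(table.category_sums())
    idx = pd.Index([f"PC{j + 1}" for j in range(k)], name="component")
    return PcaFevResult(
        eigenvalues=eigenvalues[:k],
        percent_variance=100.0 * eigenvalues[:k] / total_var,
        fev_by_variable=pd.DataFrame(rows, index=idx),
        category_sums=pd.DataFrame(cats, index=idx))
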