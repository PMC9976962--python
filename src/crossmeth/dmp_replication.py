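"""Sex-DMP calling, concordance-at-the-top and replication summaries.

Sex DMPs are called per probe by ordinary least squares of M-values on
sex plus covariates (cell fractions, age, platform, study ID) and
optional surrogate variables estimated from the residual structure.
Replication against a published discovery set is quantified by the
cumulative overlap of the discovery probes with the ranked compilation
DMPs (concordance at the top), a partition of replicated probes across
two tissues, direction agreement of effect signs, and the fraction of
replicated probes at or near CpG islands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._design import variable_block
from .containers import CELL_TYPES, MValueMatrix

DEFAULT_DMP_COVARIATES = (*CELL_TYPES, "age", "platform", "study_id")


def surrogate_variables(M: MValueMatrix, metadata: pd.DataFrame,
                        design_variables, k: int = 2) -> np.ndarray:
    """Top-k left singular vectors of the M-values residualized against the
    known design - a light-weight surrogate-variable estimate of hidden
    structure. Returns an n_samples x k matrix (k = 0 gives zero columns)."""
    meta = metadata.loc[list(M.sample_ids)]
    n = M.n_samples
    blocks = [np.ones((n, 1))] + [variable_block(meta, v)
                                  for v in design_variables]
    D = np.column_stack([b for b in blocks if b.shape[1]])
    df = np.linalg.matrix_rank(D)
    if k < 0 or k >= n - df:
        if k == 0:
            return np.empty((n, 0))
        raise ValueError(f"k must satisfy 0 <= k < n - model df = {n - df}")
    if k == 0:
        return np.empty((n, 0))
    Y = M.values.T                                # samples x probes
    coef, *_ = np.linalg.lstsq(D, Y, rcond=None)
    resid = Y - D @ coef
    U, s, _ = np.linalg.svd(resid, full_matrices=False)
    return U[:, :k] * np.sqrt(len(U))             # unit-variance-ish scaling


def _drop_aliased_columns(D: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Keep a maximal left-to-right independent column subset (lm-style
    alias handling; e.g. platform nested within study ID loses its column)."""
    n, p = D.shape
    kept: list[int] = []
    Q = np.empty((n, 0))
    scale = max(np.linalg.norm(D, axis=0).max(), 1.0)
    for j in range(p):
        x = D[:, j:j + 1].astype(float)
        r = x - Q @ (Q.T @ x)
        r = r - Q @ (Q.T @ r)
        norm = np.linalg.norm(r)
        if norm > 1e-8 * scale * np.sqrt(n):
            Q = np.column_stack([Q, r / norm])
            kept.append(j)
    return D[:, kept], kept


def call_sex_dmps(M: MValueMatrix, metadata: pd.DataFrame,
                  covariates=DEFAULT_DMP_COVARIATES,
                  surrogates: np.ndarray | None = None,
                  adjust: str = "bonferroni") -> pd.DataFrame:
    """Per-probe OLS sex contrast on M-values.

    Returns a table indexed by probe id with columns p_value, adjusted_p,
    effect (mean M difference male - female, conditional on covariates)
    and direction (sign of the effect). ``adjust`` is ``bonferroni``
    (default) or ``bh``.
    """
    meta = metadata.loc[list(M.sample_ids)]
    sexes = set(meta["sex"].astype(str))
    if len(sexes) < 2:
        raise ValueError("both sexes must be present")
    n = M.n_samples
    sex_col = (meta["sex"].astype(str) == "male").to_numpy(float)[:, None]
    blocks = [np.ones((n, 1)), sex_col]
    for v in covariates:
        blocks.append(variable_block(meta, v))
    if surrogates is not None and surrogates.size:
        blocks.append(np.asarray(surrogates, dtype=float))
    D_full = np.column_stack([b for b in blocks if b.shape[1]])
    D, kept = _drop_aliased_columns(D_full)
    if 1 not in kept:
        raise ValueError("sex contrast is aliased with the covariates")
    df_resid = n - D.shape[1]
    if df_resid < 1:
        raise ValueError("not enough samples for the model")

    Y = M.values.T                                # samples x probes
    DtD_inv = np.linalg.inv(D.T @ D)
    coef = DtD_inv @ (D.T @ Y)
    resid = Y - D @ coef
    sigma2 = (resid ** 2).sum(axis=0) / df_resid
    se = np.sqrt(np.maximum(DtD_inv[1, 1] * sigma2, 1e-300))
    effect = coef[1, :]
    tstat = effect / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df_resid)

    m = len(p)
    if adjust == "bonferroni":
        padj = np.minimum(p * m, 1.0)
    elif adjust == "bh":
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / np.arange(1, m + 1)
        cummin = np.minimum.accumulate(ranked[::-1])[::-1]
        padj = np.empty(m)
        padj[order] = np.minimum(cummin, 1.0)
    else:
        raise ValueError(f"unknown adjustment: {adjust!r}")

    return pd.DataFrame(
        {"p_value": p, "adjusted_p": np.maximum(padj, p),
         "effect": effect, "direction": np.sign(effect)},
        index=pd.Index(M.probe_ids, name="probe_id"))


def rank_dmps(results: pd.DataFrame) -> list:
    """Probe ids ranked by ascending p, ties by |effect| descending then id."""
    idcol = results.index.name or "index"
    tbl = results.reset_index()
    tbl["_abs"] = tbl["effect"].abs()
    tbl = tbl.sort_values(["p_value", "_abs", idcol],
                          ascending=[True, False, True], kind="stable")
    return list(tbl[idcol])


def top_k_set(results: pd.DataFrame, k: int = 1000) -> list:
    """The k most significant probes, in rank order."""
    if k > len(results):
        raise ValueError("k exceeds the number of probes")
    return rank_dmps(results)[:k]


def concordance_at_top(ranked_probe_ids, discovery_ids,
                       max_rank: int | None = None) -> np.ndarray:
    """curve[r-1] = |top-r ranked ids  intersect  discovery| for r=1..max_rank."""
    ranked = list(ranked_probe_ids)
    if len(set(ranked)) != len(ranked):
        raise ValueError("ranked ids must be unique")
    if max_rank is None:
        max_rank = len(ranked)
    disc = set(discovery_ids)
    member = np.fromiter((pid in disc for pid in ranked[:max_rank]),
                         dtype=float, count=min(max_rank, len(ranked)))
    return np.cumsum(member)


@dataclass
class ReplicationSummary:
    """Partition of a discovery DMP set across two replication tissues."""

    n_discovery: int
    n_only_tissue1: int
    n_only_tissue2: int
    n_both: int
    percent_replicated: int          # truncated integer percent
    percent_replicated_exact: float
    direction_agreement_fraction: float

    @property
    def n_replicated_either(self) -> int:
        return self.n_only_tissue1 + self.n_only_tissue2 + self.n_both


def replication_summary(set_t1, set_t2, discovery_ids,
                        effects_t1: pd.Series | None = None,
                        effects_t2: pd.Series | None = None,
                        effects_discovery: pd.Series | None = None
                        ) -> ReplicationSummary:
    """Partition discovery probes replicated in tissue 1 and/or tissue 2.

    The integer percent is truncated (112/292 reports as 38), matching the
    convention of printed replication rates; the exact fraction is also
    reported. Direction agreement is the fraction of (replicated probe,
    tissue) pairs whose effect sign matches the discovery sign, over pairs
    where both signs are available.
    """
    discovery = list(dict.fromkeys(discovery_ids))
    if not discovery:
        raise ValueError("discovery set is empty")
    s1, s2, disc = set(set_t1), set(set_t2), set(discovery)
    both = disc & s1 & s2
    only1 = (disc & s1) - s2
    only2 = (disc & s2) - s1
    union = both | only1 | only2
    exact = 100.0 * len(union) / len(disc)

    agree = checks = 0
    if effects_discovery is not None:
        for tissue_set, effects in ((disc & s1, effects_t1),
                                    (disc & s2, effects_t2)):
            if effects is None:
                continue
            for pid in tissue_set:
                if pid in effects.index and pid in effects_discovery.index:
                    e, d = effects.loc[pid], effects_discovery.loc[pid]
                    if e != 0 and d != 0:
                        checks += 1
                        agree += int(np.sign(e) == np.sign(d))
    agreement = agree / checks if checks else float("nan")

    return ReplicationSummary(
        n_discovery=len(disc), n_only_tissue1=len(only1),
        n_only_tissue2=len(only2), n_both=len(both),
        percent_replicated=math.floor(exact),
        percent_replicated_exact=exact,
        direction_agreement_fraction=agreement)


def island_overlap(replicated_ids, annotation: pd.DataFrame,
                   proximal_relations=("island", "shore")) -> float:
    """Fraction of probes whose island relation is at/near a CpG island."""
    ids = list(replicated_ids)
    missing = [pid for pid in ids if pid not in annotation.index]
    if missing:
        raise KeyError(f"probes missing from annotation, e.g. {missing[:5]}")
    if not ids:
        return float("nan")
    rel = annotation.loc[ids, "island_relation"]
    return float(rel.isin(proximal_relations).mean())


def cell_fraction_sex_test(fractions: pd.DataFrame, sex: pd.Series,
                           adjust_method: str = "fdr_bh") -> pd.DataFrame:
    """Welch t-test of each cell-type fraction between sexes.

    Reports the signed mean difference (male - female), the raw p-value
    and the BH-adjusted p across the six tests.
    """
    sex = sex.reindex(fractions.index).astype(str)
    male = fractions[sex == "male"]
    female = fractions[sex == "female"]
    if len(male) < 2 or len(female) < 2:
        raise ValueError("both sexes need >= 2 samples")
    rows = {}
    for ct in fractions.columns:
        res = stats.ttest_ind(male[ct], female[ct], equal_var=False)
        diff = float(male[ct].mean() - female[ct].mean())
        p = float(res.pvalue)
        if male[ct].var() == 0 and female[ct].var() == 0:
            p = 1.0 if diff == 0 else p
        if not np.isfinite(p):
            p = 1.0
        rows[ct] = {"mean_difference": diff, "p_value": p}
    out = pd.DataFrame(rows).T
    p = out["p_value"].to_numpy()
    if adjust_method == "fdr_bh":
        m = len(p)
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / np.arange(1, m + 1)
        cummin = np.minimum.accumulate(ranked[::-1])[::-1]
        padj = np.empty(m)
        padj[order] = np.minimum(cummin, 1.0)
    elif adjust_method == "bonferroni":
        padj = np.minimum(p * len(p), 1.0)
    else:
        raise ValueError(f"unknown adjustment: {adjust_method!r}")
    out["adjusted_p"] = np.maximum(padj, p)
    return out
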