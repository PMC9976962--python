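"""Simulation-based EWAS power analysis for two-group DMP detection.

The design follows the simulation approach used for methylation-array
power planning: parameterize a per-probe reference distribution (mean and
dispersion of Beta-values) from a compilation, plant mean shifts of
target size delta at a set of target probes, draw Beta-distributed
samples for two equal groups, test per probe on M-values, apply
Benjamini-Hochberg FDR control, and report marginal power - the fraction
of detectable planted DMPs (|shift| above the technical detection limit)
that are discovered - as a function of total sample size N and delta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BetaMatrix

_CLAMP = 1e-6


@dataclass
class ReferenceDistribution:
    """Per-probe mean and dispersion of Beta-values."""

    probe_ids: np.ndarray
    means: np.ndarray
    variances: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if not ((self.means > 0) & (self.means < 1)).all():
            raise ValueError("reference means must lie in (0, 1)")
        cap = self.means * (1.0 - self.means)
        if (self.variances < 0).any() or (self.variances > cap + 1e-12).any():
            raise ValueError("variances must satisfy 0 <= v <= m(1-m)")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


@dataclass
class PowerConfig:
    """Grid and nuisance parameters of the power simulation."""

    N_grid: tuple[int, ...] = tuple(range(50, 851, 100))
    delta_grid: tuple[float, ...] = (0.05, 0.1, 0.2)
    n_target_dmps: int = 500
    n_sims: int = 100
    fdr_threshold: float = 0.05
    detect_limit: float = 0.01
    tau: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.N_grid or not self.delta_grid:
            raise ValueError("grids must be non-empty")
        if min(self.N_grid) < 4:
            raise ValueError("total N must be >= 4")
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must lie in (0, 1)")
        if any(not 0 <= d < 1 for d in self.delta_grid):
            raise ValueError("delta must lie in [0, 1)")
        if self.n_target_dmps <= 0 or self.n_sims <= 0:
            raise ValueError("counts must be positive")


def estimate_reference(beta: BetaMatrix) -> ReferenceDistribution:
    """Per-probe empirical mean and population variance (ddof=0), with the
    variance clipped into the Beta-distribution feasible region."""
    if beta.n_samples < 10:
        raise ValueError("need >= 10 samples to estimate a reference")
    means = np.clip(np.nanmean(beta.values, axis=1), _CLAMP, 1 - _CLAMP)
    variances = np.nanvar(beta.values, axis=1, ddof=0)
    cap = means * (1.0 - means)
    variances = np.clip(variances, 0.0, cap * (1.0 - 1e-9))
    return ReferenceDistribution(beta.probe_ids.copy(), means, variances)


def _beta_params(mean: np.ndarray, var: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Method-of-moments Beta(a, b) for given mean/variance; a variance of
    zero degenerates to a point mass handled by the caller."""
    var = np.maximum(var, 1e-12)
    nu = mean * (1.0 - mean) / var - 1.0
    nu = np.maximum(nu, 1e-6)
    return mean * nu, (1.0 - mean) * nu


def simulate_two_groups(ref: ReferenceDistribution, N: int, delta: float,
                        n_target_dmps: int, tau: float, seed: int
                        ) -> tuple[BetaMatrix, pd.Series, np.ndarray]:
    """Simulate a two-group Beta matrix with planted mean shifts.

    Returns (beta, truth shifts indexed by probe id, group labels). Group
    sizes are floor(N/2) and ceil(N/2). Shift magnitudes are drawn from
    Normal(delta, tau^2) with random sign, redrawn (with a logged count)
    until the shifted mean stays inside (0, 1).
    """
    if N < 4:
        raise ValueError("N must be >= 4")
    if n_target_dmps > ref.n_probes:
        raise ValueError("n_target_dmps exceeds reference probes")
    rng = np.random.default_rng(seed)
    n1 = N // 2
    n2 = N - n1
    groups = np.array(["g1"] * n1 + ["g2"] * n2, dtype=object)

    targets = rng.choice(ref.n_probes, size=n_target_dmps, replace=False)
    shifts = np.zeros(ref.n_probes)
    redraws = 0
    if delta > 0 or tau > 0:
        for t in targets:
            for _ in range(100):
                mag = rng.normal(delta, tau)
                sign = rng.choice([-1.0, 1.0])
                shifted = ref.means[t] + sign * mag
                if _CLAMP < shifted < 1.0 - _CLAMP:
                    shifts[t] = sign * mag
                    break
                redraws += 1
            else:
                shifts[t] = 0.0
    if redraws:
        warnings.warn(f"redrew {redraws} infeasible effect sizes", stacklevel=2)

    means2 = np.clip(ref.means + shifts, _CLAMP, 1.0 - _CLAMP)
    values = np.empty((ref.n_probes, N))
    for mean_vec, cols in ((ref.means, slice(0, n1)), (means2, slice(n1, N))):
        cap = mean_vec * (1.0 - mean_vec)
        var = np.minimum(ref.variances, cap * (1.0 - 1e-9))
        a, b = _beta_params(mean_vec, var)
        ncols = cols.stop - cols.start
        draw = rng.beta(a[:, None], b[:, None], size=(ref.n_probes, ncols))
        point = ref.variances <= 1e-12
        if point.any():
            draw[point, :] = mean_vec[point, None]
        values[:, cols] = np.clip(draw, _CLAMP, 1.0 - _CLAMP)

    sample_ids = np.array([f"sim{i:05d}" for i in range(N)], dtype=object)
    beta = BetaMatrix(values, ref.probe_ids.copy(), sample_ids)
    truth = pd.Series(shifts, index=pd.Index(ref.probe_ids, name="probe_id"))
    return beta, truth, groups


def test_dmps(simulated: BetaMatrix, group_labels) -> pd.Series:
    """Per-probe Welch t-test on M-values; two-sided p-values.

    Probes with zero variance in both groups get p = 1.
    """
    groups = np.asarray(group_labels)
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise ValueError("exactly two groups required")
    g1 = simulated.values[:, groups == uniq[0]]
    g2 = simulated.values[:, groups == uniq[1]]
    if g1.shape[1] < 2 or g2.shape[1] < 2:
        raise ValueError("both groups need >= 2 samples")
    m1 = np.log2(np.clip(g1, _CLAMP, 1 - _CLAMP)
                 / (1 - np.clip(g1, _CLAMP, 1 - _CLAMP)))
    m2 = np.log2(np.clip(g2, _CLAMP, 1 - _CLAMP)
                 / (1 - np.clip(g2, _CLAMP, 1 - _CLAMP)))
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(m1, m2, axis=1, equal_var=False)
    pvals = np.asarray(res.pvalue)
    degenerate = (m1.var(axis=1) == 0) & (m2.var(axis=1) == 0)
    pvals[degenerate | ~np.isfinite(pvals)] = 1.0
    return pd.Series(pvals, index=pd.Index(simulated.probe_ids,
                                           name="probe_id"))


def bh_reject(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejections at level alpha."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    thresh = alpha * (np.arange(1, m + 1)) / m
    below = p[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if below.any():
        kmax = np.max(np.nonzero(below)[0])
        reject[order[:kmax + 1]] = True
    return reject


def compute_power(pvals: pd.Series, truth: pd.Series,
                  fdr_threshold: float = 0.05,
                  detect_limit: float = 0.01) -> float:
    """Marginal power among detectable planted targets after BH control.

    Power = discovered detectable targets / detectable targets, where a
    target is detectable when |shift| > detect_limit. NaN when no target
    is detectable.
    """
    truth = truth.reindex(pvals.index)
    reject = bh_reject(pvals.to_numpy(), fdr_threshold)
    detectable = truth.abs().to_numpy() > detect_limit
    if not detectable.any():
        return float("nan")
    return float(reject[detectable].sum() / detectable.sum())


def realized_fdp(pvals: pd.Series, truth: pd.Series,
                 fdr_threshold: float = 0.05,
                 detect_limit: float = 0.01) -> float:
    """False-discovery proportion among BH rejections (0 when none)."""
    truth = truth.reindex(pvals.index)
    reject = bh_reject(pvals.to_numpy(), fdr_threshold)
    if not reject.any():
        return 0.0
    null = truth.abs().to_numpy() <= detect_limit
    return float((reject & null).sum() / reject.sum())


@dataclass
class PowerCurve:
    """Mean marginal power per (N, delta) with Monte-Carlo standard errors."""

    table: pd.DataFrame   # columns: N, delta, power, mc_se, n_sims

    def power_at(self, N: int, delta: float) -> float:
        row = self.table[(self.table["N"] == N)
                         & (np.isclose(self.table["delta"], delta))]
        return float(row["power"].iloc[0])


def power_curve(ref: ReferenceDistribution, config: PowerConfig) -> PowerCurve:
    """Mean power over ``n_sims`` simulations per (N, delta) grid point."""
    root = np.random.SeedSequence(config.seed)
    rows = []
    for delta in config.delta_grid:
        for N in config.N_grid:
            child = root.spawn(1)[0]
            sim_seeds = child.generate_state(config.n_sims) % (2 ** 31)
            powers = []
            for s in sim_seeds:
                beta, truth, groups = simulate_two_groups(
                    ref, N, delta, config.n_target_dmps, config.tau, int(s))
                pvals = test_dmps(beta, groups)
                powers.append(compute_power(pvals, truth,
                                            config.fdr_threshold,
                                            config.detect_limit))
            powers = np.asarray(powers)
            mean = float(np.nanmean(powers)) if not np.isnan(powers).all() \
                else float("nan")
            se = float(np.nanstd(powers, ddof=1) / np.sqrt(config.n_sims)) \
                if config.n_sims > 1 else 0.0
            rows.append({"N": N, "delta": delta, "power": mean,
                         "mc_se": se, "n_sims": config.n_sims})
    return PowerCurve(pd.DataFrame(rows))


def find_min_n(curve: PowerCurve, target: float = 0.8) -> pd.DataFrame:
    """Smallest grid N reaching the target power per delta, plus a linearly
    interpolated crossing between the bracketing grid points."""
    rows = []
    for delta, sub in curve.table.groupby("delta", sort=True):
        sub = sub.sort_values("N")
        reached = sub[sub["power"] >= target]
        if reached.empty:
            rows.append({"delta": delta, "min_n_grid": np.nan,
                         "min_n_interpolated": np.nan})
            continue
        n_grid = int(reached["N"].iloc[0])
        i = sub.index.get_loc(reached.index[0])
        if i == 0:
            interp = float(n_grid)
        else:
            n0, p0 = sub["N"].iloc[i - 1], sub["power"].iloc[i - 1]
            n1, p1 = sub["N"].iloc[i], sub["power"].iloc[i]
            interp = float(n0 + (target - p0) / (p1 - p0) * (n1 - n0)) \
                if p1 > p0 else float(n_grid)
        rows.append({"delta": delta, "min_n_grid": n_grid,
                     "min_n_interpolated": interp})
    return pd.DataFrame(rows)
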