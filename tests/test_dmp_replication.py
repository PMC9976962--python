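"""Sex-DMP calling, concordance curves, replication arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crossmeth.containers import CELL_TYPES, MValueMatrix
from crossmeth.dmp_replication import (call_sex_dmps, cell_fraction_sex_test,
                                       concordance_at_top, island_overlap,
                                       rank_dmps, replication_summary,
                                       surrogate_variables, top_k_set)


def _meta(n, rng, sex=None):
    if sex is None:
        sex = rng.choice(["female", "male"], size=n)
    # mimic predicted fractions: true weights plus estimation noise so the
    # six columns are not exactly collinear with the intercept
    frac = np.clip(rng.dirichlet(np.ones(6) * 4, size=n)
                   + rng.normal(0, 0.01, size=(n, 6)), 0, 1)
    meta = pd.DataFrame({
        "study_id": rng.choice(["a", "b"], size=n),
        "platform": rng.choice(["hm450k", "epic"], size=n),
        "sample_type": rng.choice(["whole_blood", "pbmc"], size=n),
        "sex": sex, "age": rng.normal(40, 10, size=n),
        "ancestry_pc1": rng.normal(size=n), "ancestry_pc2": rng.normal(size=n),
        **{ct: frac[:, k] for k, ct in enumerate(CELL_TYPES)},
    }, index=[f"s{i:04d}" for i in range(n)])
    return meta


def _mmatrix(values, meta):
    return MValueMatrix(values,
                        np.array([f"p{i:04d}" for i in range(values.shape[0])],
                                 dtype=object),
                        np.asarray(meta.index, dtype=object))


def test_planted_dmp_ranked_first(rng):
    n, n_probes = 400, 1000
    meta = _meta(n, rng)
    male = (meta["sex"] == "male").to_numpy(float)
    values = rng.normal(size=(n_probes, n))
    values[37] += 1.2 * male   # strong planted sex effect on the M scale
    dmps = call_sex_dmps(_mmatrix(values, meta), meta)
    assert rank_dmps(dmps)[0] == "p0037"
    assert dmps.loc["p0037", "direction"] == 1.0


def test_null_pvalues_uniform():
    from scipy import stats
    hits = 0
    for seed in range(50):
        rng = np.random.default_rng(seed)
        meta = _meta(120, rng)
        values = rng.normal(size=(200, 120))
        dmps = call_sex_dmps(_mmatrix(values, meta), meta)
        hits += stats.kstest(dmps["p_value"], "uniform").pvalue > 0.01
    assert hits >= 45


def test_confounded_cell_fraction_effect_removed(rng):
    """A probe tracking a cell fraction that itself differs by sex must not
    be called a sex DMP once the fraction is a covariate."""
    n = 300
    sex = np.array(["male"] * (n // 2) + ["female"] * (n // 2))
    meta = _meta(n, rng, sex=sex)
    # make CD4T differ by sex, then let the probe track CD4T only
    meta["CD4T"] = meta["CD4T"] + 0.1 * (sex == "male")
    values = rng.normal(0, 0.05, size=(50, n))
    values[5] += 8.0 * meta["CD4T"].to_numpy()
    dmps = call_sex_dmps(_mmatrix(values, meta), meta)
    assert dmps.loc["p0005", "p_value"] > 1e-3
    # sanity: without the covariate the same probe looks sex-associated
    naive = call_sex_dmps(_mmatrix(values, meta), meta,
                          covariates=("age", "platform", "study_id"))
    assert naive.loc["p0005", "p_value"] < 1e-6


def test_single_sex_errors(rng):
    meta = _meta(20, rng, sex=np.array(["female"] * 20))
    with pytest.raises(ValueError, match="both sexes"):
        call_sex_dmps(_mmatrix(rng.normal(size=(5, 20)), meta), meta)


def test_adjusted_p_at_least_raw(rng):
    meta = _meta(60, rng)
    values = rng.normal(size=(40, 60))
    for method in ("bonferroni", "bh"):
        dmps = call_sex_dmps(_mmatrix(values, meta), meta, adjust=method)
        assert (dmps["adjusted_p"] >= dmps["p_value"] - 1e-15).all()
        assert (dmps["adjusted_p"] <= 1.0).all()


def test_surrogate_recovers_hidden_batch(rng):
    """A planted hidden batch orthogonal to the design appears as SV1."""
    n = 200
    meta = _meta(n, rng)
    hidden = rng.choice([-1.0, 1.0], size=n)
    values = rng.normal(size=(300, n)) + 2.0 * hidden[None, :] \
        * rng.normal(size=(300, 1))
    sv = surrogate_variables(_mmatrix(values, meta), meta,
                             ("sex", "age"), k=2)
    r = abs(np.corrcoef(sv[:, 0], hidden)[0, 1])
    assert r > 0.9


def test_surrogates_null_structure(rng):
    """Without hidden structure no surrogate dominates the residual."""
    n = 150
    meta = _meta(n, rng)
    values = rng.normal(size=(300, n))
    M = _mmatrix(values, meta)
    sv = surrogate_variables(M, meta, ("sex", "age"), k=5)
    blocks = [np.ones((n, 1)), (meta["sex"] == "male").to_numpy(float)[:, None],
              meta[["age"]].to_numpy()]
    D = np.column_stack(blocks)
    resid = values.T - D @ np.linalg.lstsq(D, values.T, rcond=None)[0]
    total = (resid ** 2).sum()
    for j in range(1, 5):
        explained = ((sv[:, j] / np.linalg.norm(sv[:, j])) @ resid) ** 2
        assert explained.sum() / total < 0.05


def test_surrogate_k_zero_and_too_large(rng):
    meta = _meta(30, rng)
    M = _mmatrix(rng.normal(size=(10, 30)), meta)
    assert surrogate_variables(M, meta, ("sex",), k=0).shape == (30, 0)
    with pytest.raises(ValueError):
        surrogate_variables(M, meta, ("sex",), k=29)


def test_top_k_set_and_ties(rng):
    meta = _meta(40, rng)
    dmps = call_sex_dmps(_mmatrix(rng.normal(size=(30, 40)), meta), meta)
    assert set(top_k_set(dmps, k=30)) == set(dmps.index)
    with pytest.raises(ValueError):
        top_k_set(dmps, k=31)
    # exact ties resolved by |effect| desc then probe id, vs oracle sort
    tied = pd.DataFrame({
        "p_value": [0.01, 0.01, 0.01, 0.5],
        "effect": [1.0, -2.0, 1.0, 3.0]},
        index=pd.Index(["pb", "pa", "paa", "pz"], name="probe_id"))
    assert top_k_set(tied, k=2) == ["pa", "paa"]
    oracle = sorted(tied.index,
                    key=lambda p: (tied.loc[p, "p_value"],
                                   -abs(tied.loc[p, "effect"]), p))
    assert top_k_set(tied, k=4) == oracle


def test_row_order_invariance(rng):
    meta = _meta(50, rng)
    dmps = call_sex_dmps(_mmatrix(rng.normal(size=(25, 50)), meta), meta)
    shuffled = dmps.sample(frac=1, random_state=1)
    assert top_k_set(dmps, k=10) == top_k_set(shuffled, k=10)


def test_concordance_identity_and_disjoint():
    ranked = [f"p{i}" for i in range(20)]
    curve = concordance_at_top(ranked, ranked[:5], max_rank=10)
    np.testing.assert_array_equal(curve[:5], np.arange(1, 6))
    assert curve[9] == 5
    np.testing.assert_array_equal(
        concordance_at_top(ranked, ["x1", "x2"], max_rank=10), np.zeros(10))


def test_concordance_random_matches_hypergeometric(rng):
    """E[overlap at rank 100] = 100 * 50/1000 = 5 under random ranking."""
    probes = [f"p{i}" for i in range(1000)]
    discovery = probes[:50]
    overlaps = []
    for _ in range(200):
        ranked = list(rng.permutation(probes))
        overlaps.append(concordance_at_top(ranked, discovery,
                                           max_rank=100)[-1])
    mean = np.mean(overlaps)
    se = np.std(overlaps, ddof=1) / np.sqrt(200)
    assert abs(mean - 5.0) <= 2 * se + 0.05


def test_replication_summary_printed_counts():
    """The worked example: 42 only-t1 + 17 only-t2 + 53 both = 112 of 292
    discovery probes -> 38% (truncated)."""
    discovery = [f"d{i}" for i in range(292)]
    both = discovery[:53]
    only1 = discovery[53:95]      # 42
    only2 = discovery[95:112]     # 17
    set_t1 = set(both) | set(only1) | {"extra1"}
    set_t2 = set(both) | set(only2) | {"extra2"}
    summary = replication_summary(set_t1, set_t2, discovery)
    assert summary.n_only_tissue1 == 42
    assert summary.n_only_tissue2 == 17
    assert summary.n_both == 53
    assert summary.n_replicated_either == 112
    assert summary.percent_replicated == 38
    assert summary.percent_replicated_exact == pytest.approx(100 * 112 / 292)


def test_replication_direction_agreement():
    discovery = ["a", "b", "c"]
    eff_d = pd.Series({"a": 1.0, "b": -1.0, "c": 1.0})
    eff_t1 = pd.Series({"a": 0.5, "b": -0.2})
    eff_t2 = pd.Series({"b": -0.4, "c": 2.0})
    summary = replication_summary({"a", "b"}, {"b", "c"}, discovery,
                                  effects_t1=eff_t1, effects_t2=eff_t2,
                                  effects_discovery=eff_d)
    assert summary.direction_agreement_fraction == 1.0
    flipped = replication_summary({"a", "b"}, {"b", "c"}, discovery,
                                  effects_t1=pd.Series({"a": -0.5,
                                                        "b": -0.2}),
                                  effects_t2=eff_t2,
                                  effects_discovery=eff_d)
    assert flipped.direction_agreement_fraction == pytest.approx(3 / 4)


def test_replication_empty_discovery_errors():
    with pytest.raises(ValueError):
        replication_summary({"a"}, {"b"}, [])


@given(st.sets(st.integers(0, 60), min_size=1),
       st.sets(st.integers(0, 60)), st.sets(st.integers(0, 60)))
@settings(max_examples=100, deadline=None)
def test_replication_partition_identity(disc, s1, s2):
    summary = replication_summary({f"p{i}" for i in s1},
                                  {f"p{i}" for i in s2},
                                  [f"p{i}" for i in disc])
    assert (summary.n_only_tissue1 + summary.n_only_tissue2 + summary.n_both
            == summary.n_replicated_either)
    assert summary.n_replicated_either <= summary.n_discovery


def test_island_overlap_fractions():
    annotation = pd.DataFrame({
        "island_relation": ["island"] * 84 + ["open_sea"] * 28,
        "chromosome": ["chr1"] * 112,
        "cross_reactive": [False] * 112, "snp_overlap": [False] * 112,
    }, index=[f"p{i}" for i in range(112)])
    ids = list(annotation.index)
    assert island_overlap(ids, annotation) == pytest.approx(84 / 112)
    assert island_overlap(ids[:84], annotation) == 1.0
    assert island_overlap(ids[84:], annotation) == 0.0
    with pytest.raises(KeyError):
        island_overlap(["ghost"], annotation)


def test_cell_fraction_sex_test_identical_groups(rng):
    frac = pd.DataFrame(rng.dirichlet(np.ones(6), size=40),
                        columns=list(CELL_TYPES),
                        index=[f"s{i}" for i in range(40)])
    frac.iloc[20:] = frac.iloc[:20].to_numpy()
    sex = pd.Series(["male"] * 20 + ["female"] * 20, index=frac.index)
    out = cell_fraction_sex_test(frac, sex)
    np.testing.assert_allclose(out["mean_difference"], 0.0, atol=1e-12)
    assert (out["p_value"] > 0.99).all()


def test_cell_fraction_sex_test_detects_gran_excess(rng):
    """3% granulocyte excess in females, n=500/arm, sd=0.02: detected with
    a negative male - female sign at adjusted p < 1e-3."""
    n = 1000
    sex = pd.Series(["male"] * 500 + ["female"] * 500,
                    index=[f"s{i}" for i in range(n)])
    frac = pd.DataFrame(
        0.1 + rng.normal(0, 0.02, size=(n, 6)).clip(-0.09, 0.5),
        columns=list(CELL_TYPES), index=sex.index)
    frac.loc[sex == "female", "Gran"] += 0.03
    out = cell_fraction_sex_test(frac, sex)
    assert out.loc["Gran", "adjusted_p"] < 1e-3
    assert out.loc["Gran", "mean_difference"] < 0
    assert (out["adjusted_p"] >= out["p_value"] - 1e-15).all()
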