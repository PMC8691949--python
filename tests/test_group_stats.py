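import numpy as np
import pandas as pd
import pytest

from breathlearn import group_stats as gs
from breathlearn import task_sim


# ---------------------------------------------------------------------------
# Anderson-Darling normality
# ---------------------------------------------------------------------------

def test_ad_calibration_on_normal_samples():
    rng = np.random.default_rng(0)
    rejections = sum(gs.ad_normality(rng.standard_normal(30)).reject for _ in range(800))
    assert 0.02 <= rejections / 800 <= 0.09


def test_ad_power_on_exponential_samples():
    rng = np.random.default_rng(1)
    rejections = sum(gs.ad_normality(rng.exponential(size=30)).reject for _ in range(300))
    assert rejections / 300 > 0.5


def test_ad_location_scale_invariance():
    rng = np.random.default_rng(2)
    x = rng.standard_normal(40)
    a = gs.ad_normality(x)
    b = gs.ad_normality(3.7 * x - 11.0)
    assert a.statistic == pytest.approx(b.statistic, abs=1e-10)


def test_ad_constant_sample():
    with pytest.warns(UserWarning):
        res = gs.ad_normality(np.full(20, 3.0))
    assert res.reject


def test_ad_minimum_n():
    with pytest.raises(ValueError):
        gs.ad_normality(np.arange(5))


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def _two_group_table(rng, n=30, shift=0.0, skew=False):
    a = rng.standard_normal(n)
    b = rng.standard_normal(n) + shift
    if skew:
        a, b = np.exp(a), np.exp(b)
    return pd.DataFrame({"group": ["low"] * n + ["moderate"] * n, "m": np.r_[a, b]})


def test_bonferroni_thresholds():
    rng = np.random.default_rng(0)
    table = _two_group_table(rng)
    c13 = gs.compare_groups(table, ["m"], family_size=13)[0]
    assert c13.corrected_threshold == pytest.approx(0.05 / 13)
    assert round(c13.corrected_threshold, 3) == 0.004
    c4 = gs.compare_groups(table, ["m"], family_size=4)[0]
    assert c4.corrected_threshold == pytest.approx(0.0125)


def test_normality_gate_selects_test():
    rng = np.random.default_rng(0)
    normal = gs.compare_groups(_two_group_table(rng), ["m"])[0]
    assert normal.test == "t"
    assert "mean" in normal.group_summaries["low"]
    skewed = gs.compare_groups(_two_group_table(rng, skew=True), ["m"])[0]
    assert skewed.test == "wilcoxon-rank-sum"
    assert "median" in skewed.group_summaries["low"]


def test_identical_groups_are_null():
    positives = 0
    for seed in range(60):
        rng = np.random.default_rng(seed)
        comp = gs.compare_groups(_two_group_table(rng), ["m"])[0]
        positives += comp.p < 0.05
    assert positives / 60 < 0.15


def test_planted_shift_detected():
    rng = np.random.default_rng(4)
    comp = gs.compare_groups(_two_group_table(rng, shift=1.5), ["m"], family_size=13)[0]
    assert comp.significant_corrected


def test_compare_groups_validation():
    df = pd.DataFrame({"group": ["a"], "m": [1.0]})
    with pytest.raises(ValueError):
        gs.compare_groups(df, ["m"])
    df3 = pd.DataFrame({"group": ["a", "b", "c"] * 5, "m": np.arange(15.0)})
    with pytest.raises(ValueError):
        gs.compare_groups(df3, ["m"])


def test_compare_groups_cohort_pattern():
    # affective measures should survive Bonferroni; vigilance (null effect)
    # should not - a pattern check on the default synthetic cohort
    cohort = task_sim.generate_multimodal_cohort(task_sim.CohortConfig(seed=0))
    questionnaires = list(task_sim.AFFECTIVE_MEASURES + task_sim.INTEROCEPTIVE_MEASURES)
    comps = {c.measure: c for c in gs.compare_groups(cohort, questionnaires)}
    assert all(comps[m].significant_corrected for m in task_sim.AFFECTIVE_MEASURES)
    assert not comps["pvq_b"].significant_corrected


# ---------------------------------------------------------------------------
# correlation matrix
# ---------------------------------------------------------------------------

def test_correlation_matrix_structure():
    cohort = task_sim.generate_multimodal_cohort(task_sim.CohortConfig(seed=1))
    res = gs.correlation_matrix(cohort)
    r = res.r.to_numpy()
    assert np.allclose(r, r.T)
    assert np.allclose(np.diag(r), 1.0)
    assert not res.significant_fdr.to_numpy().diagonal().any()


def test_correlation_planted_pair():
    rng = np.random.default_rng(5)
    x = rng.standard_normal(60)
    y = 0.9 * x + np.sqrt(1 - 0.81) * rng.standard_normal(60)
    df = pd.DataFrame({"a": x, "b": y, "c": rng.standard_normal(60)})
    res = gs.correlation_matrix(df, measures=["a", "b", "c"])
    assert 0.8 <= res.r.loc["a", "b"] <= 0.96
    assert res.significant_fdr.loc["a", "b"]


def test_correlation_independent_columns_fdr_null():
    counts = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.standard_normal((60, 6)), columns=list("abcdef"))
        res = gs.correlation_matrix(df, measures=list("abcdef"))
        counts.append(res.significant_fdr.to_numpy()[np.triu_indices(6, 1)].sum())
    assert np.mean(counts) < 1.0


def test_correlation_spearman_variant():
    rng = np.random.default_rng(6)
    df = pd.DataFrame(rng.standard_normal((40, 3)), columns=list("abc"))
    res = gs.correlation_matrix(df, measures=list("abc"), method="spearman")
    assert res.method == "spearman"


def test_correlation_zero_variance_named():
    df = pd.DataFrame({"a": np.arange(10.0), "b": np.ones(10)})
    with pytest.raises(ValueError, match="b"):
        gs.correlation_matrix(df, measures=["a", "b"])


# ---------------------------------------------------------------------------
# permutation PCA
# ---------------------------------------------------------------------------

def _planted_factor_table(seed, n=60, loading=0.9):
    loadings = np.zeros((16, 1))
    loadings[:8, 0] = loading
    cfg = task_sim.CohortConfig(group_effects={}, loadings=loadings, seed=seed)
    return task_sim.generate_multimodal_cohort(cfg)


def test_pca_variance_sums_to_one():
    pca = gs.pca_significance(_planted_factor_table(0), n_perm=150, seed=0)
    assert pca.variance_explained.sum() == pytest.approx(1.0, abs=1e-10)
    assert np.all(np.diff(pca.variance_explained) <= 1e-12)


def test_pca_score_reconstruction_identity():
    table = _planted_factor_table(1)
    pca = gs.pca_significance(table, n_perm=150, seed=0)
    X = table[list(pca.measures)].to_numpy()
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    assert np.allclose(pca.scores, Z @ pca.weights.T, atol=1e-10)
    assert np.allclose(pca.weights @ pca.weights.T, np.eye(pca.weights.shape[0]), atol=1e-10)


def test_pca_sign_convention():
    pca = gs.pca_significance(_planted_factor_table(2), n_perm=150, seed=0)
    for row in pca.weights:
        assert row[np.argmax(np.abs(row))] > 0


def test_pca_planted_factor_significant():
    pca = gs.pca_significance(_planted_factor_table(3), n_perm=300, seed=0)
    assert 0 in pca.significant
    # the affective/interoceptive block carries the weight
    assert np.abs(pca.weights[0, :8]).mean() > np.abs(pca.weights[0, 8:]).mean()


def test_pca_determinism():
    t = _planted_factor_table(4)
    a = gs.pca_significance(t, n_perm=120, seed=9)
    b = gs.pca_significance(t, n_perm=120, seed=9)
    assert np.array_equal(a.null_variance, b.null_variance)


def test_pca_n_perm_floor():
    with pytest.raises(ValueError):
        gs.pca_significance(_planted_factor_table(5), n_perm=10)


def test_pca_rank_deficient_warns():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(rng.standard_normal((10, 16)), columns=list(task_sim.MEASURE_NAMES))
    with pytest.warns(UserWarning):
        gs.pca_significance(df, n_perm=120, seed=0)


# ---------------------------------------------------------------------------
# component-score comparisons
# ---------------------------------------------------------------------------

def test_component_scores_group_difference():
    # group effect loaded on the factor columns -> PC1 separates the groups
    cohort = task_sim.generate_multimodal_cohort(task_sim.CohortConfig(seed=7))
    pca = gs.pca_significance(cohort, n_perm=300, seed=0)
    assert pca.significant
    comps = gs.compare_component_scores(pca, cohort["group"].to_numpy())
    assert comps[0].p < 0.01
    assert comps[0].significant_corrected


def test_component_scores_single_component_fdr_is_raw():
    cohort = task_sim.generate_multimodal_cohort(task_sim.CohortConfig(seed=8))
    pca = gs.pca_significance(cohort, n_perm=300, seed=0)
    one = gs.PCAResult(
        measures=pca.measures,
        weights=pca.weights,
        scores=pca.scores,
        variance_explained=pca.variance_explained,
        null_variance=pca.null_variance,
        null_95=pca.null_95,
        significant=(0,),
    )
    comps = gs.compare_component_scores(one, cohort["group"].to_numpy())
    assert len(comps) == 1
    assert comps[0].significant_corrected == (comps[0].p < 0.05)


def test_component_scores_requires_significant():
    cohort = task_sim.generate_multimodal_cohort(task_sim.CohortConfig(seed=9))
    pca = gs.pca_significance(cohort, n_perm=150, seed=0)
    empty = gs.PCAResult(
        measures=pca.measures, weights=pca.weights, scores=pca.scores,
        variance_explained=pca.variance_explained, null_variance=pca.null_variance,
        null_95=pca.null_95, significant=(),
    )
    with pytest.raises(ValueError):
        gs.compare_component_scores(empty, cohort["group"].to_numpy())
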