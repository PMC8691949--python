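"""Normality-gated group comparisons, multimodal correlations and
permutation-tested PCA.

Group comparisons use a two-tailed independent t test when an
Anderson-Darling test rejects normality in neither group, and a Wilcoxon
rank-sum test otherwise, with Bonferroni families sized per modality.
PCA component significance is assessed against a null distribution built
by independently shuffling each measure across participants and comparing
variance explained at matched component rank.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .task_sim import MEASURE_NAMES

__all__ = [
    "ADResult",
    "ad_normality",
    "GroupComparison",
    "compare_groups",
    "CorrelationResult",
    "correlation_matrix",
    "PCAResult",
    "pca_significance",
    "compare_component_scores",
]


@dataclass(frozen=True)
class ADResult:
    statistic: float
    p: float
    reject: bool


def ad_normality(sample, alpha: float = 0.05) -> ADResult:
    """Anderson-Darling test for normality with estimated parameters.

    Uses the small-sample-modified statistic
    ``A2* = A2 * (1 + 0.75/n + 2.25/n**2)`` and the standard piecewise
    approximation for its p value (composite-normal case). A constant
    sample is reported as a rejection with a warning.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 8:
        raise ValueError(f"need at least 8 observations, got {n}")
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn("constant sample; normality rejected by convention")
        return ADResult(float("inf"), 0.0, True)
    z = stats.norm.cdf((x - x.mean()) / sd)
    z = np.clip(z, 1e-15, 1 - 1e-15)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (np.log(z) + np.log(1 - z[::-1])))
    a2m = a2 * (1.0 + 0.75 / n + 2.25 / n**2)
    if a2m >= 0.6:
        p = math.exp(1.2937 - 5.709 * a2m + 0.0186 * a2m**2)
    elif a2m > 0.34:
        p = math.exp(0.9177 - 4.279 * a2m - 1.38 * a2m**2)
    elif a2m > 0.2:
        p = 1.0 - math.exp(-8.318 + 42.796 * a2m - 59.938 * a2m**2)
    else:
        p = 1.0 - math.exp(-13.436 + 101.14 * a2m - 223.73 * a2m**2)
    p = float(min(max(p, 0.0), 1.0))
    return ADResult(float(a2m), p, bool(p < alpha))


@dataclass(frozen=True)
class GroupComparison:
    measure: str
    test: str  # "t" or "wilcoxon-rank-sum"
    statistic: float
    p: float
    family_size: int
    corrected_threshold: float
    significant_corrected: bool
    group_summaries: dict

    def to_dict(self) -> dict:
        d = {
            "measure": self.measure,
            "test": self.test,
            "statistic": self.statistic,
            "p": self.p,
            "family_size": self.family_size,
            "corrected_threshold": self.corrected_threshold,
            "significant_corrected": self.significant_corrected,
        }
        for g, s in self.group_summaries.items():
            for k, v in s.items():
                d[f"{g}_{k}"] = v
        return d


def _summarise(x: np.ndarray, test: str) -> dict:
    if test == "t":
        return {"mean": float(x.mean()), "se": float(x.std(ddof=1) / math.sqrt(x.size))}
    q75, q25 = np.percentile(x, [75, 25])
    return {"median": float(np.median(x)), "iqr": float(q75 - q25)}


def compare_groups(
    table: pd.DataFrame,
    measures: list[str],
    family_size: int | None = None,
    group_col: str = "group",
    alpha: float = 0.05,
) -> list[GroupComparison]:
    """Normality-gated group tests with a Bonferroni family threshold.

    The t test is used only when the Anderson-Darling test rejects
    normality in neither group; otherwise the Wilcoxon rank-sum test.
    Summaries are mean +- SE for t tests and median +- IQR for rank-sum
    tests, matching the reporting convention of each test.
    """
    groups = sorted(table[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    fam = family_size if family_size is not None else len(measures)
    threshold = alpha / fam
    out = []
    for m in measures:
        a = table.loc[table[group_col] == groups[0], m].to_numpy(float)
        b = table.loc[table[group_col] == groups[1], m].to_numpy(float)
        if a.size < 2 or b.size < 2:
            raise ValueError(f"group with fewer than 2 observations for {m!r}")
        normal = not (ad_normality(a).reject or ad_normality(b).reject)
        if normal:
            test = "t"
            stat, p = stats.ttest_ind(a, b)
        else:
            test = "wilcoxon-rank-sum"
            stat, p = stats.ranksums(a, b)
        out.append(
            GroupComparison(
                measure=m,
                test=test,
                statistic=float(stat),
                p=float(p),
                family_size=fam,
                corrected_threshold=threshold,
                significant_corrected=bool(p < threshold),
                group_summaries={
                    groups[0]: _summarise(a, test),
                    groups[1]: _summarise(b, test),
                },
            )
        )
    return out


@dataclass(frozen=True)
class CorrelationResult:
    measures: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame
    significant_unc: pd.DataFrame
    significant_fdr: pd.DataFrame
    method: str


def correlation_matrix(
    table: pd.DataFrame,
    measures: list[str] | None = None,
    method: str = "pearson",
    alpha: float = 0.05,
) -> CorrelationResult:
    """All-pairs correlation matrix with two significance tiers.

    Significance is flagged both uncorrected (p < 0.05) and after
    Benjamini-Hochberg FDR correction over the off-diagonal upper triangle.
    A Spearman variant is available via ``method="spearman"``.
    """
    measures = measures or [m for m in MEASURE_NAMES if m in table.columns]
    X = table[measures].to_numpy(float)
    for j, m in enumerate(measures):
        if np.std(X[:, j]) == 0:
            raise ValueError(f"zero-variance column {m!r}")
    k = len(measures)
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            res = corr(X[:, i], X[:, j])
            r[i, j] = r[j, i] = res[0]
            p[i, j] = p[j, i] = res[1]
    iu = np.triu_indices(k, 1)
    rej, _, _, _ = multipletests(p[iu], alpha=alpha, method="fdr_bh")
    sig_fdr = np.zeros((k, k), dtype=bool)
    sig_fdr[iu] = rej
    sig_fdr |= sig_fdr.T
    sig_unc = (p < alpha) & ~np.eye(k, dtype=bool)
    mk = list(measures)
    return CorrelationResult(
        measures=tuple(mk),
        r=pd.DataFrame(r, index=mk, columns=mk),
        p=pd.DataFrame(p, index=mk, columns=mk),
        significant_unc=pd.DataFrame(sig_unc, index=mk, columns=mk),
        significant_fdr=pd.DataFrame(sig_fdr, index=mk, columns=mk),
        method=method,
    )


@dataclass(frozen=True)
class PCAResult:
    measures: tuple[str, ...]
    weights: np.ndarray  # (n_components, n_measures)
    scores: np.ndarray  # (n_subjects, n_components)
    variance_explained: np.ndarray
    null_variance: np.ndarray  # (n_perm, n_components)
    null_95: np.ndarray
    significant: tuple[int, ...]  # 0-based component indices

    @property
    def n_significant(self) -> int:
        return len(self.significant)


def _pca(X: np.ndarray):
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    var = s**2 / np.sum(s**2)
    return u, s, vt, var


def pca_significance(
    table: pd.DataFrame,
    measures: list[str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    percentile: float = 95.0,
) -> PCAResult:
    """PCA with a column-shuffling permutation test of component rank.

    Columns are z-scored, decomposed by SVD, and each component's variance
    explained is compared with the 95th percentile of the null distribution
    at the same rank, built by independently permuting every column across
    participants ``n_perm`` times. Weight signs are fixed so the
    largest-magnitude loading of each component is positive.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    measures = measures or [m for m in MEASURE_NAMES if m in table.columns]
    X = table[measures].to_numpy(float)
    n, m = X.shape
    if m > n:
        warnings.warn(f"more measures ({m}) than subjects ({n}); PCA is rank-deficient")
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [measures[j] for j in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance columns {bad}")
    Z = (X - X.mean(axis=0)) / sd

    _, _, vt, var = _pca(Z)
    k = var.size
    # reproducible sign convention
    weights = vt.copy()
    for c in range(k):
        j = np.argmax(np.abs(weights[c]))
        if weights[c, j] < 0:
            weights[c] = -weights[c]
    scores = Z @ weights.T

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, k))
    for p_i in range(n_perm):
        Zp = np.empty_like(Z)
        for j in range(m):
            Zp[:, j] = Z[rng.permutation(n), j]
        s = np.linalg.svd(Zp, compute_uv=False)
        null[p_i] = s**2 / np.sum(s**2)
    null_95 = np.percentile(null, percentile, axis=0)
    significant = tuple(int(c) for c in range(k) if var[c] > null_95[c])
    return PCAResult(
        measures=tuple(measures),
        weights=weights,
        scores=scores,
        variance_explained=var,
        null_variance=null,
        null_95=null_95,
        significant=significant,
    )


def compare_component_scores(
    pca: PCAResult,
    groups,
    alpha: float = 0.05,
) -> list[GroupComparison]:
    """Normality-gated group tests on significant component scores.

    FDR (Benjamini-Hochberg) correction is applied across the significant
    components only; with a single significant component the corrected
    decision equals the raw one.
    """
    if not pca.significant:
        raise ValueError("no significant components to compare")
    groups = np.asarray(groups)
    labels = sorted(np.unique(groups).tolist())
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, found {labels}")
    comps = []
    pvals = []
    for c in pca.significant:
        a = pca.scores[groups == labels[0], c]
        b = pca.scores[groups == labels[1], c]
        normal = not (ad_normality(a).reject or ad_normality(b).reject)
        if normal:
            test = "t"
            stat, p = stats.ttest_ind(a, b)
        else:
            test = "wilcoxon-rank-sum"
            stat, p = stats.ranksums(a, b)
        comps.append((c, test, float(stat), float(p), a, b))
        pvals.append(float(p))
    rej, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    out = []
    for (c, test, stat, p, a, b), sig in zip(comps, rej):
        out.append(
            GroupComparison(
                measure=f"PC{c + 1}",
                test=test,
                statistic=stat,
                p=p,
                family_size=len(pca.significant),
                corrected_threshold=float("nan"),  # FDR, not Bonferroni
                significant_corrected=bool(sig),
                group_summaries={
                    labels[0]: _summarise(a, test),
                    labels[1]: _summarise(b, test),
                },
            )
        )
    return out
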