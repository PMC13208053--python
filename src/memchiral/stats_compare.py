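"""Two-group statistical battery for descriptor comparisons.

Per descriptor: descriptive statistics, Shapiro-Wilk normality per group,
Welch's two-tailed unequal-variance t, Mann-Whitney U (exact by full labeling
enumeration for small tie-free samples, normal approximation with tie and
continuity corrections otherwise), Cohen's d; plus balanced two-way ANOVA
with interaction and a z-scored PCA over the pooled descriptor matrix with
per-group dispersion metrics. Significance threshold alpha = 0.05, no
multiple-testing correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

from .descriptors import DESCRIPTOR_NAMES, DescriptorVector

logger = logging.getLogger(__name__)


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: float | tuple | None = None


@dataclass
class PCAResult:
    """Loadings, scores and explained variance of the z-scored PCA.

    ``loadings`` is (descriptor x component) with unit-norm columns;
    ``scores`` is (structure x component); ``dispersion`` maps group label ->
    dict with mean distance-to-centroid and within-group variance in the
    retained 2-component space.
    """

    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame
    group_labels: list
    dispersion: dict
    dropped_columns: list


def shapiro_wilk(values) -> TestResult:
    """Shapiro-Wilk normality test (W, p) for a sample of 3..5000 values."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("sample too small for Shapiro-Wilk (n < 3)")
    if x.size > 5000:
        raise ValueError("sample too large for Shapiro-Wilk (n > 5000)")
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample: zero variance")
    w, p = sps.shapiro(x)
    return TestResult(statistic=float(w), p_value=float(p), method="shapiro")


def welch_t(a, b) -> TestResult:
    """Welch's two-tailed t test with Welch-Satterthwaite df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t needs n >= 2 per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            raise ValueError("degenerate: zero variance and equal means")
        return TestResult(statistic=np.inf if b.mean() < a.mean() else -np.inf,
                          p_value=0.0, method="welch_t", df=float("nan"))
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(statistic=float(res.statistic),
                      p_value=float(res.pvalue), method="welch_t",
                      df=float(res.df))


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x versus y, counting ties as 1/2."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney(a, b, exact_threshold: int = 8) -> TestResult:
    """Mann-Whitney U with U = min(U_a, U_b).

    When both samples have at most ``exact_threshold`` observations and there
    are no ties, the two-sided p is exact: the proportion of all
    C(n_a+n_b, n_a) group labelings of the pooled values whose min-U is at
    most the observed one. Otherwise the normal approximation with tie and
    continuity corrections is used; the method is recorded in the result.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = a.size, b.size
    if n_a < 1 or n_b < 1:
        raise ValueError("mann_whitney needs n >= 1 per group")
    u_a = _u_statistic(a, b)
    u_b = n_a * n_b - u_a
    u_min = min(u_a, u_b)
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if max(n_a, n_b) <= exact_threshold and not has_ties:
        total = comb(n_a + n_b, n_a)
        count = 0
        idx_all = frozenset(range(n_a + n_b))
        for chosen in combinations(range(n_a + n_b), n_a):
            xa = pooled[list(chosen)]
            xb = pooled[list(idx_all - set(chosen))]
            ua = _u_statistic(xa, xb)
            if min(ua, n_a * n_b - ua) <= u_min:
                count += 1
        return TestResult(statistic=u_min, p_value=count / total,
                          method="mann_whitney_exact", df=(n_a, n_b))
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="asymptotic", use_continuity=True)
    return TestResult(statistic=u_min, p_value=float(res.pvalue),
                      method="mann_whitney_normal", df=(n_a, n_b))


def cohens_d(a_mean: float, a_sd: float, b_mean: float, b_sd: float) -> float:
    """Unsigned standardized mean difference, equal-n pooled-SD form.

    d = |b_mean - a_mean| / sqrt((a_sd^2 + b_sd^2) / 2).
    """
    if a_sd < 0 or b_sd < 0:
        raise ValueError("standard deviations must be nonnegative")
    denom = np.sqrt((a_sd ** 2 + b_sd ** 2) / 2.0)
    if denom == 0:
        raise ValueError("degenerate: both standard deviations zero")
    return float(abs(b_mean - a_mean) / denom)


def cohens_d_from_samples(a, b) -> float:
    """Cohen's d from raw samples using sample (ddof=1) SDs."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return cohens_d(a.mean(), a.std(ddof=1), b.mean(), b.std(ddof=1))


def two_way_anova(values, factor_a_labels, factor_b_labels) -> dict:
    """Balanced fixed-effects two-way ANOVA with interaction.

    Requires a complete balanced design with >= 2 replicates per cell.
    Returns a dict with TestResults keyed 'factor_a', 'factor_b',
    'interaction'.
    """
    y = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a_labels)
    fb = np.asarray(factor_b_labels)
    if not (y.size == fa.size == fb.size):
        raise ValueError("values and factor labels must have equal length")
    a_levels = sorted(set(fa.tolist()))
    b_levels = sorted(set(fb.tolist()))
    I, J = len(a_levels), len(b_levels)
    cells = {}
    for ai in a_levels:
        for bj in b_levels:
            cells[(ai, bj)] = y[(fa == ai) & (fb == bj)]
    sizes = {k: v.size for k, v in cells.items()}
    n = next(iter(sizes.values()))
    if n < 2 or any(sz != n for sz in sizes.values()):
        raise ValueError("unbalanced design: need equal cell sizes >= 2")
    grand = y.mean()
    mean_a = {ai: y[fa == ai].mean() for ai in a_levels}
    mean_b = {bj: y[fb == bj].mean() for bj in b_levels}
    ss_a = n * J * sum((mean_a[ai] - grand) ** 2 for ai in a_levels)
    ss_b = n * I * sum((mean_b[bj] - grand) ** 2 for bj in b_levels)
    ss_ab = n * sum(
        (cells[(ai, bj)].mean() - mean_a[ai] - mean_b[bj] + grand) ** 2
        for ai in a_levels for bj in b_levels)
    ss_err = sum(((cells[k] - cells[k].mean()) ** 2).sum() for k in cells)
    df_a, df_b = I - 1, J - 1
    df_ab = df_a * df_b
    df_err = I * J * (n - 1)
    ms_err = ss_err / df_err

    def _f(ss, df):
        if ms_err == 0:
            f = 0.0 if ss == 0 else np.inf
            p = 1.0 if ss == 0 else 0.0
        else:
            f = (ss / df) / ms_err
            p = float(sps.f.sf(f, df, df_err))
        return TestResult(statistic=float(f), p_value=p,
                          method="anova", df=(df, df_err))

    out = {"factor_a": _f(ss_a, df_a), "factor_b": _f(ss_b, df_b),
           "interaction": _f(ss_ab, df_ab)}
    out["interaction"].method = "anova_interaction"
    return out


def zscore_pca(matrix, group_labels, n_components: int = 2) -> PCAResult:
    """PCA of a z-scored descriptor matrix with group-dispersion metrics.

    Columns are standardized to mean 0, sd 1 (ddof=1); zero-variance columns
    are dropped with a warning. Components carry a deterministic sign (the
    largest-magnitude loading of each component is positive). Dispersion per
    group: mean Euclidean distance of the group's scores to the group
    centroid, and the within-group variance (sum of per-component ddof=1
    variances) in the retained space.
    """
    from sklearn.decomposition import PCA

    X = pd.DataFrame(matrix).astype(float)
    labels = list(group_labels)
    if X.shape[0] < 3:
        raise ValueError("insufficient samples for PCA (need >= 3 rows)")
    sd = X.std(ddof=1)
    dropped = list(X.columns[(sd == 0) | sd.isna()])
    if dropped:
        logger.warning("dropping zero-variance columns from PCA: %s", dropped)
        X = X.drop(columns=dropped)
        sd = sd.drop(index=dropped)
    Z = (X - X.mean()) / sd
    k = min(n_components, Z.shape[1], Z.shape[0])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Z.values)
    loadings = pca.components_.T  # (features x components), unit columns
    for c in range(k):
        j = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[j, c] < 0:
            loadings[:, c] = -loadings[:, c]
            scores[:, c] = -scores[:, c]
    comp_names = [f"PC{i + 1}" for i in range(k)]
    scores_df = pd.DataFrame(scores, index=X.index, columns=comp_names)
    load_df = pd.DataFrame(loadings, index=X.columns, columns=comp_names)
    dispersion = {}
    for g in dict.fromkeys(labels):
        mask = np.array([lab == g for lab in labels])
        pts = scores[mask]
        centroid = pts.mean(axis=0)
        dists = np.linalg.norm(pts - centroid, axis=1)
        var = float(pts.var(axis=0, ddof=1).sum()) if pts.shape[0] > 1 else 0.0
        dispersion[g] = {"mean_distance_to_centroid": float(dists.mean()),
                         "within_group_variance": var}
    return PCAResult(loadings=load_df,
                     explained_variance_ratio=pca.explained_variance_ratio_,
                     scores=scores_df, group_labels=labels,
                     dispersion=dispersion, dropped_columns=dropped)


REPORT_COLUMNS = (
    "descriptor", "mean_a", "sd_a", "mean_b", "sd_b",
    "shapiro_w_a", "shapiro_p_a", "shapiro_w_b", "shapiro_p_b",
    "welch_t", "welch_p", "mw_u", "mw_p", "mw_method", "cohens_d",
    "significant",
)


def _vectors_to_frame(group: list[DescriptorVector]) -> pd.DataFrame:
    rows = [v.as_row() for v in group]
    return pd.DataFrame(rows).set_index("structure_id").astype(float)


def compare_groups(group_a, group_b, alpha: float = 0.05,
                   label_a: str = "group_a", label_b: str = "group_b"):
    """Full per-descriptor comparison of two replicate groups.

    Groups are lists of :class:`DescriptorVector` or DataFrames with
    descriptor columns. Structures missing a descriptor are dropped pairwise
    for that row (logged). Returns (report DataFrame in REPORT_COLUMNS order,
    PCAResult or None if the pooled matrix is too small).
    """
    if isinstance(group_a, pd.DataFrame):
        df_a = group_a.astype(float)
    else:
        df_a = _vectors_to_frame(list(group_a))
    if isinstance(group_b, pd.DataFrame):
        df_b = group_b.astype(float)
    else:
        df_b = _vectors_to_frame(list(group_b))
    if df_a.empty or df_b.empty:
        raise ValueError("empty group")

    rows = []
    for name in DESCRIPTOR_NAMES:
        if name not in df_a.columns or name not in df_b.columns:
            continue
        a = df_a[name].dropna().values
        b = df_b[name].dropna().values
        n_drop = (len(df_a) - a.size) + (len(df_b) - b.size)
        if n_drop:
            logger.info("%s: dropped %d structures with missing values",
                        name, n_drop)
        row: dict = {"descriptor": name}
        if a.size and b.size:
            row["mean_a"], row["sd_a"] = a.mean(), a.std(ddof=1)
            row["mean_b"], row["sd_b"] = b.mean(), b.std(ddof=1)
        for suffix, x in (("a", a), ("b", b)):
            try:
                sh = shapiro_wilk(x)
                row[f"shapiro_w_{suffix}"] = sh.statistic
                row[f"shapiro_p_{suffix}"] = sh.p_value
            except ValueError:
                row[f"shapiro_w_{suffix}"] = np.nan
                row[f"shapiro_p_{suffix}"] = np.nan
        try:
            wt = welch_t(a, b)
            row["welch_t"], row["welch_p"] = wt.statistic, wt.p_value
        except ValueError:
            row["welch_t"] = row["welch_p"] = np.nan
        try:
            mw = mann_whitney(a, b)
            row["mw_u"], row["mw_p"] = mw.statistic, mw.p_value
            row["mw_method"] = mw.method
        except ValueError:
            row["mw_u"] = row["mw_p"] = np.nan
            row["mw_method"] = ""
        try:
            row["cohens_d"] = cohens_d_from_samples(a, b)
        except ValueError:
            row["cohens_d"] = np.nan
        p_vals = [row.get("welch_p"), row.get("mw_p")]
        p_vals = [p for p in p_vals if p is not None and np.isfinite(p)]
        row["significant"] = bool(p_vals and min(p_vals) < alpha)
        rows.append(row)
    report = pd.DataFrame(rows, columns=list(REPORT_COLUMNS))

    pooled = pd.concat([df_a, df_b])
    pooled = pooled.dropna(axis=1)
    labels = [label_a] * len(df_a) + [label_b] * len(df_b)
    pca = None
    if pooled.shape[0] >= 3 and pooled.shape[1] >= 2:
        try:
            pca = zscore_pca(pooled, labels)
        except ValueError as exc:
            logger.warning("PCA skipped: %s", exc)
    return report, pca


class GroupComparison:
    """Estimator form of the two-group battery.

    ``fit(X, y)`` takes a descriptor DataFrame (rows = structures) and a
    group-label vector with exactly two levels; fitted attributes are
    ``report_`` (per-descriptor statistics table), ``pca_`` and
    ``n_significant_``.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def get_params(self, deep: bool = True) -> dict:
        return {"alpha": self.alpha}

    def set_params(self, **params) -> "GroupComparison":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X: pd.DataFrame, y) -> "GroupComparison":
        labels = pd.Series(list(y), index=X.index)
        levels = list(dict.fromkeys(labels))
        if len(levels) != 2:
            raise ValueError(f"need exactly 2 group labels, got {levels}")
        a, b = levels
        self.report_, self.pca_ = compare_groups(
            X[labels == a], X[labels == b], alpha=self.alpha,
            label_a=str(a), label_b=str(b))
        self.classes_ = levels
        self.n_significant_ = int(self.report_["significant"].sum())
        return self
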