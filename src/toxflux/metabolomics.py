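"""Two-group MS feature-table preprocessing and significance analyses.

The pipeline mirrors standard metabolomics-suite practice for comparing
treated vs control intensity tables: impute missing values (half of the
global minimum positive intensity), drop up to a stated fraction of
near-constant features, normalize per platform (total-sum for direct-
injection ESI-MS, internal standard for GC-MS), Pareto-scale, then run the
statistical analyses whose 0/1 significance calls feed the majority vote:
Welch t-test with Benjamini-Hochberg correction, PCA loading thresholds,
and PLS-DA VIP thresholds with a label-permutation validation of class
separation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FeatureTable",
    "impute_missing",
    "filter_near_constant",
    "total_sum_normalize",
    "internal_standard_normalize",
    "pareto_scale",
    "preprocess",
    "ttest_fc_calls",
    "pca_calls",
    "plsda_vip_calls",
    "plsda_permutation_test",
]

GROUPS = ("control", "treated")


@dataclass(frozen=True)
class FeatureTable:
    """Feature x sample intensity matrix with two-group labels.

    ``intensities``: DataFrame, index = feature ids, columns = sample ids;
    NaN marks a missing measurement.  ``group_of`` maps each sample to
    'control' or 'treated'.  ``platform`` is 'ESI' or 'GC' and selects the
    normalization in :func:`preprocess`.
    """

    intensities: pd.DataFrame
    group_of: dict[str, str]
    platform: str = "ESI"

    def __post_init__(self) -> None:
        missing = [s for s in self.intensities.columns if s not in self.group_of]
        if missing:
            raise ValueError(f"samples without group label: {missing}")

    @property
    def features(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)

    def group_columns(self, group: str) -> list[str]:
        return [s for s in self.samples if self.group_of[s] == group]

    def with_values(self, intensities: pd.DataFrame) -> "FeatureTable":
        return replace(self, intensities=intensities)

    def group_vector(self) -> np.ndarray:
        """0/1 response (control=0, treated=1) in column order."""
        return np.array([1.0 if self.group_of[s] == "treated" else 0.0 for s in self.samples])


def impute_missing(table: FeatureTable, per_feature: bool = False) -> FeatureTable:
    """Replace missing entries by half of the minimum positive intensity.

    The minimum is global over the whole table by default (``per_feature``
    switches to each feature's own minimum positive value).
    """
    X = table.intensities
    vals = X.to_numpy(dtype=float)
    if np.nanmin(vals) < 0 if np.isfinite(vals).any() else False:
        raise ValueError("raw intensities must be nonnegative")
    positives = vals[np.isfinite(vals) & (vals > 0)]
    if positives.size == 0:
        raise ValueError("table has no positive intensity; cannot impute")
    if per_feature:
        fill = X.where(X > 0).min(axis=1).fillna(positives.min()) / 2.0
        out = X.apply(lambda col: col.fillna(fill))
    else:
        out = X.fillna(positives.min() / 2.0)
    return table.with_values(out)


def _variability_scores(X: pd.DataFrame) -> pd.DataFrame:
    iqr = X.quantile(0.75, axis=1) - X.quantile(0.25, axis=1)
    var = X.var(axis=1, ddof=1)
    return pd.DataFrame({"iqr": iqr, "var": var})


def filter_near_constant(
    table: FeatureTable, fraction: float = 0.05, protect: set[str] | None = None
) -> FeatureTable:
    """Drop the floor(fraction * n) least variable features ("up to 5%").

    Variability is the interquartile range across samples, with variance and
    then input order as tie-breaks; surviving features keep their order.
    ``protect`` lists features never dropped (an internal standard is
    near-constant by design but must survive to the normalization stage).
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    X = table.intensities
    k = int(np.floor(fraction * len(X)))
    if k == 0:
        return table
    scores = _variability_scores(X)
    scores["order"] = np.arange(len(X))
    if protect:
        scores = scores.drop(index=[f for f in protect if f in scores.index])
    drop = scores.sort_values(["iqr", "var", "order"], kind="stable").index[:k]
    return table.with_values(X.drop(index=drop))


def total_sum_normalize(table: FeatureTable) -> FeatureTable:
    """Rescale each sample so its intensities sum to 100 (percent of the
    spectrum's total signal)."""
    X = table.intensities
    totals = X.sum(axis=0, skipna=True)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    return table.with_values(X.div(totals, axis=1) * 100.0)


def internal_standard_normalize(table: FeatureTable, standard_feature: str) -> FeatureTable:
    """Divide every intensity by its sample's internal-standard intensity and
    drop the standard feature from the output."""
    X = table.intensities
    if standard_feature not in X.index:
        raise KeyError(f"internal standard {standard_feature!r} not in table")
    std = X.loc[standard_feature]
    bad = std.index[~(std > 0) | std.isna()].tolist()
    if bad:
        raise ValueError(f"internal standard missing or nonpositive in sample(s): {bad}")
    return table.with_values(X.drop(index=standard_feature).div(std, axis=1))


def pareto_scale(table: FeatureTable) -> FeatureTable:
    """Per feature: (x - mean) / sqrt(sd); zero-sd features are centered only.

    Intermediate between mean-centering and unit-variance scaling; large
    intensities keep some leverage without drowning small ones.
    """
    X = table.intensities
    if X.shape[1] < 2:
        raise ValueError("Pareto scaling needs at least two samples")
    mean = X.mean(axis=1)
    sd = X.std(axis=1, ddof=1)
    denom = np.sqrt(sd).replace(0.0, 1.0)
    return table.with_values(X.sub(mean, axis=0).div(denom, axis=0))


def preprocess(
    table: FeatureTable,
    filter_fraction: float = 0.05,
    standard_feature: str | None = None,
    _stage_log: list | None = None,
) -> dict[str, FeatureTable]:
    """Run the full preprocessing chain in its fixed order.

    impute -> near-constant filter -> normalize (total-sum for ESI,
    internal standard for GC) -> Pareto scale.  Returns every stage keyed by
    name; 'scaled' feeds the multivariate analyses, 'normalized' the
    univariate ones.
    """
    stages: dict[str, FeatureTable] = {"raw": table}

    def log(name: str, t: FeatureTable) -> FeatureTable:
        stages[name] = t
        if _stage_log is not None:
            _stage_log.append(name)
        return t

    protect = {standard_feature} if standard_feature else None
    t = log("imputed", impute_missing(table))
    t = log("filtered", filter_near_constant(t, filter_fraction, protect=protect))
    if table.platform.upper() == "GC":
        if standard_feature is None:
            raise ValueError("GC tables require an internal-standard feature id")
        t = log("normalized", internal_standard_normalize(t, standard_feature))
    else:
        t = log("normalized", total_sum_normalize(t))
    log("scaled", pareto_scale(t))
    return stages


# --- significance analyses ---------------------------------------------------


def _group_split(table: FeatureTable) -> tuple[np.ndarray, np.ndarray]:
    a = table.intensities[table.group_columns("control")].to_numpy(dtype=float)
    b = table.intensities[table.group_columns("treated")].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs at least two samples")
    return a, b


def ttest_fc_calls(
    table: FeatureTable, alpha: float = 0.05, equal_var: bool = False
) -> pd.DataFrame:
    """Per-feature two-sample t-test (Welch by default) with BH adjustment.

    Runs on the normalized (pre-scaling) table.  MS intensities are
    approximately log-normal, so the test compares log2 intensities, where
    replicate noise is close to normal; ``log2_fc`` is the difference of the
    group means on that scale (the log2 ratio of geometric means).  A
    feature is significant when its BH-adjusted p is below ``alpha``.
    Degenerate features (zero variance in both groups, equal means) get
    p = 1; nonpositive intensities (possible only before imputation) are
    omitted from the test.
    """
    ctrl, trt = _group_split(table)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_c = np.log2(np.where(ctrl > 0, ctrl, np.nan))
        log_t = np.log2(np.where(trt > 0, trt, np.nan))
    res = stats.ttest_ind(log_t, log_c, axis=1, equal_var=equal_var, nan_policy="omit")
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    log2_fc = np.nanmean(log_t, axis=1) - np.nanmean(log_c, axis=1)
    return pd.DataFrame(
        {
            "p": p,
            "p_adj": p_adj,
            "log2_fc": log2_fc,
            "significant": p_adj < alpha,
        },
        index=table.intensities.index,
    )


def pca_calls(
    table: FeatureTable,
    loading_threshold: float = 0.1,
    components: Sequence[int] = (1,),
) -> dict:
    """PCA on the Pareto-scaled matrix; a feature is significant when any
    selected component's |loading| exceeds the threshold.

    Loadings are the unit-norm principal axes.  Returns calls, loadings,
    scores and explained-variance fractions.
    """
    X = table.intensities.to_numpy(dtype=float).T  # samples x features
    n_comp = max(components)
    max_rank = min(X.shape[0] - 1, X.shape[1])
    if n_comp > max_rank:
        raise ValueError(f"requested component {n_comp} exceeds matrix rank {max_rank}")
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(X)
    loadings = pd.DataFrame(
        pca.components_.T,
        index=table.intensities.index,
        columns=[f"PC{i + 1}" for i in range(n_comp)],
    )
    sig = np.zeros(len(loadings), dtype=bool)
    for c in components:
        sig |= loadings[f"PC{c}"].abs().to_numpy() > loading_threshold
    calls = pd.DataFrame({"significant": sig}, index=loadings.index)
    return {
        "calls": calls,
        "loadings": loadings,
        "scores": scores,
        "explained_variance_ratio": pca.explained_variance_ratio_,
    }


def _fit_pls(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSRegression:
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, y.reshape(-1, 1))
    return pls


def _vip(pls: PLSRegression, upto: int) -> np.ndarray:
    """VIP over the first ``upto`` latent components.

    Standard weighted-sum-of-squares definition: the y-variance explained
    per component weights each feature's squared normalized weight; squared
    VIPs average to 1 over features by construction.
    """
    T = pls.x_scores_[:, :upto]
    W = pls.x_weights_[:, :upto]
    Q = pls.y_loadings_[:, :upto]
    p = W.shape[0]
    ssy = np.einsum("ij,ij->j", T, T) * (Q[0] ** 2)
    wnorm2 = (W**2) / np.sum(W**2, axis=0)
    return np.sqrt(p * (wnorm2 @ ssy) / ssy.sum())


def plsda_vip_calls(
    table: FeatureTable,
    vip_threshold: float = 1.0,
    components: Sequence[int] = (1,),
) -> dict:
    """PLS-DA variable importance on the scaled matrix against group labels.

    VIP is computed cumulatively for each requested component count; a
    feature is significant when VIP exceeds the threshold for any of them.
    """
    y = table.group_vector()
    if len(set(y)) < 2:
        raise ValueError("PLS-DA needs both groups present")
    X = table.intensities.to_numpy(dtype=float).T
    n_comp = max(components)
    pls = _fit_pls(X, y, n_comp)
    vips = pd.DataFrame(
        {f"VIP{k}": _vip(pls, k) for k in components},
        index=table.intensities.index,
    )
    sig = (vips > vip_threshold).any(axis=1)
    calls = pd.DataFrame({"significant": sig}, index=vips.index)
    return {"calls": calls, "vip": vips, "scores": pls.x_scores_}


def _bw_ratio(scores: np.ndarray, y: np.ndarray) -> float:
    """Between-group over within-group sum of squares of LV1 scores."""
    t = scores[:, 0]
    grand = t.mean()
    between = within = 0.0
    for g in np.unique(y):
        tg = t[y == g]
        between += len(tg) * (tg.mean() - grand) ** 2
        within += ((tg - tg.mean()) ** 2).sum()
    return between / within if within > 0 else np.inf


def plsda_permutation_test(
    table: FeatureTable,
    n_perm: int = 1000,
    seed: int | None = None,
    n_components: int = 1,
) -> dict:
    """Label-permutation validation of PLS-DA class separation.

    The statistic is the between/within sum-of-squares ratio (B/W) of the
    first latent-variable scores; p = (1 + #{null >= observed}) /
    (1 + n_perm).  Permutations that reproduce the original partition
    (identical labels or the two groups swapped) are redrawn: they would
    duplicate the observed statistic rather than sample the null, and with
    them a perfectly separated data set could never reach the attainable
    floor p = 1/(1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = table.group_vector()
    if len(set(y)) < 2:
        raise ValueError("permutation test needs both groups present")
    X = table.intensities.to_numpy(dtype=float).T
    observed = _bw_ratio(_fit_pls(X, y, n_components).x_scores_, y)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        yp = rng.permutation(y)
        while np.array_equal(yp, y) or np.array_equal(yp, 1 - y):
            yp = rng.permutation(y)
        null[i] = _bw_ratio(_fit_pls(X, yp, n_components).x_scores_, yp)
    p = (1 + int((null >= observed).sum())) / (1 + n_perm)
    return {"p_value": p, "observed": observed, "null": null}
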