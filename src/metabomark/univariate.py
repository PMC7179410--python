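"""Per-feature two-group screening and the clustered heat-map matrix.

The univariate track asks, feature by feature, whether the two biological
groups differ in mean abundance (pooled-variance Student's t-test, two-sided,
raw p < alpha by default — no multiple-testing correction, though BH-FDR is
available).  Significant features feed a z-scored, hierarchically clustered
matrix suitable for heat-map rendering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io import FeatureTable
from .preprocessing import impute_half_min


class UnivariateError(ValueError):
    pass


@dataclass
class UnivariateResult:
    feature_id: str
    t_statistic: float
    p_value: float
    log2_fold_change: float
    significant: bool


def t_test_screen(
    table: FeatureTable,
    alpha: float = 0.05,
    log2: bool = False,
    welch: bool = False,
    fdr: bool = False,
) -> list[UnivariateResult]:
    """Two-sample t-test per feature between the two biological groups.

    Runs on half-minimum-imputed raw abundances (``log2=True`` tests
    log2-transformed values instead).  ``welch=True`` drops the equal-variance
    assumption; ``fdr=True`` flags significance on Benjamini-Hochberg adjusted
    p-values instead of raw ones.  Features that are constant and identical in
    both groups get t = 0, p = 1 with a warning.
    """
    labels = table.group_labels()
    if len(labels) != 2:
        raise UnivariateError(f"expected two biological groups, got {labels}")
    g_a, g_b = labels
    imputed = impute_half_min(table).abundances
    a = imputed.loc[(table.groups == g_a).values].to_numpy(dtype=float)
    b = imputed.loc[(table.groups == g_b).values].to_numpy(dtype=float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise UnivariateError("each group needs at least 2 samples")

    vals_a, vals_b = (np.log2(a), np.log2(b)) if log2 else (a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(vals_a, vals_b, axis=0, equal_var=not welch)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} feature(s) with zero pooled variance; p set to 1"
        )
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate, 1.0, p)

    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(a.mean(axis=0) / b.mean(axis=0))

    p_flag = p
    if fdr:
        p_flag = stats.false_discovery_control(p, method="bh")
    return [
        UnivariateResult(
            feature_id=f,
            t_statistic=float(t[j]),
            p_value=float(p[j]),
            log2_fold_change=float(lfc[j]),
            significant=bool(p_flag[j] < alpha),
        )
        for j, f in enumerate(table.feature_ids)
    ]


def results_frame(results: list[UnivariateResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "t_statistic": [r.t_statistic for r in results],
            "p_value": [r.p_value for r in results],
            "log2_fold_change": [r.log2_fold_change for r in results],
            "significant": [r.significant for r in results],
        }
    ).set_index("feature_id")


@dataclass
class HeatmapMatrix:
    """Z-scored significant-feature matrix with clustering orders.

    Rows are significant features (z-scored across non-QC samples), columns
    are the biological samples.  ``row_order``/``col_order`` are leaf orders
    of average-linkage hierarchical clustering on Euclidean distance.
    """

    z_values: pd.DataFrame
    row_order: list[int]
    col_order: list[int]
    row_linkage: np.ndarray
    col_linkage: np.ndarray


def heatmap_matrix(
    table: FeatureTable, results: list[UnivariateResult]
) -> HeatmapMatrix:
    """Build the clustered heat-map matrix of significant features."""
    sig = [r.feature_id for r in results if r.significant]
    if len(sig) < 2:
        raise UnivariateError("need at least 2 significant features to cluster")
    bio = impute_half_min(table.biological())
    x = bio.abundances[sig].to_numpy(dtype=float).T  # features x samples
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mean) / sd

    row_link = hierarchy.linkage(pdist(z, metric="euclidean"), method="average")
    col_link = hierarchy.linkage(pdist(z.T, metric="euclidean"), method="average")
    return HeatmapMatrix(
        z_values=pd.DataFrame(z, index=sig, columns=bio.sample_ids),
        row_order=[int(i) for i in hierarchy.leaves_list(row_link)],
        col_order=[int(i) for i in hierarchy.leaves_list(col_link)],
        row_linkage=row_link,
        col_linkage=col_link,
    )
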