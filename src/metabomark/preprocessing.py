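"""Feature filtering and scaling applied before any statistics.

Two sequential filters clean the aligned table before modelling:

1. **QC-RSD filter** — a feature whose relative standard deviation across the
   pooled QC injections exceeds 15% was not measured stably and is removed.
2. **80% rule** — a feature must be detected in at least 80% of the samples of
   at least one biological group; otherwise it is too sparse to model.

Multivariate models additionally use **Pareto scaling**: mean-centring
followed by division by the square root of each feature's standard deviation,
a compromise between no scaling (large peaks dominate) and unit-variance
scaling (noise features are inflated).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import FeatureTable


class PreprocessingError(ValueError):
    pass


@dataclass
class FilterReport:
    """Bookkeeping for one filtering pass; counts satisfy
    ``n_input - n_removed_qc_rsd - n_removed_80pct == n_retained``."""

    n_input: int
    n_removed_qc_rsd: int = 0
    n_removed_80pct: int = 0
    removed_qc_rsd_ids: list[str] = field(default_factory=list)
    removed_80pct_ids: list[str] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed_qc_rsd - self.n_removed_80pct

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed_qc_rsd": self.n_removed_qc_rsd,
            "n_removed_80pct": self.n_removed_80pct,
            "n_retained": self.n_retained,
            "removed_qc_rsd_ids": self.removed_qc_rsd_ids,
            "removed_80pct_ids": self.removed_80pct_ids,
        }


def impute_half_min(table: FeatureTable) -> FeatureTable:
    """Replace missing cells with half the feature's minimum observed value.

    The conventional below-detection-limit substitute in metabolomics.  A
    feature with no observed value at all is filled with 0.
    """
    ab = table.abundances.copy()
    fill = ab.min(axis=0, skipna=True) / 2.0
    fill = fill.fillna(0.0)
    ab = ab.fillna(fill)
    return FeatureTable(
        abundances=ab,
        groups=table.groups,
        feature_mz=table.feature_mz,
        feature_rt=table.feature_rt,
    )


def qc_rsd(table: FeatureTable) -> pd.Series:
    """Per-feature RSD (%) over the QC injections: 100 * sd(n-1) / mean.

    Missing QC cells are imputed with half the feature minimum first.
    Features whose QC mean is 0 get RSD = +inf (undefined implies unstable).
    """
    qc_mask = table.qc_mask()
    if qc_mask.sum() < 2:
        raise PreprocessingError("QC-RSD filter needs at least 2 QC samples")
    qc = impute_half_min(table).abundances.loc[qc_mask.values]
    mean = qc.mean(axis=0)
    sd = qc.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = 100.0 * sd / mean
    rsd[mean == 0] = np.inf
    return rsd


def qc_rsd_filter(
    table: FeatureTable, threshold_pct: float = 15.0
) -> tuple[FeatureTable, FilterReport]:
    """Remove features with QC RSD above ``threshold_pct`` (default 15%)."""
    rsd = qc_rsd(table)
    removed = list(rsd.index[rsd > threshold_pct])
    keep = [f for f in table.feature_ids if f not in set(removed)]
    report = FilterReport(
        n_input=table.n_features,
        n_removed_qc_rsd=len(removed),
        removed_qc_rsd_ids=removed,
    )
    return table.select_features(keep), report


def presence_fraction(table: FeatureTable) -> pd.DataFrame:
    """Fraction of samples in which each feature is present, per biological group.

    "Present" means non-missing and strictly positive (vendor exports use 0 and
    blank interchangeably for undetected).  QC samples are excluded.
    """
    labels = table.group_labels()
    if len(labels) != 2:
        raise PreprocessingError(f"expected two biological groups, got {labels}")
    out = {}
    for g in labels:
        rows = table.abundances.loc[(table.groups == g).values]
        if rows.empty:
            raise PreprocessingError(f"group {g!r} has no samples")
        out[g] = (rows.notna() & (rows > 0)).mean(axis=0)
    return pd.DataFrame(out)


def eighty_percent_rule(
    table: FeatureTable, threshold: float = 0.80
) -> tuple[FeatureTable, FilterReport]:
    """Retain a feature iff it is present in >= ``threshold`` of the samples of
    at least one biological group (boundary inclusive)."""
    frac = presence_fraction(table)
    keep_mask = (frac >= threshold).any(axis=1)
    removed = list(frac.index[~keep_mask])
    keep = [f for f in table.feature_ids if keep_mask[f]]
    report = FilterReport(
        n_input=table.n_features,
        n_removed_80pct=len(removed),
        removed_80pct_ids=removed,
    )
    return table.select_features(keep), report


def filter_features(
    table: FeatureTable,
    rsd_threshold_pct: float = 15.0,
    presence_threshold: float = 0.80,
) -> tuple[FeatureTable, FilterReport]:
    """Both filters in order (QC-RSD first, then the 80% rule), one report."""
    t1, rep1 = qc_rsd_filter(table, rsd_threshold_pct)
    t2, rep2 = eighty_percent_rule(t1, presence_threshold)
    report = FilterReport(
        n_input=table.n_features,
        n_removed_qc_rsd=rep1.n_removed_qc_rsd,
        n_removed_80pct=rep2.n_removed_80pct,
        removed_qc_rsd_ids=rep1.removed_qc_rsd_ids,
        removed_80pct_ids=rep2.removed_80pct_ids,
    )
    return t2, report


@dataclass
class ScaledMatrix:
    """A Pareto-scaled analysis matrix (samples x features).

    ``values[i, j] = (x[i, j] - centers[j]) / scale_factors[j]`` with
    ``scale_factors = sqrt(sd)``.  Constant columns are dropped (their scale is
    undefined), with a warning.
    """

    values: np.ndarray
    centers: np.ndarray
    scale_factors: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str] | None = None


def pareto_scale(
    matrix: np.ndarray | pd.DataFrame,
    feature_ids: list[str] | None = None,
    sample_ids: list[str] | None = None,
) -> ScaledMatrix:
    """Pareto scaling: (x - mean) / sqrt(sd), sd with n-1 denominator.

    Constant columns (sd == 0) are dropped with a warning; if every column is
    constant the input is degenerate and an error is raised.
    """
    if isinstance(matrix, pd.DataFrame):
        feature_ids = feature_ids or list(matrix.columns)
        sample_ids = sample_ids or list(matrix.index)
        matrix = matrix.to_numpy(dtype=float)
    else:
        matrix = np.asarray(matrix, dtype=float)
        if feature_ids is None:
            feature_ids = [f"x{j}" for j in range(matrix.shape[1])]
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise PreprocessingError("Pareto scaling needs a 2-D matrix with >= 2 rows")
    if np.isnan(matrix).any():
        raise PreprocessingError("impute missing values before scaling")

    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise PreprocessingError("all columns are constant; nothing to scale")
    if not keep.all():
        dropped = [f for f, k in zip(feature_ids, keep) if not k]
        warnings.warn(f"dropping {len(dropped)} constant feature(s): {dropped[:5]}...")
    scale = np.sqrt(sd[keep])
    values = (matrix[:, keep] - mean[keep]) / scale
    return ScaledMatrix(
        values=values,
        centers=mean[keep],
        scale_factors=scale,
        feature_ids=[f for f, k in zip(feature_ids, keep) if k],
        sample_ids=sample_ids,
    )
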