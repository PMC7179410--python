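"""Synthetic two-group LC-MS feature tables with known ground truth.

Emulates the study design the pipeline targets: two groups of plant batches
(52 vs 34 by default) plus pooled QC injections, log-normally distributed
feature abundances, a small set of planted group-discriminant markers, a
subset of analytically unstable features (QC RSD above the 15% filter), a
subset of sparse features that fail the 80% presence rule, and completely
random missingness elsewhere.

All randomness flows through one ``numpy.random.default_rng(seed)`` instance,
so generation is a pure function of the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import FeatureTable

GROUP_A = "group_a"
GROUP_B = "group_b"
QC = "qc"

#: QC coefficient of variation planted for "unstable" features; chosen so the
#: empirical RSD over n_qc=8 replicates exceeds the 15% filter threshold with
#: probability well above 0.95.
UNSTABLE_QC_CV = 0.40

#: Fraction of samples *per biological group* set missing for planted sparse
#: features (> 20%, so the feature fails the 80% rule in both groups).
SPARSE_MISSING_FRACTION = 0.30

#: Range of feature baseline intensities on the log2 scale (typical dynamic
#: range of normalised LC-MS abundances).
BASELINE_LOG2_RANGE = (14.0, 20.0)


class SyntheticConfigError(ValueError):
    """Invalid synthetic-data configuration."""


@dataclass
class SyntheticConfig:
    """Study-design parameters of the simulated experiment.

    Defaults mirror the target design: 52 + 34 biological batches, 8 pooled
    QC injections, 400 aligned features of which 10 are true markers at a
    log2 fold change of 2, 30% biological CV, 8% QC technical CV, 5% random
    missingness, 10% analytically unstable features and 5% sparse features.
    """

    n_group_a: int = 52
    n_group_b: int = 34
    n_qc: int = 8
    n_features: int = 400
    n_markers: int = 10
    log2_fold_change: float = 2.0
    biological_cv: float = 0.30
    qc_cv: float = 0.08
    missing_rate: float = 0.05
    frac_high_qc_rsd: float = 0.10
    frac_sparse: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_group_a, self.n_group_b, self.n_qc, self.n_features) < 1:
            raise SyntheticConfigError("sample/feature counts must be positive")
        if not 0 <= self.n_markers <= self.n_features:
            raise SyntheticConfigError("n_markers must be in [0, n_features]")
        if not (0 < self.biological_cv < 1 and 0 < self.qc_cv < 1):
            raise SyntheticConfigError("CVs must be in (0, 1)")
        for name in ("missing_rate", "frac_high_qc_rsd", "frac_sparse"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise SyntheticConfigError(f"{name} must be in [0, 1)")
        n_special = self.n_markers + int(self.frac_high_qc_rsd * self.n_features) + int(
            self.frac_sparse * self.n_features
        )
        if n_special > self.n_features:
            raise SyntheticConfigError(
                "markers + unstable + sparse features exceed n_features"
            )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Ground truth of a generated table (the planted feature roles).

    The three lists are disjoint: markers are never planted as unstable or
    sparse, so filtering cannot legitimately remove a true marker.
    """

    marker_feature_ids: list[str] = field(default_factory=list)
    unstable_feature_ids: list[str] = field(default_factory=list)
    sparse_feature_ids: list[str] = field(default_factory=list)


def _sigma_log2(cv: float) -> float:
    """log2-scale normal sd giving a natural-scale coefficient of variation cv."""
    return np.sqrt(np.log1p(cv**2)) / np.log(2)


def generate(config: SyntheticConfig) -> tuple[FeatureTable, SyntheticTruth]:
    """Generate one feature table plus its ground truth.

    Log2 intensity of biological sample *s*, feature *f* is
    ``baseline_f + effect_{g(s),f} + eps`` with ``eps ~ N(0, sigma(biological_cv))``;
    marker features get an antisymmetric group effect of ±log2_fold_change/2
    (group A up).  QC injections replicate the empirical pooled mean profile
    with technical CV ``qc_cv`` (``UNSTABLE_QC_CV`` for planted unstable
    features).  Sparse features are blanked in 30% of the samples of *both*
    groups; all other biological cells are blanked completely at random with
    probability ``missing_rate``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    p = config.n_features
    n_a, n_b, n_qc = config.n_group_a, config.n_group_b, config.n_qc
    n_bio = n_a + n_b

    width = len(str(p))
    feature_ids = [f"F{i + 1:0{width}d}" for i in range(p)]
    sample_ids = (
        [f"A{i + 1:03d}" for i in range(n_a)]
        + [f"B{i + 1:03d}" for i in range(n_b)]
        + [f"QC{i + 1:02d}" for i in range(n_qc)]
    )
    groups = pd.Series(
        [GROUP_A] * n_a + [GROUP_B] * n_b + [QC] * n_qc, index=sample_ids, name="group"
    )

    # disjoint feature roles, drawn in one permutation
    n_unstable = int(config.frac_high_qc_rsd * p)
    n_sparse = int(config.frac_sparse * p)
    perm = rng.permutation(p)
    marker_idx = np.sort(perm[: config.n_markers])
    unstable_idx = np.sort(perm[config.n_markers : config.n_markers + n_unstable])
    sparse_idx = np.sort(
        perm[config.n_markers + n_unstable : config.n_markers + n_unstable + n_sparse]
    )

    baseline = rng.uniform(*BASELINE_LOG2_RANGE, size=p)
    effect = np.zeros((2, p))  # rows: group A, group B
    effect[0, marker_idx] = +config.log2_fold_change / 2
    effect[1, marker_idx] = -config.log2_fold_change / 2

    sigma_bio = _sigma_log2(config.biological_cv)
    log2_bio = np.empty((n_bio, p))
    log2_bio[:n_a] = baseline + effect[0]
    log2_bio[n_a:] = baseline + effect[1]
    log2_bio += rng.normal(0.0, sigma_bio, size=(n_bio, p))
    bio = np.exp2(log2_bio)

    # QC: multiplicative log-normal noise with mean 1 around the pooled mean
    pooled_mean = bio.mean(axis=0)
    sigma_qc = np.full(p, np.sqrt(np.log1p(config.qc_cv**2)))
    sigma_qc[unstable_idx] = np.sqrt(np.log1p(UNSTABLE_QC_CV**2))
    qc_noise = np.exp(
        rng.normal(0.0, 1.0, size=(n_qc, p)) * sigma_qc - 0.5 * sigma_qc**2
    )
    qc = pooled_mean * qc_noise

    # missingness: MCAR over biological cells, then planted sparsity
    missing = rng.random((n_bio, p)) < config.missing_rate
    for j in sparse_idx:
        for lo, hi in ((0, n_a), (n_a, n_bio)):
            n_g = hi - lo
            k = int(np.ceil(SPARSE_MISSING_FRACTION * n_g))
            rows = rng.choice(n_g, size=k, replace=False) + lo
            missing[rows, j] = True
    bio[missing] = np.nan

    abundances = pd.DataFrame(
        np.vstack([bio, qc]), index=sample_ids, columns=feature_ids
    )
    abundances.index.name = "sample_id"
    abundances.columns.name = None
    mz = pd.Series(
        np.round(rng.uniform(100.0, 1200.0, size=p), 4), index=feature_ids, name="mz"
    )
    rt = pd.Series(
        np.round(rng.uniform(0.5, 30.0, size=p), 2), index=feature_ids, name="rt"
    )
    table = FeatureTable(abundances=abundances, groups=groups, feature_mz=mz, feature_rt=rt)
    truth = SyntheticTruth(
        marker_feature_ids=[feature_ids[i] for i in marker_idx],
        unstable_feature_ids=[feature_ids[i] for i in unstable_idx],
        sparse_feature_ids=[feature_ids[i] for i in sparse_idx],
    )
    return table, truth


@dataclass
class RecoveryReport:
    sensitivity: float
    false_discovery_proportion: float
    n_selected: int
    n_markers: int
    true_positives: list[str]
    false_positives: list[str]


def truth_recovery_report(
    truth: SyntheticTruth, selected: list[str], universe: list[str] | None = None
) -> RecoveryReport:
    """Score a marker selection against the planted truth.

    sensitivity = |selected ∩ markers| / |markers|;
    FDP = |selected \\ markers| / max(1, |selected|).
    """
    if universe is not None:
        unknown = set(selected) - set(universe)
        if unknown:
            raise ValueError(f"selected ids outside the feature universe: {sorted(unknown)}")
    markers = set(truth.marker_feature_ids)
    sel = list(dict.fromkeys(selected))  # de-dup, keep order
    tp = [s for s in sel if s in markers]
    fp = [s for s in sel if s not in markers]
    sensitivity = len(tp) / len(markers) if markers else float("nan")
    fdp = len(fp) / max(1, len(sel))
    return RecoveryReport(
        sensitivity=sensitivity,
        false_discovery_proportion=fdp,
        n_selected=len(sel),
        n_markers=len(markers),
        true_positives=tp,
        false_positives=fp,
    )
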