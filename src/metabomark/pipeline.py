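"""End-to-end marker-screening pipeline.

Runs the stages in the study's order — simulate (or load) → QC-RSD filter →
80% rule → univariate t-test screen → Pareto scaling → PCA → OPLS-DA with
VIP > 1 selection (on all filtered features, in parallel with the univariate
track) → iterative random-forest refinement → final-model evaluation — and
persists every intermediate plus a deterministic JSON run report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import chemometrics, preprocessing, rf_selection, univariate
from .io import FeatureTable, read_feature_table, write_feature_table
from .synthetic import SyntheticConfig, generate, truth_recovery_report

logger = logging.getLogger("metabomark.pipeline")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """All stage thresholds plus the data source and global seed.

    Defaults are the reference settings of the workflow: RSD 15%, presence
    0.80, alpha 0.05, VIP 1.0, 100 iterations x 500 trees, top-1 frequency 4,
    200 permutations, 7-fold CV.
    """

    # data source: either paths or a synthetic config
    input_table: str | None = None
    input_metadata: str | None = None
    synthetic: SyntheticConfig | None = None
    # stage thresholds
    rsd_threshold_pct: float = 15.0
    presence_threshold: float = 0.80
    alpha: float = 0.05
    vip_threshold: float = 1.0
    n_components_pca: int = 7
    k_orth: int | str = "auto"
    cv_folds: int = 7
    n_permutations: int = 200
    n_iterations: int = 100
    n_trees: int = 500
    min_frequency: int = 4
    seed: int = 0
    output_dir: str = "metabomark_run"

    def validate(self) -> None:
        if (self.input_table is None) == (self.synthetic is None):
            raise PipelineError("provide either input paths or a synthetic config")
        if not 0 < self.presence_threshold <= 1:
            raise PipelineError("presence_threshold must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise PipelineError("alpha must be in (0, 1)")
        for name in ("n_iterations", "n_trees", "cv_folds", "min_frequency"):
            if getattr(self, name) < 1:
                raise PipelineError(f"{name} must be positive")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                logger.info("stage %s", name)
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run report."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    def save_df(df: pd.DataFrame, name: str) -> None:
        df.to_csv(outdir / name)
        manifest.append(name)

    # -- data --------------------------------------------------------------
    truth = None
    if config.synthetic is not None:
        table, truth = _stage("simulate")(generate)(config.synthetic)
        write_feature_table(table, outdir / "feature_table.csv", outdir / "metadata.yaml")
        manifest += ["feature_table.csv", "metadata.yaml"]
        (outdir / "truth.json").write_text(json.dumps(truth.__dict__, indent=1))
        manifest.append("truth.json")
    else:
        table = _stage("load")(read_feature_table)(
            config.input_table, config.input_metadata
        )

    # -- filtering ---------------------------------------------------------
    filtered, report = _stage("filter")(preprocessing.filter_features)(
        table, config.rsd_threshold_pct, config.presence_threshold
    )
    (outdir / "filter_report.json").write_text(json.dumps(report.to_dict(), indent=1))
    manifest.append("filter_report.json")

    # -- univariate track ---------------------------------------------------
    results = _stage("univariate")(univariate.t_test_screen)(filtered, config.alpha)
    uni_frame = univariate.results_frame(results)
    save_df(uni_frame, "univariate.csv")
    n_significant = int(uni_frame["significant"].sum())
    if n_significant >= 2:
        hm = _stage("heatmap")(univariate.heatmap_matrix)(filtered, results)
        save_df(hm.z_values, "heatmap_z.csv")
        (outdir / "heatmap_orders.json").write_text(json.dumps(
            {"row_order": hm.row_order, "col_order": hm.col_order}, indent=1
        ))
        manifest.append("heatmap_orders.json")

    # -- multivariate track --------------------------------------------------
    bio = preprocessing.impute_half_min(filtered.biological())
    scaled = preprocessing.pareto_scale(bio.abundances)

    n_pcs = min(config.n_components_pca, bio.n_samples - 1, len(scaled.feature_ids))
    pca = _stage("pca")(chemometrics.fit_pca)(scaled, n_pcs, config.cv_folds)

    y = bio.groups.to_numpy()
    model = chemometrics.OPLSDA(scaled, y)
    opls = _stage("oplsda")(model.fit)(k_orth=config.k_orth, cv_folds=config.cv_folds)
    save_df(opls.vip.to_frame(), "vip.csv")
    save_df(opls.s_plot, "s_plot.csv")

    perm_summary = None
    if config.n_permutations >= 20:
        perm = _stage("permutation")(model.permutation_test)(
            k_orth=opls.k_orth,
            cv_folds=config.cv_folds,
            n_permutations=config.n_permutations,
            seed=config.seed,
        )
        perm_summary = {
            "n_permutations": perm.n_permutations,
            "r2_intercept": round(perm.r2_intercept, 4),
            "q2_intercept": round(perm.q2_intercept, 4),
            "empirical_p_q2": round(perm.empirical_p_q2(), 6),
        }

    vip_features = opls.vip_selection(config.vip_threshold)
    if len(vip_features) < 2:
        raise PipelineError("fewer than 2 features passed the VIP threshold")

    # -- iterative RF refinement ---------------------------------------------
    selector = rf_selection.RFMarkerSelector(
        bio.abundances[vip_features], y, feature_ids=vip_features
    )
    rf = _stage("rfselect")(selector.fit)(
        n_iterations=config.n_iterations,
        n_trees=config.n_trees,
        min_frequency=config.min_frequency,
        seed=config.seed,
    )
    save_df(rf.log.to_frame(), "rf_rankings.csv")
    save_df(rf.cumulative, "rf_cumulative_topn.csv")

    report_dict = {
        "config": _config_dict(config),
        "n_input": table.n_features,
        "n_retained": report.n_retained,
        "n_removed_qc_rsd": report.n_removed_qc_rsd,
        "n_removed_80pct": report.n_removed_80pct,
        "n_significant": n_significant,
        "pca": {
            "n_components": pca.n_components,
            "r2x_cum": round(pca.r2x_cum, 4),
            "q2_cum": round(pca.q2_cum, 4),
        },
        "oplsda": {
            "k_orth": opls.k_orth,
            "r2x_cum": round(opls.r2x_cum, 4),
            "r2y_cum": round(opls.r2y_cum, 4),
            "q2_cum": round(opls.q2_cum, 4),
        },
        "permutation_test": perm_summary,
        "n_vip": len(vip_features),
        "rf": {
            "n_star": rf.n_star,
            "n_stable": len(rf.stable_features),
            "top1_frequencies": {
                f: int(v) for f, v in rf.top1.items() if v > 0
            },
        },
        "n_selected": len(rf.selected_markers),
        "selected_markers": rf.selected_markers,
        "oob_error": round(rf.final_oob_error, 6),
        "auc": round(rf.final_auc, 6),
        "manifest": sorted(manifest),
    }
    if truth is not None:
        rec = truth_recovery_report(truth, rf.selected_markers, table.feature_ids)
        report_dict["recovery"] = {
            "sensitivity": round(rec.sensitivity, 4),
            "false_discovery_proportion": round(rec.false_discovery_proportion, 4),
        }
    (outdir / "report.json").write_text(
        json.dumps(report_dict, indent=1, sort_keys=True)
    )
    return report_dict


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    return d
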