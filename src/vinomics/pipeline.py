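"""End-to-end per-cellar, per-platform, per-factor analysis.

Stage order: platform-appropriate preprocessing (untargeted matrices get
the missingness/imputation/outlier/VSN chain; concentration platforms are
analysed on their reported scale), differential significance per factor,
Euclidean PCoA with loadings and PERMANOVA per factor, growth-rate
matrices with hierarchical clustering, and U/D/S trend labels. All outputs
are deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import diffsig, kinetics, ordination, preprocess
from .core_io import (
    Factor,
    FeatureMatrix,
    Platform,
    SampleDesign,
    build_grouping,
    dump_json,
    read_design_sheet,
    read_feature_matrix,
)

logger = logging.getLogger(__name__)

CELLAR_FACTORS = {
    "FB": [Factor.BARREL_TYPE, Factor.TIME],
    "ICVV": [Factor.BARREL_TYPE, Factor.TIME, Factor.BOTTLED_WINE],
}


@dataclass
class RunConfig:
    """Everything one pipeline run needs; no hidden state."""

    cellar: str = "FB"
    feature_tables: dict = field(default_factory=dict)  # Platform -> path
    design_path: str | None = None
    factors: list | None = None  # default: all factors the cellar supports
    alpha: float = diffsig.DEFAULT_ALPHA
    fcmm_min: float = diffsig.DEFAULT_FCMM_MIN
    max_missing_frac: float = preprocess.DEFAULT_MAX_MISSING_FRAC
    knn_k: int = preprocess.DEFAULT_KNN_K
    outlier_k_max: int = preprocess.DEFAULT_KMEANS_KMAX
    remove_outliers: bool = False
    n_perm: int = ordination.DEFAULT_N_PERM
    cluster_linkage: str = "average"
    cluster_metric: str = "euclidean"
    trend_tolerance: float = kinetics.DEFAULT_TREND_TOLERANCE
    seed: int = 0
    out_dir: str | None = None

    def child_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        return (self.seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def linear_view(fm: FeatureMatrix) -> FeatureMatrix:
    """Back-transform a variance-stabilised matrix to the linear domain.

    Fold changes on the glog scale are not fold changes, so FCMM, median
    fold-changes and growth rates are computed on 2**value, which inverts
    log2 and approximately inverts glog away from the detection floor.
    """
    if fm.scale != "normalized":
        return fm
    return dataclasses.replace(fm, values=2.0 ** fm.values, scale="raw")


def _prepare_platform(
    fm: FeatureMatrix, config: RunConfig
) -> tuple[FeatureMatrix, preprocess.PreprocessReport]:
    if fm.platform.untargeted:
        return preprocess.preprocess_untargeted(
            fm,
            max_missing_frac=config.max_missing_frac,
            knn_k=config.knn_k,
            outlier_k_max=config.outlier_k_max,
            remove_outliers=config.remove_outliers,
            seed=config.child_seed(f"outliers/{fm.platform.value}"),
        )
    report = preprocess.PreprocessReport()
    if fm.missing_mask.any():
        n = int(fm.missing_mask.sum())
        fm = preprocess.knn_impute(fm, config.knn_k)
        report.n_imputed_cells = n
    return fm, report


def _trend_series(
    fm: FeatureMatrix, design: list[SampleDesign], cellar: str
) -> tuple[list[int], np.ndarray]:
    """Replicate-mean trajectory per metabolite over barrel time-points."""
    months = sorted(
        {d.timepoint_months for d in design if d.cellar == cellar and d.vessel == "barrel"}
    )
    series = np.empty((len(months), fm.n_metabolites))
    for i, month in enumerate(months):
        ids = [
            d.sample_id
            for d in design
            if d.cellar == cellar
            and d.vessel == "barrel"
            and d.timepoint_months == month
            and d.sample_id in fm.sample_ids
        ]
        sub = fm.subset_samples(ids)
        vals = np.where(sub.missing_mask, np.nan, sub.values)
        series[i] = np.nanmean(vals, axis=0)
    return months, series


def analyse_platform(
    fm: FeatureMatrix,
    design: list[SampleDesign],
    config: RunConfig,
) -> dict:
    """Run every stage for one platform; returns the result bundle."""
    cellar = config.cellar
    factors = config.factors or CELLAR_FACTORS[cellar]
    processed, prep_report = _prepare_platform(fm, config)
    linear = linear_view(processed)

    results: dict = {
        "platform": fm.platform.value,
        "preprocess": prep_report.to_dict(),
        "factors": {},
        "errors": {},
    }

    dm = ordination.euclidean_distances(processed)
    ordn = ordination.pcoa(dm, processed.sample_ids)
    ordination.loadings(processed, ordn)
    results["ordination"] = ordn.to_dict()

    sig_tables: dict[str, diffsig.SignificanceTable] = {}
    for factor in [Factor(f) for f in factors]:
        key = factor.value
        try:
            grouping = build_grouping(design, factor, cellar)
            sig = diffsig.significance_table(
                processed,
                grouping,
                alpha=config.alpha,
                fcmm_min=config.fcmm_min,
                fcmm_values=linear,
            )
            perma = ordination.permanova(
                dm,
                grouping,
                processed.sample_ids,
                n_perm=config.n_perm,
                seed=config.child_seed(f"permanova/{fm.platform.value}/{key}"),
            )
            sig_tables[key] = sig
            results["factors"][key] = {
                "n_significant": sig.n_significant,
                "significant_ids": sig.significant_ids,
                "permanova": perma.to_dict(),
                "table": sig.table.to_dict(orient="records"),
            }
        except ValueError as exc:
            logger.warning("factor %s skipped for %s: %s", key, fm.platform.value, exc)
            results["errors"][key] = str(exc)

    # growth-rate kinetics on the linear-domain matrix
    grm = kinetics.growth_rate_matrix(linear, design, cellar)
    results["growth_rates"] = {
        "row_labels": grm.row_labels,
        "values": grm.values.tolist(),
        "metabolite_ids": grm.metabolite_ids,
    }
    finite_cols = np.all(np.isfinite(grm.values), axis=0)
    if len(grm.row_labels) >= 3 and finite_cols.any():
        sub = kinetics.GrowthRateMatrix(
            row_labels=grm.row_labels,
            metabolite_ids=[m for m, ok in zip(grm.metabolite_ids, finite_cols) if ok],
            values=grm.values[:, finite_cols],
        )
        dendro = kinetics.cluster_growth_rates(
            sub, linkage=config.cluster_linkage, metric=config.cluster_metric
        )
        results["dendrogram_newick"] = dendro.to_newick()
    if cellar == "ICVV":
        bottle_grm = kinetics.growth_rate_matrix(
            linear, design, cellar, include_bottles=True
        )
        results["bottle_growth_rates"] = {
            "row_labels": bottle_grm.row_labels,
            "values": bottle_grm.values.tolist(),
        }

    months, series = _trend_series(linear, design, cellar)
    trends = {}
    for j, met in enumerate(linear.metabolite_ids):
        y = series[:, j]
        if np.all(np.isfinite(y)) and np.all(y > 0):
            trends[met] = kinetics.classify_trend(y, config.trend_tolerance)
        else:
            trends[met] = None
    results["trends"] = trends
    results["trend_months"] = months

    distinct = set()
    for sig in sig_tables.values():
        distinct.update(sig.significant_ids)
    results["n_significant_distinct"] = len(distinct)
    return results


def run_pipeline(
    config: RunConfig,
    matrices: dict[Platform, FeatureMatrix] | None = None,
    design: list[SampleDesign] | None = None,
) -> dict:
    """Run the full analysis; pass matrices in memory or via config paths.

    Stage errors abort only their platform x factor cell; the summary
    records them. Returns the summary dict and, when ``config.out_dir`` is
    set, writes per-platform JSON bundles plus a summary.json.
    """
    if matrices is None:
        if design is None:
            design = read_design_sheet(config.design_path)
        matrices = {
            Platform(p): read_feature_matrix(path, Platform(p), design=design)
            for p, path in config.feature_tables.items()
        }
    elif design is None:
        raise ValueError("design required when matrices are passed in memory")

    summary: dict = {
        "cellar": config.cellar,
        "seed": config.seed,
        "alpha": config.alpha,
        "fcmm_min": config.fcmm_min,
        "platforms": {},
        "errors": {},
    }
    bundles = {}
    for platform, fm in sorted(matrices.items(), key=lambda kv: kv[0].value):
        try:
            bundle = analyse_platform(fm, design, config)
        except ValueError as exc:
            logger.error("platform %s failed: %s", platform.value, exc)
            summary["errors"][platform.value] = str(exc)
            continue
        bundles[platform.value] = bundle
        summary["platforms"][platform.value] = {
            "n_significant_distinct": bundle["n_significant_distinct"],
            "factors": {
                k: {
                    "n_significant": v["n_significant"],
                    "permanova_p": v["permanova"]["p_value"],
                }
                for k, v in bundle["factors"].items()
            },
            "errors": bundle["errors"],
            "outliers": bundle["preprocess"]["outlier_sample_ids"],
        }
    summary["n_significant_overall"] = sum(
        b["n_significant_distinct"] for b in bundles.values()
    )

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {"files": [], "seed": config.seed}
        for name, bundle in bundles.items():
            path = out / f"{config.cellar}_{name}.json"
            dump_json(bundle, str(path))
            manifest["files"].append(path.name)
        dump_json(summary, str(out / "summary.json"))
        manifest["files"].append("summary.json")
        dump_json(manifest, str(out / "manifest.json"))
    return summary
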