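"""Preprocessing chain for untargeted intensity matrices.

Mirrors the standard metabolomics sequence: drop features with excessive
missingness, impute the remainder by k-nearest-neighbour averaging over
metabolite profiles, screen for outlying samples with k-means on a 2-D
ordination, and variance-stabilise by per-sample calibration followed by a
generalized-log (glog) transform. NMR and targeted GC-MS concentration
tables are analysed on their reported scale and skip the VSN step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .core_io import FeatureMatrix

logger = logging.getLogger(__name__)

DEFAULT_MAX_MISSING_FRAC = 0.4
DEFAULT_KNN_K = 10
DEFAULT_KMEANS_KMAX = 4


@dataclass
class PreprocessReport:
    """Record of what the preprocessing chain did to one matrix."""

    n_imputed_cells: int = 0
    dropped_metabolite_ids: list[str] = field(default_factory=list)
    outlier_sample_ids: list[str] = field(default_factory=list)
    vsn_sample_factors: dict[str, float] = field(default_factory=dict)
    vsn_glog_a: float | None = None
    sd_rank_slope_vsn: float | None = None
    sd_rank_slope_log2: float | None = None

    def to_dict(self) -> dict:
        return {
            "n_imputed_cells": self.n_imputed_cells,
            "dropped_metabolite_ids": self.dropped_metabolite_ids,
            "outlier_sample_ids": self.outlier_sample_ids,
            "vsn_sample_factors": self.vsn_sample_factors,
            "vsn_glog_a": self.vsn_glog_a,
            "sd_rank_slope_vsn": self.sd_rank_slope_vsn,
            "sd_rank_slope_log2": self.sd_rank_slope_log2,
        }


def filter_missingness(
    fm: FeatureMatrix, max_missing_frac: float = DEFAULT_MAX_MISSING_FRAC
) -> tuple[FeatureMatrix, list[str]]:
    """Drop metabolites whose missing fraction exceeds the threshold."""
    if not 0 <= max_missing_frac < 1:
        raise ValueError("max_missing_frac must be in [0, 1)")
    frac = fm.missing_mask.mean(axis=0)
    keep = frac <= max_missing_frac
    dropped = [m for m, k in zip(fm.metabolite_ids, keep) if not k]
    if not keep.any():
        raise ValueError("all metabolites exceed the missingness threshold")
    if dropped:
        logger.info("filter_missingness dropped %d metabolites: %s",
                    len(dropped), dropped)
    kept_ids = [m for m, k in zip(fm.metabolite_ids, keep) if k]
    return fm.subset_metabolites(kept_ids), dropped


def knn_impute(fm: FeatureMatrix, k: int = DEFAULT_KNN_K) -> FeatureMatrix:
    """Replace missing cells by the mean of the k nearest metabolites.

    Neighbourhoods are defined between metabolite profiles (not samples: the
    study has at most 8 samples per factor) using Euclidean distance over
    co-observed samples of log-scale values, normalised by the number of
    co-observed samples so that profiles with different overlap are
    comparable. A metabolite with no co-observed neighbour in a sample falls
    back to its own observed median.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    mask = fm.missing_mask
    if not mask.any():
        return fm

    X = fm.values.T.copy()  # metabolites x samples
    M = mask.T
    obs = ~M
    with np.errstate(divide="ignore", invalid="ignore"):
        logX = np.where(obs & (X > 0), np.log(np.where(X > 0, X, 1.0)), np.nan)
    logX[~obs] = np.nan

    n_met, n_samp = X.shape
    filled = X.copy()
    for i in range(n_met):
        miss_cols = np.where(M[i])[0]
        if miss_cols.size == 0:
            continue
        co = obs & obs[i]  # co-observed pattern vs every metabolite
        co_counts = co.sum(axis=1)
        diff = logX - logX[i]
        with np.errstate(invalid="ignore"):
            d2 = np.nansum(np.where(co, diff**2, 0.0), axis=1)
        dist = np.sqrt(np.where(co_counts > 0, d2 / np.maximum(co_counts, 1), np.inf))
        dist[i] = np.inf
        for j in miss_cols:
            cand = np.where(obs[:, j] & np.isfinite(dist))[0]
            if cand.size == 0:
                med = np.nanmedian(np.where(obs[i], X[i], np.nan))
                logger.warning(
                    "metabolite %s has no co-observed neighbour in sample %s; "
                    "falling back to its median",
                    fm.metabolite_ids[i], fm.sample_ids[j],
                )
                filled[i, j] = med
                continue
            kk = min(k, cand.size)
            nearest = cand[np.argsort(dist[cand], kind="stable")[:kk]]
            filled[i, j] = X[nearest, j].mean()

    return replace(
        fm,
        values=filled.T,
        missing_mask=np.zeros_like(mask),
    )


OUTLIER_SEPARATION_MULT = 3.0


def detect_outliers(
    fm: FeatureMatrix,
    k_max: int = DEFAULT_KMEANS_KMAX,
    seed: int = 0,
    separation_mult: float = OUTLIER_SEPARATION_MULT,
) -> list[str]:
    """Flag samples that form separated singleton k-means clusters.

    Samples are projected onto the first two principal coordinates of their
    Euclidean distances (on log2 values for raw positive matrices, since
    intensity data are multiplicative); k-means runs for k = 2..k_max with
    a fixed seed and the silhouette-optimal k is kept. A singleton cluster
    at that k is flagged only when its sample also lies further than
    ``separation_mult`` times the RMS spread of the remaining samples from
    their centroid — a 3-sigma guard so that k-means carving a straggler
    out of homogeneous replicates does not raise false alarms. Flagged
    samples are never removed automatically.
    """
    if fm.missing_mask.any():
        raise ValueError("detect_outliers requires an imputed matrix")
    n = fm.n_samples
    if n < 4:
        logger.warning("detect_outliers skipped: fewer than 4 samples")
        return []

    from .ordination import euclidean_distances, pcoa

    view = fm
    if fm.scale == "raw" and np.all(fm.values > 0):
        view = replace(fm, values=np.log2(fm.values), scale="normalized")
    ordn = pcoa(euclidean_distances(view))
    coords = ordn.coordinates[:, : min(2, ordn.coordinates.shape[1])]

    best_k, best_sil, best_labels = None, -np.inf, None
    for k in range(2, min(k_max, n - 1) + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(coords)
        if len(set(km.labels_)) < 2:
            continue
        sil = silhouette_score(coords, km.labels_)
        if sil > best_sil:
            best_k, best_sil, best_labels = k, sil, km.labels_
    if best_labels is None:
        return []

    flagged = []
    counts = np.bincount(best_labels)
    for lab in np.where(counts == 1)[0]:
        idx = int(np.where(best_labels == lab)[0][0])
        others = np.delete(coords, idx, axis=0)
        centroid = others.mean(axis=0)
        spread = np.sqrt(((others - centroid) ** 2).sum(axis=1).mean())
        dist = np.sqrt(((coords[idx] - centroid) ** 2).sum())
        if dist > separation_mult * max(spread, 1e-12):
            flagged.append(fm.sample_ids[idx])
    if flagged:
        logger.info("detect_outliers flagged %s at k=%d", flagged, best_k)
    return sorted(flagged)


def glog(x: np.ndarray | float, a: float) -> np.ndarray | float:
    """Generalized log2: glog_a(x) = log2((x + sqrt(x^2 + a^2)) / 2).

    Defined for all reals; tends to log2(x) for x >> a and compresses the
    variance of near-zero values instead of exploding like log2.
    """
    x = np.asarray(x, dtype=float)
    return np.log2((x + np.sqrt(x**2 + a**2)) / 2.0)


def sd_mean_rank_slope(values: np.ndarray) -> float:
    """Slope of per-metabolite SD against the rank of its mean.

    Ranks are scaled to [0, 1] so slopes are comparable across matrix sizes.
    A variance-stabilised matrix has a slope near zero.
    """
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    rank = stats.rankdata(mean) / len(mean)
    res = stats.linregress(rank, sd)
    return float(res.slope)


def vsn_normalize(
    fm: FeatureMatrix, a_quantile: float = 0.05
) -> tuple[FeatureMatrix, PreprocessReport]:
    """Median-quotient calibration followed by a glog transform.

    Each sample is divided by the median, over metabolites, of its quotients
    against the geometric-mean reference sample, equalising overall
    intensity. The glog parameter ``a`` is the ``a_quantile`` quantile of
    the calibrated positive values, so that the transform behaves like log2
    in the well-measured range and stabilises variance near the detection
    floor. The report records the SD-vs-mean-rank slope after glog and, for
    comparison, after a plain log2 of the calibrated values.
    """
    if fm.missing_mask.any():
        raise ValueError("vsn_normalize requires an imputed matrix")
    X = fm.values
    if np.any(X <= 0):
        raise ValueError("vsn_normalize requires strictly positive values")
    if np.any(X.std(axis=1) == 0):
        raise ValueError("zero-variance sample")

    ref = stats.gmean(X, axis=0)  # geometric-mean reference per metabolite
    factors = np.median(X / ref, axis=1)  # per-sample median quotient
    calibrated = X / factors[:, None]

    a = float(np.quantile(calibrated[calibrated > 0], a_quantile))
    transformed = glog(calibrated, a)

    report = PreprocessReport(
        vsn_sample_factors={s: float(f) for s, f in zip(fm.sample_ids, factors)},
        vsn_glog_a=a,
        sd_rank_slope_vsn=sd_mean_rank_slope(transformed),
        sd_rank_slope_log2=sd_mean_rank_slope(np.log2(calibrated)),
    )
    out = replace(fm, values=transformed, scale="normalized")
    return out, report


def preprocess_untargeted(
    fm: FeatureMatrix,
    max_missing_frac: float = DEFAULT_MAX_MISSING_FRAC,
    knn_k: int = DEFAULT_KNN_K,
    outlier_k_max: int = DEFAULT_KMEANS_KMAX,
    remove_outliers: bool = False,
    seed: int = 0,
) -> tuple[FeatureMatrix, PreprocessReport]:
    """Full chain: missingness filter -> kNN impute -> outlier flag -> VSN."""
    filtered, dropped = filter_missingness(fm, max_missing_frac)
    n_missing = int(filtered.missing_mask.sum())
    imputed = knn_impute(filtered, knn_k)
    flagged = detect_outliers(imputed, outlier_k_max, seed=seed)
    if remove_outliers and flagged:
        keep = [s for s in imputed.sample_ids if s not in flagged]
        imputed = imputed.subset_samples(keep)
    normalized, report = vsn_normalize(imputed)
    report.n_imputed_cells = n_missing
    report.dropped_metabolite_ids = dropped
    report.outlier_sample_ids = flagged
    return normalized, report
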