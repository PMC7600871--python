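"""Differential analysis coupling statistical and practical significance.

For each metabolite, statistical significance comes from a pooled-variance
Student's t-test (two-group factors) or one-way ANOVA (the time factor),
with Benjamini-Hochberg FDR correction within each platform x factor table.
Practical significance is the fold change between the minimum and maximum
value observed among the samples of the factor (FCMM); a metabolite is
called significant when q <= alpha AND FCMM >= fcmm_min (defaults 0.05, 2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import Factor, FactorGrouping, FeatureMatrix

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_FCMM_MIN = 2.0


@dataclass
class SignificanceTable:
    """Per-metabolite significance results for one factor."""

    factor: Factor
    table: pd.DataFrame = field(repr=False)
    # columns: metabolite_id, p_value, q_value, fcmm, median_fc, significant

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    @property
    def significant_ids(self) -> list[str]:
        return self.table.loc[self.table["significant"], "metabolite_id"].tolist()

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False)

    def to_dict(self) -> dict:
        return {
            "factor": self.factor.value,
            "n_significant": self.n_significant,
            "rows": self.table.to_dict(orient="records"),
        }


def fcmm(values) -> float:
    """Fold change between the minimum and maximum observed value.

    Scale-invariant practical-significance statistic: max / min over all
    samples in the factor's group union. Returns +inf (with a warning) when
    the minimum is zero under a keep-zeros policy.
    """
    v = np.asarray([x for x in np.ravel(values) if np.isfinite(x)], dtype=float)
    if v.size < 2:
        raise ValueError("fcmm needs at least 2 observed values")
    if np.any(v < 0):
        raise ValueError("fcmm requires non-negative values")
    vmin, vmax = v.min(), v.max()
    if vmin == 0:
        logger.warning("fcmm: minimum value is 0; returning +inf")
        return math.inf
    return float(vmax / vmin)


def two_group_test(fm: FeatureMatrix, grouping: FactorGrouping,
                   welch: bool = False) -> np.ndarray:
    """Two-sided Student's t-test (pooled variance) per metabolite.

    Metabolites constant in both groups get p = 1. ``welch=True`` switches
    to the unequal-variance form.
    """
    if len(grouping.groups) != 2:
        raise ValueError("two_group_test requires exactly 2 groups")
    (ga, gb) = grouping.groups.values()
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("each group needs >= 2 samples")
    A = fm.subset_samples(ga).values
    B = fm.subset_samples(gb).values
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(A, B, axis=0, equal_var=not welch)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(p)
    if degenerate.any():
        logger.info("%d constant metabolites set to p = 1", degenerate.sum())
        p[degenerate] = 1.0
    return p


def multi_group_test(fm: FeatureMatrix, grouping: FactorGrouping) -> np.ndarray:
    """One-way fixed-effects ANOVA F-test per metabolite."""
    if len(grouping.groups) < 3:
        raise ValueError("multi_group_test requires >= 3 groups")
    mats = []
    for label, ids in grouping.groups.items():
        if len(ids) < 2:
            raise ValueError(f"group {label!r} needs >= 2 samples")
        mats.append(fm.subset_samples(ids).values)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.f_oneway(*mats, axis=0)
    p = np.asarray(res.pvalue, dtype=float)
    # perfect separation with zero within-group variance -> p = 0-cap;
    # constant everywhere -> p = 1
    const_all = np.all([m.std(axis=0) == 0 for m in mats], axis=0)
    between_var = np.stack([m.mean(axis=0) for m in mats]).std(axis=0)
    nanp = np.isnan(p)
    p[nanp & const_all & (between_var == 0)] = 1.0
    p[nanp & (between_var > 0)] = np.finfo(float).tiny
    p[np.isnan(p)] = 1.0
    return p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} (p_(j) * m / j), capped at 1, mapped back to the
    input order with stable tie handling.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def median_fold_change(
    fm: FeatureMatrix, grouping: FactorGrouping, metabolite: str
) -> float:
    """Ratio of the two group medians, oriented so the result is >= 1."""
    if len(grouping.groups) != 2:
        raise ValueError("median_fold_change requires exactly 2 groups")
    j = fm.metabolite_ids.index(metabolite)
    meds = []
    for label, ids in grouping.groups.items():
        if not ids:
            raise ValueError(f"group {label!r} is empty")
        sub = fm.subset_samples(ids)
        vals = sub.values[:, j][~sub.missing_mask[:, j]]
        if vals.size == 0:
            raise ValueError(f"group {label!r} has no observed values")
        meds.append(float(np.median(vals)))
    lo, hi = sorted(meds)
    if lo == 0:
        logger.warning("median_fold_change: smaller median is 0; +inf")
        return math.inf
    return hi / lo


def significance_table(
    fm: FeatureMatrix,
    grouping: FactorGrouping,
    alpha: float = DEFAULT_ALPHA,
    fcmm_min: float = DEFAULT_FCMM_MIN,
    fcmm_values: FeatureMatrix | None = None,
    welch: bool = False,
) -> SignificanceTable:
    """Run the factor's test, BH-FDR and FCMM; combine into verdicts.

    ``fcmm_values``, when given, supplies the matrix on which fold changes
    are computed (e.g. linear-scale values when the tests run on the
    variance-stabilised scale); it must share ids with ``fm``.
    """
    n_groups = len(grouping.groups)
    if n_groups == 2:
        p = two_group_test(fm, grouping, welch=welch)
    else:
        p = multi_group_test(fm, grouping)
    q = bh_fdr(p)

    fold_src = fcmm_values if fcmm_values is not None else fm
    union = grouping.sample_ids
    sub = fold_src.subset_samples(union)
    fold = np.empty(fm.n_metabolites)
    for j in range(fm.n_metabolites):
        vals = sub.values[:, j][~sub.missing_mask[:, j]]
        fold[j] = fcmm(vals) if vals.size >= 2 else np.nan

    med_fc = np.full(fm.n_metabolites, np.nan)
    if n_groups == 2:
        for j, met in enumerate(fm.metabolite_ids):
            med_fc[j] = median_fold_change(fold_src, grouping, met)

    significant = (q <= alpha) & (fold >= fcmm_min)
    table = pd.DataFrame(
        {
            "metabolite_id": fm.metabolite_ids,
            "p_value": p,
            "q_value": q,
            "fcmm": fold,
            "median_fc": med_fc,
            "significant": significant,
        }
    )
    return SignificanceTable(factor=grouping.factor, table=table)
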