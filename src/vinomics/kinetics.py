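"""Growth-rate kinetics over ageing periods and trend classification.

The per-period growth rate k relates the endpoint concentrations of a
metabolite: k = 1 + (C2 - C1)/C1 when the concentration rose between the
two time-points, and k = 1 + (C1 - C2)/C1 when it fell. Both branches give
k >= 1 (direction-free magnitude); a signed variant k = C2/C1 is available
behind a flag. Period x series growth-rate rows are clustered
hierarchically to reveal which ageing periods behave alike, and replicate-
mean trajectories are classified as increasing (U), decreasing (D) or
stable-with-interior-peak (S).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core_io import FeatureMatrix, SampleDesign

logger = logging.getLogger(__name__)

# per-cellar barrel-ageing period schedules (months)
SCHEDULES = {
    "FB": [(0, 3), (3, 6), (6, 9), (9, 12)],
    "ICVV": [(0, 3), (3, 9), (9, 12)],
}
BOTTLE_SCHEDULE = [(0, 12)]

DEFAULT_TREND_TOLERANCE = 0.2


def growth_rate(c1: float, c2: float, signed: bool = False) -> float:
    """Growth coefficient between two endpoint concentrations.

    Increase branch gives C2/C1, decrease branch 2 - C2/C1; both are >= 1
    whenever both concentrations are positive, so the statistic measures
    the magnitude of change without its direction. ``signed=True`` returns
    the plain ratio C2/C1 instead.
    """
    if c1 <= 0:
        raise ValueError("growth_rate undefined for c1 <= 0")
    if signed:
        return c2 / c1
    if c2 >= c1:
        return 1.0 + (c2 - c1) / c1
    return 1.0 + (c1 - c2) / c1


@dataclass
class GrowthRateMatrix:
    """Period x series rows of growth coefficients per metabolite."""

    row_labels: list[str]  # e.g. "0-3_OLD"
    metabolite_ids: list[str]
    values: np.ndarray  # rows x metabolites

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.metabolite_ids)):
            raise ValueError("values shape does not match labels")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.row_labels, columns=self.metabolite_ids
        )

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index_label="period_series")


def _endpoint_means(
    fm: FeatureMatrix,
    design: list[SampleDesign],
    cellar: str,
    barrel_type: str,
    vessel: str,
) -> dict[int, np.ndarray]:
    """Replicate-mean concentration per time-point for one wine series."""
    by_month: dict[int, list[str]] = {}
    for d in design:
        if d.cellar == cellar and d.barrel_type == barrel_type and d.vessel == vessel:
            by_month.setdefault(d.timepoint_months, []).append(d.sample_id)
    out = {}
    for month, ids in sorted(by_month.items()):
        sub = fm.subset_samples([s for s in ids if s in fm.sample_ids])
        if sub.n_samples == 0:
            continue
        vals = np.where(sub.missing_mask, np.nan, sub.values)
        out[month] = np.nanmean(vals, axis=0)
    return out


def growth_rate_matrix(
    fm: FeatureMatrix,
    design: list[SampleDesign],
    cellar: str,
    schedule: list[tuple[int, int]] | None = None,
    include_bottles: bool = False,
    signed: bool = False,
) -> GrowthRateMatrix:
    """Growth rates per (period, series) row over the cellar's schedule.

    Series are the old- and new-barrel wines ("OLD"/"NEW"); with
    ``include_bottles`` the bottled series ("BTO"/"BTN") are added on the
    0-12-month period, their month-0 endpoint being the wine entering the
    corresponding barrel. Endpoint concentrations are arithmetic replicate
    means. Periods whose endpoints are absent for a series are dropped with
    a warning; zero starting concentrations mark the cell missing (NaN).
    """
    if schedule is None:
        schedule = BOTTLE_SCHEDULE if include_bottles else SCHEDULES[cellar]

    series: list[tuple[str, str, str]] = [  # (label, barrel_type, vessel)
        ("OLD", "old", "barrel"),
        ("NEW", "new", "barrel"),
    ]
    if include_bottles:
        series += [("BTO", "old", "bottle"), ("BTN", "new", "bottle")]

    rows, labels = [], []
    for label, bt, vessel in series:
        means = _endpoint_means(fm, design, cellar, bt, vessel)
        if vessel == "bottle":
            # the bottled wine starts as the month-0 barrel wine
            barrel_means = _endpoint_means(fm, design, cellar, bt, "barrel")
            if 0 in barrel_means:
                means = {0: barrel_means[0], **means}
        for t1, t2 in schedule:
            if t1 not in means or t2 not in means:
                logger.warning(
                    "period %d-%d dropped for series %s: endpoint missing",
                    t1, t2, label,
                )
                continue
            c1, c2 = means[t1], means[t2]
            row = np.full(fm.n_metabolites, np.nan)
            for j in range(fm.n_metabolites):
                if np.isfinite(c1[j]) and np.isfinite(c2[j]) and c1[j] > 0:
                    row[j] = growth_rate(c1[j], c2[j], signed=signed)
                else:
                    logger.warning(
                        "growth rate undefined for %s, period %d-%d, series %s",
                        fm.metabolite_ids[j], t1, t2, label,
                    )
            rows.append(row)
            labels.append(f"{t1}-{t2}_{label}")
    return GrowthRateMatrix(
        row_labels=labels, metabolite_ids=list(fm.metabolite_ids), values=np.array(rows)
    )


@dataclass
class Dendrogram:
    """Agglomerative merge tree over growth-rate rows."""

    labels: list[str]
    merge_table: np.ndarray = field(repr=False)  # scipy linkage Z
    linkage: str = "average"
    metric: str = "euclidean"

    @property
    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.merge_table)
        return [self.labels[i] for i in order]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.merge_table)

        def rec(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        return rec(tree, tree.dist)[: -len(":0")] + ";"

    def merge_frame(self) -> pd.DataFrame:
        n = len(self.labels)
        recs = []
        for i, (a, b, h, cnt) in enumerate(self.merge_table):
            recs.append(
                {"node": n + i, "child1": int(a), "child2": int(b),
                 "height": float(h), "n_leaves": int(cnt)}
            )
        return pd.DataFrame(recs)


def cluster_growth_rates(
    grm: GrowthRateMatrix, linkage: str = "average", metric: str = "euclidean"
) -> Dendrogram:
    """Hierarchically cluster the period x series rows.

    Rows are pre-sorted lexicographically by label so ties in the distance
    matrix break deterministically regardless of input order.
    """
    if len(grm.row_labels) < 3:
        raise ValueError("clustering needs >= 3 rows")
    if not np.all(np.isfinite(grm.values)):
        i, j = np.argwhere(~np.isfinite(grm.values))[0]
        raise ValueError(
            f"non-finite growth rate at row {grm.row_labels[i]!r}, "
            f"metabolite {grm.metabolite_ids[j]!r}"
        )
    order = np.argsort(np.asarray(grm.row_labels, dtype=object), kind="stable")
    labels = [grm.row_labels[i] for i in order]
    X = grm.values[order]
    Z = hierarchy.linkage(pdist(X, metric=metric), method=linkage)
    return Dendrogram(labels=labels, merge_table=Z, linkage=linkage, metric=metric)


def classify_trend(
    series, tolerance: float = DEFAULT_TREND_TOLERANCE
) -> str | None:
    """Label a replicate-mean trajectory U (up), D (down) or S (stable/peaked).

    U: rank correlation with time >= +0.5 and the final value exceeds the
    initial by more than the tolerance fold. D: the mirror image. S: the
    trajectory returns to near its starting level (end-vs-start fold below
    tolerance) while peaking at an interior time-point. Remaining cases take
    the direction of the larger end-vs-start fold. The rule is heuristic and
    scale-invariant; tolerance defaults to a 20% fold. Returns None for
    fewer than 3 points.
    """
    y = np.asarray(series, dtype=float)
    if y.size < 3:
        return None
    if np.any(y <= 0) or not np.all(np.isfinite(y)):
        raise ValueError("classify_trend requires positive finite values")
    thresh = 1.0 + tolerance
    first, last = y[0], y[-1]
    if np.all(y == y[0]):
        rho = 0.0
    else:
        rho = stats.spearmanr(np.arange(y.size), y).statistic
    if rho >= 0.5 and last / first >= thresh:
        return "U"
    if rho <= -0.5 and first / last >= thresh:
        return "D"
    fold_end = max(last / first, first / last)
    interior_max = y[1:-1].max() >= max(first, last)
    if interior_max and fold_end < thresh:
        return "S"
    return "U" if last >= first else "D"
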