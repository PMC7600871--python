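"""Synthetic multi-platform wine-ageing datasets with known ground truth.

The generator reproduces the two-cellar sampling design: cellar FB samples
its old and new barrel at 0, 3, 6 and 9 months (plus 12 months from the new
barrel only), while cellar ICVV samples both barrels at 0, 3, 9 and 12
months and analyses a bottled aliquot of each barrel's wine at 12 months.
Metabolite trajectories are phenomenological: geometric increase or decrease
across time-points reaching a target fold at the final point, an interior-
maximum bump for peaked metabolites, and flat lines for nulls. Replicate
values carry multiplicative log-normal noise; untargeted platforms lose
their low-intensity cells to left-censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import FeatureMatrix, Platform, SampleDesign

# sampling months per cellar; FB old barrel misses month 12
FB_MONTHS = (0, 3, 6, 9, 12)
ICVV_MONTHS = (0, 3, 9, 12)

# realistic default feature counts per platform
DEFAULT_N_METABOLITES = {
    Platform.NMR: 39,
    Platform.GCMS_TARGETED: 5,
    Platform.GCMS_UNTARGETED: 394,
    Platform.LCMS: 502,
}

_BASELINE_LOG_MEAN = {
    Platform.NMR: np.log(10.0),  # relative concentrations, most < 90
    Platform.GCMS_TARGETED: np.log(50.0),  # µg/L
    Platform.GCMS_UNTARGETED: np.log(1e5),  # peak areas
    Platform.LCMS: np.log(1e5),
}


@dataclass
class SimulationSpec:
    """Conditions of one simulated ageing experiment."""

    cellar: str = "FB"
    n_metabolites: dict = field(default_factory=lambda: dict(DEFAULT_N_METABOLITES))
    fraction_increasing: float = 0.10
    fraction_decreasing: float = 0.10
    fraction_peaked: float = 0.05
    effect_fold: float = 4.0  # planted final/initial fold over time
    barrel_effect_fold: float = 1.0  # old-vs-new multiplier for affected mets
    fraction_barrel_affected: float = 0.0
    bottle_effect_fold: float = 1.0  # bottle-vs-barrel multiplier at month 12
    fraction_bottle_affected: float = 0.0
    noise_cv: float = 0.2  # multiplicative log-normal replicate noise
    additive_sd_frac: float = 0.0  # platform floor noise, as fraction of the
    # median baseline (untargeted platforms only)
    missing_rate: float = 0.1  # untargeted left-censor fraction
    mcar: bool = False  # missing completely at random instead of censoring
    baseline_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cellar not in ("FB", "ICVV"):
            raise ValueError(f"unknown cellar {self.cellar!r}")
        fr = self.fraction_increasing + self.fraction_decreasing + self.fraction_peaked
        if fr > 1 + 1e-12:
            raise ValueError("trend fractions must sum to <= 1")
        for name in ("effect_fold", "barrel_effect_fold", "bottle_effect_fold"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        self.n_metabolites = {Platform(k): v for k, v in self.n_metabolites.items()}


@dataclass
class GroundTruth:
    """What was planted, per platform and metabolite."""

    # platform -> metabolite_id -> record
    records: dict = field(default_factory=dict)

    def trend(self, platform: Platform, metabolite_id: str) -> str:
        return self.records[Platform(platform)][metabolite_id]["trend"]

    def platform_records(self, platform: Platform) -> dict:
        return self.records[Platform(platform)]


def _design(cellar: str) -> list[SampleDesign]:
    rows = []
    months = FB_MONTHS if cellar == "FB" else ICVV_MONTHS
    for bt, code in (("old", "BAO"), ("new", "BAN")):
        for m in months:
            if cellar == "FB" and bt == "old" and m == 12:
                continue  # old FB barrel was emptied before month 12
            rows.append(SampleDesign(
                sample_id=f"{cellar}_{code}_{m}", cellar=cellar, barrel_type=bt,
                vessel="barrel", timepoint_months=m, replicate=1,
            ))
    if cellar == "ICVV":
        for bt, code in (("old", "BTO"), ("new", "BTN")):
            rows.append(SampleDesign(
                sample_id=f"{cellar}_{code}_12", cellar=cellar, barrel_type=bt,
                vessel="bottle", timepoint_months=12, replicate=1,
            ))
    return rows


def _trend_weight(trend: str, n_points: int) -> np.ndarray:
    """Exponent profile w(t) so value = baseline * fold**w over time-points."""
    idx = np.arange(n_points, dtype=float)
    if trend == "U":
        return idx / (n_points - 1)
    if trend == "D":
        return -idx / (n_points - 1)
    if trend == "S":
        peak = (n_points - 1) / 2.0
        return 1.0 - np.abs(idx - peak) / peak
    return np.zeros(n_points)


def simulate_dataset(
    spec: SimulationSpec,
) -> tuple[dict[Platform, FeatureMatrix], list[SampleDesign], GroundTruth]:
    """Generate feature matrices per platform, the design sheet and truth.

    Fully reproducible from ``spec.seed``: the same spec yields bit-identical
    matrices.
    """
    rng = np.random.default_rng(spec.seed)
    design = _design(spec.cellar)
    months = sorted({d.timepoint_months for d in design})
    month_index = {m: i for i, m in enumerate(months)}
    n_points = len(months)

    matrices: dict[Platform, FeatureMatrix] = {}
    truth = GroundTruth()

    for platform in Platform:
        m = spec.n_metabolites.get(platform, 0)
        if m == 0:
            continue
        met_ids = [f"{platform.value}_met_{j:04d}" for j in range(m)]

        # exact planted counts: round(fraction * m) metabolites per trend,
        # placed at seeded-random positions
        n_u = round(spec.fraction_increasing * m)
        n_d = round(spec.fraction_decreasing * m)
        n_s = round(spec.fraction_peaked * m)
        trends = np.array(
            ["U"] * n_u + ["D"] * n_d + ["S"] * n_s
            + ["flat"] * (m - n_u - n_d - n_s)
        )
        trends = trends[rng.permutation(m)]
        barrel_hit = rng.random(m) < spec.fraction_barrel_affected
        bottle_hit = rng.random(m) < spec.fraction_bottle_affected
        baseline = np.exp(
            rng.normal(_BASELINE_LOG_MEAN[platform], spec.baseline_log_sd, size=m)
        )

        sigma = np.sqrt(np.log1p(spec.noise_cv**2))
        values = np.empty((len(design), m))
        for i, d in enumerate(design):
            w = np.array(
                [_trend_weight(t, n_points)[month_index[d.timepoint_months]]
                 for t in trends]
            )
            mean = baseline * spec.effect_fold**w
            if spec.barrel_effect_fold > 1:
                # the new barrel carries the planted barrel effect
                mean = np.where(
                    barrel_hit & (d.barrel_type == "new"),
                    mean * spec.barrel_effect_fold,
                    mean,
                )
            if d.vessel == "bottle" and spec.bottle_effect_fold > 1:
                mean = np.where(bottle_hit, mean * spec.bottle_effect_fold, mean)
            noise = (
                np.exp(rng.normal(0.0, sigma, size=m)) if sigma > 0 else 1.0
            )
            row = mean * noise
            if spec.additive_sd_frac > 0 and platform.untargeted:
                floor_sd = spec.additive_sd_frac * float(np.median(baseline))
                row = np.abs(row + rng.normal(0.0, floor_sd, size=m))
            values[i] = row

        mask = np.zeros_like(values, dtype=bool)
        if platform.untargeted and spec.missing_rate > 0:
            if spec.mcar:
                mask = rng.random(values.shape) < spec.missing_rate
            else:
                thresh = np.quantile(values, spec.missing_rate)
                mask = values < thresh
        vals = values.copy()
        vals[mask] = np.nan

        matrices[platform] = FeatureMatrix(
            platform=platform,
            sample_ids=[d.sample_id for d in design],
            metabolite_ids=met_ids,
            values=vals,
            missing_mask=mask,
        )
        truth.records[platform] = {
            met: {
                "trend": str(t),
                "true_fcmm_time": float(spec.effect_fold) if t != "flat" else 1.0,
                "affected_by_barrel": bool(bh),
                "affected_by_bottling": bool(bo),
            }
            for met, t, bh, bo in zip(met_ids, trends, barrel_hit, bottle_hit)
        }

    return matrices, design, truth


def recovery_report(
    truth_records: dict,
    sig_table,
    trend_labels: dict[str, str] | None = None,
    positive_key: str = "true_fcmm_time",
) -> dict:
    """Compare pipeline calls against planted ground truth.

    ``truth_records`` is one platform's record dict; a metabolite is truly
    positive when ``positive_key`` exceeds 1 (fold keys) or is truthy
    (boolean keys). Returns sensitivity/specificity of the combined verdict,
    the empirical FDR among the calls, and — when trend labels are supplied —
    a confusion matrix and accuracy over metabolites with a planted U/D/S
    trend.
    """
    table = sig_table.table
    called = set(table.loc[table["significant"], "metabolite_id"])
    ids = list(table["metabolite_id"])
    if set(ids) != set(truth_records):
        raise ValueError("metabolite ids of truth and table differ")

    def is_pos(rec) -> bool:
        v = rec[positive_key]
        return v > 1 if isinstance(v, (int, float)) and not isinstance(v, bool) else bool(v)

    tp = sum(1 for m in ids if is_pos(truth_records[m]) and m in called)
    fp = sum(1 for m in ids if not is_pos(truth_records[m]) and m in called)
    fn = sum(1 for m in ids if is_pos(truth_records[m]) and m not in called)
    tn = len(ids) - tp - fp - fn

    out = {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "empirical_fdr": fp / (tp + fp) if tp + fp else float("nan"),
        "n_called": tp + fp,
    }

    if trend_labels is not None:
        confusion: dict[str, dict[str, int]] = {}
        correct = total = 0
        for met, rec in truth_records.items():
            t = rec["trend"]
            if t not in ("U", "D", "S"):
                continue
            pred = trend_labels.get(met)
            confusion.setdefault(t, {}).setdefault(str(pred), 0)
            confusion[t][str(pred)] += 1
            total += 1
            if pred == t:
                correct += 1
        out["trend_confusion"] = confusion
        out["trend_accuracy"] = correct / total if total else float("nan")
    return out
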