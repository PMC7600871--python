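"""Domain types and I/O for wine-ageing metabolomics feature tables.

The study design has two cellars. FB ages wine in one old and one new oak
barrel sampled at 0, 3, 6, 9 and (new barrel only) 12 months. ICVV samples
both barrels at 0, 3, 9 and 12 months and additionally keeps a bottled
aliquot of each barrel's wine, analysed at 12 months. Metabolite
quantification comes from four analytical platforms: NMR (relative
concentrations), targeted GC-MS (absolute µg/L), and untargeted GC-MS and
LC-MS (chromatographic peak areas).
"""

from __future__ import annotations

import csv
import enum
import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"

DESIGN_COLUMNS = [
    "sample_id",
    "cellar",
    "barrel_type",
    "vessel",
    "timepoint_months",
    "replicate",
]


class Platform(str, enum.Enum):
    """Analytical platform a feature table comes from."""

    NMR = "NMR"
    GCMS_TARGETED = "GCMS_targeted"
    GCMS_UNTARGETED = "GCMS_untargeted"
    LCMS = "LCMS"

    @property
    def untargeted(self) -> bool:
        return self in (Platform.GCMS_UNTARGETED, Platform.LCMS)


class Factor(str, enum.Enum):
    BARREL_TYPE = "barrel_type"
    TIME = "time"
    BOTTLED_WINE = "bottled_wine"


@dataclass
class FeatureMatrix:
    """Samples x metabolites value matrix for one platform.

    ``values`` is oriented samples (rows) by metabolites (columns).
    ``missing_mask`` marks cells that every downstream operation must
    ignore; masked cells hold NaN in ``values``.
    """

    platform: Platform
    sample_ids: list[str]
    metabolite_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray
    scale: str = "raw"  # "raw" | "normalized"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, m = len(self.sample_ids), len(self.metabolite_ids)
        if self.values.shape != (n, m):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{n} samples x {m} metabolites"
            )
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape does not match values")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.metabolite_ids)) != m:
            raise ValueError("duplicate metabolite ids")
        observed = self.values[~self.missing_mask]
        if not np.all(np.isfinite(observed)):
            raise ValueError("observed values must be finite")
        if self.scale == "raw" and np.any(observed < 0):
            raise ValueError("raw-scale values must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    def to_frame(self) -> pd.DataFrame:
        """Values as DataFrame (samples x metabolites), missing cells NaN."""
        vals = self.values.copy()
        vals[self.missing_mask] = np.nan
        return pd.DataFrame(vals, index=self.sample_ids, columns=self.metabolite_ids)

    def subset_samples(self, sample_ids: list[str]) -> "FeatureMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return replace(
            self,
            sample_ids=list(sample_ids),
            values=self.values[idx],
            missing_mask=self.missing_mask[idx],
        )

    def subset_metabolites(self, metabolite_ids: list[str]) -> "FeatureMatrix":
        idx = [self.metabolite_ids.index(m) for m in metabolite_ids]
        return replace(
            self,
            metabolite_ids=list(metabolite_ids),
            values=self.values[:, idx],
            missing_mask=self.missing_mask[:, idx],
        )


@dataclass(frozen=True)
class SampleDesign:
    """Per-sample metadata row of the design sheet."""

    sample_id: str
    cellar: str  # "FB" | "ICVV"
    barrel_type: str  # "old" | "new"
    vessel: str  # "barrel" | "bottle"
    timepoint_months: int
    replicate: int

    def __post_init__(self) -> None:
        if self.cellar not in ("FB", "ICVV"):
            raise ValueError(f"unknown cellar {self.cellar!r}")
        if self.barrel_type not in ("old", "new"):
            raise ValueError(f"unknown barrel_type {self.barrel_type!r}")
        if self.vessel not in ("barrel", "bottle"):
            raise ValueError(f"unknown vessel {self.vessel!r}")
        if self.timepoint_months < 0:
            raise ValueError("timepoint_months must be >= 0")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        if self.vessel == "bottle" and not (
            self.cellar == "ICVV" and self.timepoint_months == 12
        ):
            raise ValueError(
                "bottled samples only exist in cellar ICVV at month 12"
            )


@dataclass
class FactorGrouping:
    """Disjoint sample groups for one statistical factor."""

    factor: Factor
    groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        all_ids: list[str] = []
        for label, ids in self.groups.items():
            if len(ids) < 2:
                raise ValueError(f"group {label!r} has fewer than 2 samples")
            all_ids.extend(ids)
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("groups are not disjoint")
        n = len(self.groups)
        if self.factor in (Factor.BARREL_TYPE, Factor.BOTTLED_WINE) and n != 2:
            raise ValueError(f"factor {self.factor.value} requires exactly 2 groups")
        if self.factor == Factor.TIME and n < 3:
            raise ValueError("factor time requires >= 3 groups")

    @property
    def sample_ids(self) -> list[str]:
        """Union of all group members, group order preserved."""
        out: list[str] = []
        for ids in self.groups.values():
            out.extend(ids)
        return out

    @property
    def labels(self) -> list[str]:
        return list(self.groups)


# ---------------------------------------------------------------------------
# readers / writers


def _sniff_delimiter(path: str) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(4096)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_design_sheet(path: str) -> list[SampleDesign]:
    """Read the 6-column sample design CSV/TSV."""
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    missing = set(DESIGN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"design sheet missing columns: {sorted(missing)}")
    rows = [
        SampleDesign(
            sample_id=str(r.sample_id),
            cellar=str(r.cellar),
            barrel_type=str(r.barrel_type),
            vessel=str(r.vessel),
            timepoint_months=int(r.timepoint_months),
            replicate=int(r.replicate),
        )
        for r in df.itertuples(index=False)
    ]
    ids = [r.sample_id for r in rows]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in design sheet")
    return rows


def write_design_sheet(design: list[SampleDesign], path: str) -> None:
    pd.DataFrame([d.__dict__ for d in design]).to_csv(path, index=False)


def read_feature_matrix(
    path: str,
    platform: Platform | str,
    design: list[SampleDesign] | None = None,
    zeros_as_missing: bool | None = None,
) -> FeatureMatrix:
    """Read a delimited feature table into a validated :class:`FeatureMatrix`.

    The table has metabolites in rows and samples in columns (first column =
    metabolite id) or the transpose; orientation is auto-detected against the
    design sheet's sample ids when a design is given. Blank and NA cells are
    missing. Zeros are additionally treated as missing (left-censored
    non-detection) on untargeted platforms unless ``zeros_as_missing``
    overrides the default.
    """
    platform = Platform(platform)
    if zeros_as_missing is None:
        zeros_as_missing = platform.untargeted

    df = pd.read_csv(
        path, sep=_sniff_delimiter(path), index_col=0, float_precision="round_trip"
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate id in first column: {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate column header: {dup!r}")

    # orientation: metabolites-in-rows iff column headers match design ids
    if design is not None:
        design_ids = {d.sample_id for d in design}
        cols_match = set(df.columns) <= design_ids
        rows_match = set(df.index) <= design_ids
        if not cols_match and rows_match:
            df = df.T
        elif not cols_match and not rows_match:
            raise ValueError("neither table axis matches design sample ids")

    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        bad &= ~df[col].astype(str).str.upper().isin(["NA", "NAN", "N/A"])
        if bad.any():
            row = df.index[bad.argmax()]
            raise ValueError(f"non-numeric cell at row {row!r}, column {col!r}")
        df[col] = coerced

    values = df.to_numpy(dtype=float).T  # -> samples x metabolites
    mask = ~np.isfinite(values)
    if zeros_as_missing:
        mask |= values == 0
    values = values.copy()
    values[mask] = np.nan

    fm = FeatureMatrix(
        platform=platform,
        sample_ids=list(df.columns),
        metabolite_ids=list(df.index),
        values=values,
        missing_mask=mask,
    )
    logger.info(
        "read %s table: %d metabolites, %d samples, %d missing cells",
        platform.value,
        fm.n_metabolites,
        fm.n_samples,
        int(mask.sum()),
    )
    return fm


def write_feature_matrix(fm: FeatureMatrix, path: str) -> None:
    """Write metabolites-in-rows CSV; masked cells are left blank.

    Floats use shortest round-trip repr so write/read is bit-identical.
    """
    fm.to_frame().T.to_csv(path, float_format=lambda v: repr(float(v)))


# ---------------------------------------------------------------------------
# factor / group construction

FB_BARREL_MONTHS = (0, 3, 6, 9)
ICVV_BARREL_TYPE_MONTHS = (3, 9, 12)
ICVV_TIME_MONTHS = (3, 9)


def build_grouping(
    design: list[SampleDesign], factor: Factor | str, cellar: str
) -> FactorGrouping:
    """Construct the study's sample groups for one factor and cellar.

    FB barrel-type contrasts old vs new barrels over months 0/3/6/9 (four
    samples per group); FB time pools barrel types per month. ICVV
    barrel-type uses the 3/9/12-month barrel samples; ICVV time has groups
    3, 9, barrel-aged 12 and bottle-aged 12; the bottled-wine factor
    contrasts barrel- vs bottle-aged wine at month 12 (ICVV only).
    """
    factor = Factor(factor)
    rows = [d for d in design if d.cellar == cellar]
    if not rows:
        raise ValueError(f"design has no samples for cellar {cellar!r}")

    groups: dict[str, list[str]] = {}
    if factor == Factor.BARREL_TYPE:
        months = FB_BARREL_MONTHS if cellar == "FB" else ICVV_BARREL_TYPE_MONTHS
        for bt in ("old", "new"):
            groups[bt] = [
                d.sample_id
                for d in rows
                if d.vessel == "barrel"
                and d.barrel_type == bt
                and d.timepoint_months in months
            ]
    elif factor == Factor.TIME:
        if cellar == "FB":
            for month in FB_BARREL_MONTHS:
                groups[str(month)] = [
                    d.sample_id
                    for d in rows
                    if d.vessel == "barrel" and d.timepoint_months == month
                ]
        else:
            for month in ICVV_TIME_MONTHS:
                groups[str(month)] = [
                    d.sample_id
                    for d in rows
                    if d.vessel == "barrel" and d.timepoint_months == month
                ]
            groups["barrel12"] = [
                d.sample_id
                for d in rows
                if d.vessel == "barrel" and d.timepoint_months == 12
            ]
            groups["bottle12"] = [
                d.sample_id for d in rows if d.vessel == "bottle"
            ]
    else:  # bottled_wine
        if cellar != "ICVV":
            raise ValueError(
                f"factor bottled_wine undefined for cellar {cellar!r}: "
                "no bottled samples exist"
            )
        groups["barrel12"] = [
            d.sample_id
            for d in rows
            if d.vessel == "barrel" and d.timepoint_months == 12
        ]
        groups["bottle12"] = [d.sample_id for d in rows if d.vessel == "bottle"]

    groups = {k: v for k, v in groups.items() if v}
    return FactorGrouping(factor=factor, groups=groups)


# ---------------------------------------------------------------------------
# JSON serialization


def dump_json(obj: dict, path: str) -> None:
    """Write a result object as JSON with a schema-version field."""
    payload = {"schema_version": SCHEMA_VERSION, **obj}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, enum.Enum):
        return o.value
    raise TypeError(f"not JSON serializable: {type(o)}")
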