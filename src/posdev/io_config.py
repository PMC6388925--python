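"""Survey-table and configuration I/O for the positive-deviance pipeline.

The pipeline consumes a household-level table in the style of the Rural
Household Multiple Indicator Survey (RHoMIS): one row per interviewed
household, carrying resource endowments (land, livestock, household size in
male adult equivalents), dietary and food-security indicators, incomes,
greenhouse-gas emissions and intra-household decision-making shares.
This module reads and validates such tables (CSV or single-sheet XLSX),
loads the pipeline configuration, and reads the practice catalog used for
homologue-based practice targeting.
"""

from __future__ import annotations

import dataclasses

from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

__all__ = [
    "CANONICAL_COLUMNS",
    "HOUSEHOLD_TYPES",
    "INDICATOR_COLUMNS",
    "PipelineConfig",
    "ConfigError",
    "ValidationIssue",
    "ValidationReport",
    "read_household_table",
    "write_household_table",
    "validate_and_filter",
    "load_config",
    "read_practice_catalog",
]

#: Canonical column names, in canonical order.
CANONICAL_COLUMNS = [
    "household_id",
    "village_id",
    "region",
    "mae",
    "household_type",
    "land_ha",
    "livestock_tlu",
    "crop_diversity",
    "livestock_diversity",
    "market_orientation",
    "food_availability",
    "food_insecure_months",
    "hdds_good",
    "hdds_lean",
    "farm_income",
    "offfarm_income",
    "ghg_emissions",
    "female_share",
    "male_share",
]

#: Marital-status / headship categories of the survey.
HOUSEHOLD_TYPES = frozenset(
    {
        "couple",
        "single_woman",
        "single_man",
        "married_woman_absent_spouse",
        "married_man_absent_spouse",
    }
)

#: Fields required to compute the five performance indicators (rows with a
#: missing value in any of these are excluded listwise).
INDICATOR_COLUMNS = [
    "mae",
    "household_type",
    "food_availability",
    "food_insecure_months",
    "hdds_good",
    "hdds_lean",
    "farm_income",
    "offfarm_income",
    "ghg_emissions",
    "female_share",
    "male_share",
    "land_ha",
    "livestock_tlu",
    "market_orientation",
    "village_id",
    "region",
]

_NUMERIC_COLUMNS = [
    c for c in CANONICAL_COLUMNS if c not in ("household_id", "village_id", "region", "household_type")
]


#: (low, high) closed bounds per numeric field; None = unbounded on that side.
_FIELD_BOUNDS: dict[str, tuple[float | None, float | None]] = {
    "mae": (0.0, None),  # strictly positive, checked separately
    "land_ha": (0.0, None),
    "livestock_tlu": (0.0, None),
    "crop_diversity": (0.0, None),
    "livestock_diversity": (0.0, None),
    "market_orientation": (0.0, 1.0),
    "food_availability": (0.0, None),
    "food_insecure_months": (0.0, 12.0),
    "hdds_good": (0.0, 12.0),
    "hdds_lean": (0.0, 12.0),
    "farm_income": (0.0, None),
    "offfarm_income": (0.0, None),
    "ghg_emissions": (None, None),
    "female_share": (0.0, 1.0),
    "male_share": (0.0, 1.0),
}

_SHARE_TOLERANCE = 1e-6


class ConfigError(ValueError):
    """Raised for unreadable or invalid configuration files."""


_DEFAULT_GENDER_WEIGHTS = {
    "couple": 1.0,
    "single_woman": 0.5,
    "single_man": 0.5,
    "married_woman_absent_spouse": 1.0,
    "married_man_absent_spouse": 1.0,
}

_DEFAULT_PROXIES = {
    "agro_ecological_ability": "crop_diversity",
    "labor": "mae",
    "financial_capital": "farm_income + offfarm_income",
    "land_holdings": "land_ha",
    "livestock_holdings": "livestock_tlu",
    "social_capital": "market_access",
}

_DEFAULT_COVARIATES = ["land_ha", "livestock_tlu", "mae", "region", "market_access"]


class PipelineConfig(BaseModel, extra="forbid", validate_assignment=True):
    """Effective configuration of a pipeline run.

    Defaults encode the reference analysis: a 2,550 kcal/MAE/day caloric
    requirement (Tanzania's recommended daily intake), median (tau = 0.5)
    regression for relative performance, Pareto front depth 2, land-decile by
    livestock-median stratification, and three resource homologues per
    household.
    """

    kcal_requirement: float = Field(default=2550.0, gt=0)
    quantile_tau: float = 0.5
    cap_percentile: float = Field(default=99.0, gt=0, le=100)
    cap_low: bool = False
    #: absolute per-indicator overrides: {indicator: [low, high]} (null = open)
    cap_bounds: dict[str, tuple[float | None, float | None]] = Field(default_factory=dict)
    gender_weights: dict[str, float] = Field(default_factory=lambda: dict(_DEFAULT_GENDER_WEIGHTS))
    candidate_covariates: list[str] = Field(default_factory=lambda: list(_DEFAULT_COVARIATES))
    max_front_rank: int = Field(default=2, ge=1)
    n_land_deciles: int = Field(default=10, ge=2)
    homologue_k: int = Field(default=3, ge=1)
    homologue_include_self: bool = True
    crowding_within_selection: bool = True
    group_test: str = Field(default="welch", pattern="^(welch|student)$")
    resource_proxies: dict[str, str] = Field(default_factory=lambda: dict(_DEFAULT_PROXIES))
    column_map: dict[str, str] = Field(default_factory=dict)
    seed: int = 0

    @field_validator("quantile_tau")
    @classmethod
    def _tau_is_median(cls, v: float) -> float:
        if v != 0.5:
            raise ValueError(
                "quantile_tau must be 0.5: relative performance is defined on the median"
            )
        return v

    @field_validator("gender_weights")
    @classmethod
    def _known_types(cls, v: dict[str, float]) -> dict[str, float]:
        unknown = set(v) - HOUSEHOLD_TYPES
        if unknown:
            raise ValueError(f"unknown household types in gender_weights: {sorted(unknown)}")
        return v


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config file, applying defaults for absent keys.

    An empty file (or ``None``) yields the full default configuration.
    Raises :class:`ConfigError` with the line number for malformed YAML and
    for unknown or invalid keys.
    """
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"malformed config file{where}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ConfigError("config file must contain a mapping of keys to values")
    try:
        return PipelineConfig(**data)
    except Exception as exc:  # pydantic ValidationError
        raise ConfigError(f"invalid configuration: {exc}") from exc


@dataclasses.dataclass(frozen=True)
class ValidationIssue:
    household_id: str
    field: str
    message: str


@dataclasses.dataclass
class ValidationReport:
    """Outcome of table validation: per-record issues and drop counts."""

    issues: list[ValidationIssue] = dataclasses.field(default_factory=list)
    n_input: int = 0
    n_dropped: int = 0
    warnings: list[str] = dataclasses.field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_dropped

    def summary(self) -> dict[str, Any]:
        return {
            "n_input": self.n_input,
            "n_dropped": self.n_dropped,
            "n_kept": self.n_kept,
            "n_issues": len(self.issues),
            "warnings": list(self.warnings),
        }


def _resolve_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    return "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv"


def read_household_table(
    path: str | Path,
    format: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a household survey table into canonical columns.

    Parameters
    ----------
    path
        CSV or single-sheet XLSX file.
    format
        ``"csv"`` or ``"xlsx"``; inferred from the suffix when omitted.
    column_map
        Optional mapping from canonical name to the header used in the file,
        for adapting arbitrary survey exports without code changes.

    Records are returned in file order; numeric fields are parsed and missing
    values kept as NaN. Unknown ``household_type`` labels and out-of-range
    values are left in place for :func:`validate_and_filter` to report.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"household table not found: {path}")
    fmt = _resolve_format(path, format)
    if fmt == "csv":
        raw = pd.read_csv(path, dtype="object")
    elif fmt == "xlsx":
        raw = pd.read_excel(path, dtype="object")
    else:
        raise ValueError(f"unsupported format: {fmt!r} (expected 'csv' or 'xlsx')")

    rename = {src: canon for canon, src in (column_map or {}).items()}
    raw = raw.rename(columns=rename)
    missing = [c for c in CANONICAL_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"household table is missing required columns: {missing}")

    df = raw[CANONICAL_COLUMNS].copy()
    for col in ("household_id", "village_id", "region", "household_type"):
        df[col] = df[col].astype("string").str.strip()
    for col in _NUMERIC_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
    df.index = pd.RangeIndex(len(df))
    return df


def write_household_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a canonical household table to CSV (round-trip stable)."""
    df.to_csv(path, index=False)


def validate_and_filter(
    records: pd.DataFrame, config: PipelineConfig | None = None
) -> tuple[pd.DataFrame, ValidationReport]:
    """Validate records and drop those unusable for the five indicators.

    Rows with a missing or out-of-range value in any indicator-required field
    are excluded listwise and listed in the report. Duplicate household ids
    and villages spanning several regions violate table-level invariants and
    raise immediately; more than half the table failing validation aborts,
    since that signals a schema mismatch rather than scattered bad rows.
    """
    report = ValidationReport(n_input=len(records))
    df = records.copy()

    dup = df["household_id"][df["household_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicated household_id values: {sorted(dup.unique().tolist())}")

    vr = df.dropna(subset=["village_id", "region"]).groupby("village_id")["region"].nunique()
    multi = vr[vr > 1]
    if len(multi):
        raise ValueError(
            f"villages mapped to more than one region: {sorted(multi.index.tolist())}"
        )

    bad = pd.Series(False, index=df.index)

    for col in INDICATOR_COLUMNS:
        isna = df[col].isna()
        for idx in df.index[isna]:
            report.issues.append(
                ValidationIssue(str(df.at[idx, "household_id"]), col, "missing value")
            )
        bad |= isna

    unknown_type = df["household_type"].notna() & ~df["household_type"].isin(HOUSEHOLD_TYPES)
    for idx in df.index[unknown_type]:
        report.issues.append(
            ValidationIssue(
                str(df.at[idx, "household_id"]),
                "household_type",
                f"unknown label {df.at[idx, 'household_type']!r}",
            )
        )
    bad |= unknown_type

    for col, (lo, hi) in _FIELD_BOUNDS.items():
        vals = df[col]
        out = pd.Series(False, index=df.index)
        if lo is not None:
            out |= vals < lo
        if hi is not None:
            out |= vals > hi
        out &= vals.notna()
        for idx in df.index[out]:
            bound = f"[{lo if lo is not None else '-inf'},{hi if hi is not None else 'inf'}]"
            report.issues.append(
                ValidationIssue(
                    str(df.at[idx, "household_id"]), col, f"out of range {bound}"
                )
            )
        bad |= out

    nonpos_mae = df["mae"].notna() & (df["mae"] <= 0)
    for idx in df.index[nonpos_mae]:
        report.issues.append(
            ValidationIssue(str(df.at[idx, "household_id"]), "mae", "must be > 0")
        )
    bad |= nonpos_mae

    share_sum = df["female_share"] + df["male_share"]
    over = share_sum.notna() & (share_sum > 1.0 + _SHARE_TOLERANCE)
    for idx in df.index[over]:
        report.issues.append(
            ValidationIssue(
                str(df.at[idx, "household_id"]),
                "female_share",
                f"female_share + male_share = {share_sum[idx]:.4f} > 1",
            )
        )
    bad |= over

    neg_ghg = df["ghg_emissions"].notna() & (df["ghg_emissions"] < 0)
    if neg_ghg.any():
        report.warnings.append(
            f"{int(neg_ghg.sum())} record(s) report negative GHG emissions (kept, unusual)"
        )

    report.n_dropped = int(bad.sum())
    if report.n_input > 0 and report.n_dropped > report.n_input / 2:
        raise ValueError(
            f"{report.n_dropped}/{report.n_input} records failed validation; "
            "this indicates a schema or unit mismatch, aborting"
        )

    clean = df.loc[~bad].copy()
    clean.index = pd.RangeIndex(len(clean))
    return clean, report


def read_practice_catalog(path: str | Path) -> pd.DataFrame:
    """Read a practice catalog CSV (practice_code, positive_deviant_id, description).

    Returns one row per (practice, holder) pair; practice codes may repeat
    across holders but (code, holder) pairs must be unique.
    """
    cat = pd.read_csv(path, dtype="object")
    required = ["practice_code", "positive_deviant_id"]
    missing = [c for c in required if c not in cat.columns]
    if missing:
        raise ValueError(f"practice catalog is missing columns: {missing}")
    if "description" not in cat.columns:
        cat["description"] = ""
    for col in required:
        cat[col] = cat[col].astype("string").str.strip()
    dup = cat.duplicated(subset=required)
    if dup.any():
        raise ValueError("practice catalog contains duplicated (practice, holder) pairs")
    return cat[["practice_code", "positive_deviant_id", "description"]]
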