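"""File formats: registry CSV, benchmark CSV, YAML scenario configs.

Registry CSV schema (one header row, one row per resection)::

    hospital_id,year,procedure,tumour_type,cd_grade_3a_plus,death,
    readmission,los_days,margin_adequate,popf_bc,reoperation

Booleans are serialized as 0/1; optional fields absent for a procedure
family are empty strings.  Rates elsewhere are stored as decimals with six
significant digits next to their numerator/denominator, so printed-table
rounding is purely a formatting layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .definitions import Procedure, TumourType
from .registry import (
    REGISTRY_COLUMNS,
    ConfigError,
    HospitalProfile,
    ProcedureParams,
    SimConfig,
)

__all__ = [
    "write_registry",
    "read_registry",
    "validate_registry",
    "ValidationReport",
    "load_sim_config",
    "dump_sim_config",
    "write_rates",
]

_BOOL_COLS = ["cd_grade_3a_plus", "death", "readmission", "margin_adequate", "popf_bc", "reoperation"]
_LIVER_ONLY = ["margin_adequate"]
_PANCREAS_ONLY = ["popf_bc", "reoperation"]


def write_registry(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for col in _BOOL_COLS:
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else str(int(bool(v))))
    out["tumour_type"] = out["tumour_type"].map(lambda v: "" if pd.isna(v) else str(v))
    out[REGISTRY_COLUMNS].to_csv(path, index=False)


def read_registry(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"hospital_id": str, "procedure": str, "tumour_type": str},
        keep_default_na=False,
    )
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"registry is missing column(s): {', '.join(missing)}")

    def parse_bool(v):
        if v == "" or pd.isna(v):
            return pd.NA
        return bool(int(v))

    for col in _BOOL_COLS:
        df[col] = df[col].map(parse_bool)
    df["tumour_type"] = df["tumour_type"].map(lambda v: pd.NA if v == "" else v)
    df["year"] = df["year"].astype(int)
    df["los_days"] = df["los_days"].astype(int)
    return df[REGISTRY_COLUMNS]


@dataclass
class ValidationReport:
    """Registry validation outcome: (row, column, message) violations.

    Row numbers are 1-based data rows (header excluded) so they match what
    a reader sees in the file.
    """

    n_records: int = 0
    violations: list[tuple[int, str, str]] = field(default_factory=list)
    #: count of fully identical rows; informational, since the schema has no
    #: patient identifier and uneventful records legitimately coincide
    n_duplicates: int = 0

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_registry(df: pd.DataFrame) -> ValidationReport:
    """Check types, closed vocabularies, domains and conditional presence."""
    report = ValidationReport(n_records=len(df))
    procedures = {p.value for p in Procedure}
    tumours = {t.value for t in TumourType}
    liver = {Procedure.MINOR_LR.value, Procedure.MAJOR_LR.value}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.procedure not in procedures:
            report.violations.append((i, "procedure", f"unknown procedure {row.procedure!r}"))
            continue
        is_liver = row.procedure in liver
        if row.los_days < 0:
            report.violations.append((i, "los_days", f"negative length of stay {row.los_days}"))
        for col in ["cd_grade_3a_plus", "death", "readmission"]:
            if pd.isna(getattr(row, col)):
                report.violations.append((i, col, "missing required outcome component"))
        if is_liver:
            if pd.isna(row.margin_adequate):
                report.violations.append((i, "margin_adequate", "missing for liver resection"))
            if not pd.isna(row.popf_bc) or not pd.isna(row.reoperation):
                report.violations.append((i, "popf_bc", "pancreas-only field set on liver record"))
            if not pd.isna(row.tumour_type) and row.tumour_type not in tumours:
                report.violations.append((i, "tumour_type", f"unknown tumour type {row.tumour_type!r}"))
        else:
            if pd.isna(row.popf_bc):
                report.violations.append((i, "popf_bc", "missing for pancreatic resection"))
            if pd.isna(row.reoperation):
                report.violations.append((i, "reoperation", "missing for pancreatic resection"))
            if not pd.isna(row.margin_adequate):
                report.violations.append((i, "margin_adequate", "liver-only field set on pancreas record"))
            if not pd.isna(row.tumour_type):
                report.violations.append((i, "tumour_type", "tumour type set on pancreas record"))
    report.n_duplicates = int(df.duplicated().sum())
    return report


# ---------------------------------------------------------------------------
# Scenario configuration (YAML)
# ---------------------------------------------------------------------------

_PARAM_FIELDS = [
    "volume", "p_severe", "p_death_given_severe", "p_death_given_not_severe",
    "p_readmission", "p_margin_adequate", "p_popf_bc", "p_reoperation",
    "los_median", "los_dispersion",
]


def load_sim_config(path: str | Path, seed: int | None = None) -> SimConfig:
    """Parse a YAML scenario file; ``seed`` overrides the file's seed."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        hospitals = []
        for h in raw["hospitals"]:
            procedures = {}
            for pname, pdata in h["procedures"].items():
                kwargs = {k: pdata[k] for k in _PARAM_FIELDS if k in pdata}
                procedures[Procedure(pname)] = ProcedureParams(**kwargs)
            hospitals.append(HospitalProfile(hospital_id=str(h["hospital_id"]), procedures=procedures))
        years = tuple(int(y) for y in raw["years"])
        config = SimConfig(
            hospitals=hospitals,
            years=(years[0], years[-1]),
            seed=int(raw.get("seed", 0)) if seed is None else int(seed),
            label=str(raw.get("label", "")),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"malformed scenario config {path}: {exc}") from exc
    config.validate()
    return config


def dump_sim_config(config: SimConfig, path: str | Path) -> None:
    doc = {
        "label": config.label,
        "seed": config.seed,
        "years": list(config.years),
        "hospitals": [
            {
                "hospital_id": h.hospital_id,
                "procedures": {
                    proc.value: {
                        k: getattr(params, k)
                        for k in _PARAM_FIELDS
                        if getattr(params, k) is not None
                    }
                    for proc, params in h.procedures.items()
                },
            }
            for h in config.hospitals
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_rates(df: pd.DataFrame, path: str | Path, rate_cols: tuple[str, ...] = ("p0", "rate_min", "rate_max")) -> None:
    """Write a tidy rate table with 6-significant-digit decimals."""
    out = df.copy()
    for col in rate_cols:
        if col in out.columns:
            out[col] = out[col].map(lambda v: v if pd.isna(v) else float(f"{v:.6g}"))
    out.to_csv(path, index=False)
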