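"""Quality indicators and national benchmarks from patient-level records.

Four indicators per treatment group:

* mortality — death during the initial admission or within 30 days;
* major morbidity — Clavien-Dindo grade >= 3a complication;
* failure to rescue (FTR) — death *among* the severely-complicated
  (a conditional rate: its denominator is the major-morbidity numerator);
* composite — textbook outcome (TO) for liver resections, ideal outcome
  (IO) for pancreatic resections; an all-or-nothing conjunction.

The benchmark of an indicator is the patient-weighted pooled national rate
(total events / total eligible patients) over a year window, reported next
to the extremes of per-hospital rates.  Length-of-stay thresholds for the
composites are national nearest-rank percentiles per procedure group: the
90th for TO, the 75th for IO.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .definitions import (
    BenchmarkEntry,
    Indicator,
    LOS_PERCENTILE,
    Procedure,
)
from .registry import PatientRecord

logger = logging.getLogger(__name__)

NATIONAL = "NATIONAL"

__all__ = [
    "NATIONAL",
    "WrongProcedureError",
    "LOSThresholds",
    "IndicatorSummary",
    "mortality_flag",
    "major_morbidity_flag",
    "textbook_outcome_flag",
    "ideal_outcome_flag",
    "los_thresholds",
    "indicator_flags",
    "summarize",
    "ftr_summary",
    "benchmark",
    "benchmark_table",
]


class WrongProcedureError(ValueError):
    """A composite flag was requested for the wrong procedure family."""


@dataclass(frozen=True)
class LOSThresholds:
    """Nearest-rank length-of-stay thresholds per procedure group (days)."""

    thresholds: dict[Procedure, int]

    def __getitem__(self, procedure: Procedure) -> int:
        return self.thresholds[Procedure(procedure)]

    def __contains__(self, procedure: Procedure) -> bool:
        return Procedure(procedure) in self.thresholds


@dataclass(frozen=True)
class IndicatorSummary:
    """Numerator/denominator/rate of one indicator for one stratum.

    ``rate`` is NaN and ``undefined`` is True when the denominator is zero
    (e.g. FTR in a stratum without severe complications).
    """

    hospital_id: str
    procedure: Procedure
    indicator: Indicator
    window: tuple[int, int]
    numerator: int
    denominator: int

    @property
    def rate(self) -> float:
        if self.denominator == 0:
            return float("nan")
        return self.numerator / self.denominator

    @property
    def undefined(self) -> bool:
        return self.denominator == 0


def mortality_flag(record: PatientRecord) -> bool:
    """Death during initial admission or within 30 days of surgery."""
    return bool(record.death)


def major_morbidity_flag(record: PatientRecord) -> bool:
    """Clavien-Dindo grade >= 3a complication (death alone does not count)."""
    return bool(record.cd_grade_3a_plus)


def textbook_outcome_flag(record: PatientRecord, thresholds: LOSThresholds) -> bool:
    """Textbook outcome for a liver resection.

    True iff there was no severe complication, no death, no readmission,
    the stay did not exceed the national 90th percentile (inclusive), and
    resection margins were adequate.
    """
    procedure = Procedure(record.procedure)
    if not procedure.is_liver:
        raise WrongProcedureError(
            f"textbook outcome is defined for liver resections, got {procedure.value}"
        )
    return (
        not record.cd_grade_3a_plus
        and not record.death
        and not record.readmission
        and record.los_days <= thresholds[procedure]
        and bool(record.margin_adequate)
    )


def ideal_outcome_flag(record: PatientRecord, thresholds: LOSThresholds) -> bool:
    """Ideal outcome for a pancreatic resection.

    True iff there was no death, no severe complication, no grade B/C
    postoperative pancreatic fistula, no reoperation, the stay did not
    exceed the national 75th percentile (inclusive), and no readmission.
    """
    procedure = Procedure(record.procedure)
    if not procedure.is_pancreas:
        raise WrongProcedureError(
            f"ideal outcome is defined for pancreatic resections, got {procedure.value}"
        )
    return (
        not record.death
        and not record.cd_grade_3a_plus
        and not record.popf_bc
        and not record.reoperation
        and record.los_days <= thresholds[procedure]
        and not record.readmission
    )


def _window_mask(df: pd.DataFrame, window: tuple[int, int]) -> pd.Series:
    if window[1] < window[0]:
        raise ValueError(f"empty window {window}")
    return (df["year"] >= window[0]) & (df["year"] <= window[1])


def _nearest_rank(values: np.ndarray, q: float) -> int:
    """ceil(q*n)-th order statistic of the observed integer stays."""
    v = np.sort(np.asarray(values))
    k = int(math.ceil(q * len(v)))
    return int(v[max(k - 1, 0)])


def los_thresholds(df: pd.DataFrame, window: tuple[int, int]) -> LOSThresholds:
    """National per-procedure-group LOS thresholds over the window."""
    sub = df[_window_mask(df, window)]
    out: dict[Procedure, int] = {}
    for procedure in Procedure:
        values = sub.loc[sub["procedure"] == procedure.value, "los_days"].to_numpy()
        if len(values) == 0:
            continue
        out[procedure] = _nearest_rank(values, LOS_PERCENTILE[procedure])
    return LOSThresholds(out)


def _composite_required(procedure: Procedure) -> list[str]:
    if procedure.is_liver:
        return ["margin_adequate"]
    return ["popf_bc", "reoperation"]


def indicator_flags(
    df: pd.DataFrame,
    indicator: Indicator,
    procedure: Procedure,
    thresholds: LOSThresholds | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Vectorized (eligible, event) masks for one indicator in one group.

    ``eligible`` marks rows in the indicator's denominator; ``event`` marks
    rows in its numerator (always a subset of ``eligible``).  Rows missing
    a component required by the composite are excluded from its denominator
    and logged.
    """
    indicator = Indicator(indicator)
    procedure = Procedure(procedure)
    in_group = df["procedure"] == procedure.value
    if indicator is Indicator.MORTALITY:
        return in_group, in_group & df["death"].astype(bool)
    if indicator is Indicator.MAJOR_MORBIDITY:
        return in_group, in_group & df["cd_grade_3a_plus"].astype(bool)
    if indicator is Indicator.FTR:
        eligible = in_group & df["cd_grade_3a_plus"].astype(bool)
        return eligible, eligible & df["death"].astype(bool)
    if thresholds is None or procedure not in thresholds:
        raise ValueError("composite indicator needs LOS thresholds for this group")
    required = _composite_required(procedure)
    complete = in_group
    for col in required:
        complete = complete & df[col].notna()
    excluded = int(in_group.sum() - complete.sum())
    if excluded:
        logger.info(
            "%s %s: excluded %d record(s) with missing %s from the composite denominator",
            procedure.value, indicator.value, excluded, "/".join(required),
        )
    ok = (
        ~df["cd_grade_3a_plus"].astype(bool)
        & ~df["death"].astype(bool)
        & ~df["readmission"].astype(bool)
        & (df["los_days"] <= thresholds[procedure])
    )
    def as_bool(col: str, fill: bool) -> pd.Series:
        return df[col].map(lambda v: fill if pd.isna(v) else bool(v)).astype(bool)

    if procedure.is_liver:
        ok = ok & as_bool("margin_adequate", False)
    else:
        ok = ok & ~as_bool("popf_bc", True) & ~as_bool("reoperation", True)
    return complete, complete & ok


def summarize(
    df: pd.DataFrame,
    window: tuple[int, int],
    indicator: Indicator,
    procedure: Procedure,
    thresholds: LOSThresholds | None = None,
    include_national: bool = True,
) -> list[IndicatorSummary]:
    """Per-hospital (and national) summaries of one indicator.

    LOS thresholds for composites are computed nationally over the window
    when not supplied.  Hospitals with zero eligible records in the window
    are omitted; the national row sums the hospital rows exactly.
    """
    sub = df[_window_mask(df, window)]
    if Indicator(indicator) is Indicator.COMPOSITE and thresholds is None:
        thresholds = los_thresholds(df, window)
    eligible, event = indicator_flags(sub, indicator, procedure, thresholds)
    out: list[IndicatorSummary] = []
    for hospital_id in sorted(sub.loc[eligible, "hospital_id"].unique()):
        mask = sub["hospital_id"] == hospital_id
        out.append(
            IndicatorSummary(
                hospital_id=hospital_id,
                procedure=Procedure(procedure),
                indicator=Indicator(indicator),
                window=tuple(window),
                numerator=int((event & mask).sum()),
                denominator=int((eligible & mask).sum()),
            )
        )
    if include_national:
        out.append(
            IndicatorSummary(
                hospital_id=NATIONAL,
                procedure=Procedure(procedure),
                indicator=Indicator(indicator),
                window=tuple(window),
                numerator=int(event.sum()),
                denominator=int(eligible.sum()),
            )
        )
    return out


def ftr_summary(
    df: pd.DataFrame,
    procedure: Procedure,
    window: tuple[int, int] | None = None,
) -> IndicatorSummary:
    """Pooled failure-to-rescue summary for one treatment group.

    Denominator: records with a severe complication; numerator: those that
    also died.  A stratum without severe complications yields a summary with
    denominator 0 flagged ``undefined`` rather than an error.
    """
    if window is None:
        window = (int(df["year"].min()), int(df["year"].max())) if len(df) else (0, 0)
    sub = df[_window_mask(df, window)] if len(df) else df
    eligible, event = (
        indicator_flags(sub, Indicator.FTR, procedure)
        if len(sub)
        else (pd.Series(dtype=bool), pd.Series(dtype=bool))
    )
    return IndicatorSummary(
        hospital_id=NATIONAL,
        procedure=Procedure(procedure),
        indicator=Indicator.FTR,
        window=tuple(window),
        numerator=int(event.sum()),
        denominator=int(eligible.sum()),
    )


def benchmark(
    df: pd.DataFrame,
    window: tuple[int, int],
    indicator: Indicator,
    procedure: Procedure,
    thresholds: LOSThresholds | None = None,
) -> BenchmarkEntry:
    """National benchmark entry: pooled rate plus per-hospital extremes."""
    summaries = summarize(df, window, indicator, procedure, thresholds)
    national = summaries[-1]
    hospital_rates = [s.rate for s in summaries[:-1] if not s.undefined]
    if national.denominator == 0 or not hospital_rates:
        return BenchmarkEntry(
            procedure=Procedure(procedure),
            indicator=Indicator(indicator),
            p0=float("nan"), rate_min=float("nan"), rate_max=float("nan"),
            window=tuple(window), empty=True,
        )
    return BenchmarkEntry(
        procedure=Procedure(procedure),
        indicator=Indicator(indicator),
        p0=national.rate,
        rate_min=min(hospital_rates),
        rate_max=max(hospital_rates),
        window=tuple(window),
        numerator=national.numerator,
        denominator=national.denominator,
    )


def benchmark_table(df: pd.DataFrame, window: tuple[int, int]) -> pd.DataFrame:
    """Tidy benchmark frame over all procedure groups and indicators.

    Mirrors the layout consumed by :func:`hpbbench.power.threshold_table`;
    strata without eligible records are emitted with NaN rates and
    ``empty=True``.
    """
    thresholds = los_thresholds(df, window)
    rows = []
    for procedure in Procedure:
        for indicator in Indicator:
            if indicator is Indicator.COMPOSITE and procedure not in thresholds:
                entry = BenchmarkEntry(
                    procedure=procedure, indicator=indicator,
                    p0=float("nan"), rate_min=float("nan"), rate_max=float("nan"),
                    window=tuple(window), empty=True,
                )
            else:
                entry = benchmark(df, window, indicator, procedure, thresholds)
            rows.append(
                {
                    "procedure": procedure.value,
                    "indicator": indicator.value,
                    "p0": entry.p0,
                    "rate_min": entry.rate_min,
                    "rate_max": entry.rate_max,
                    "numerator": entry.numerator,
                    "denominator": entry.denominator,
                    "window_start": window[0],
                    "window_end": window[1],
                    "empty": entry.empty,
                }
            )
    return pd.DataFrame(rows)
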