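"""Closed vocabularies and published national benchmark rates.

The four treatment groups and four quality indicators used throughout the
package, plus the nationwide 2020-2021 benchmark rates of the Dutch
Hepatobiliary Audit (DHBA) and Dutch Pancreatic Cancer Audit (DPCA), which
parameterize the power analysis and the synthetic registry.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd


class Procedure(str, enum.Enum):
    """Treatment group of a resection."""

    MINOR_LR = "MINOR_LR"  # minor liver resection (< 3 adjacent segments)
    MAJOR_LR = "MAJOR_LR"  # major liver resection (>= 3 adjacent segments)
    PD = "PD"              # pancreatoduodenectomy
    DP = "DP"              # distal (left-sided) pancreatectomy

    @property
    def is_liver(self) -> bool:
        return self in (Procedure.MINOR_LR, Procedure.MAJOR_LR)

    @property
    def is_pancreas(self) -> bool:
        return not self.is_liver


class Indicator(str, enum.Enum):
    """Quality indicator.

    COMPOSITE is textbook outcome (TO) for liver groups and ideal outcome
    (IO) for pancreas groups; both are all-or-nothing conjunctions, so a
    *higher* rate is better, unlike the three adverse indicators.
    """

    MORTALITY = "MORTALITY"
    MAJOR_MORBIDITY = "MAJOR_MORBIDITY"
    FTR = "FTR"
    COMPOSITE = "COMPOSITE"

    @property
    def adverse(self) -> bool:
        """True when a higher rate means worse performance."""
        return self is not Indicator.COMPOSITE


class Direction(str, enum.Enum):
    """Side of the benchmark on which an outlier deviation is sought."""

    INCREASE = "increase"
    DECREASE = "decrease"

    @property
    def sign(self) -> int:
        return 1 if self is Direction.INCREASE else -1


def outlier_direction(indicator: Indicator) -> Direction:
    """Worse-performance direction for an indicator: adverse indicators go
    up, composite outcomes go down."""
    return Direction.INCREASE if indicator.adverse else Direction.DECREASE


class TumourType(str, enum.Enum):
    """Tumour types registered for liver resections."""

    CRLM = "CRLM"
    HCC = "HCC"
    PCCA = "pCCA"
    ICCA = "iCCA"


#: Length-of-stay percentile defining "prolonged stay" per procedure family:
#: textbook outcome (liver) uses the 90th percentile, ideal outcome
#: (pancreas) the 75th.
LOS_PERCENTILE = {
    Procedure.MINOR_LR: 0.90,
    Procedure.MAJOR_LR: 0.90,
    Procedure.PD: 0.75,
    Procedure.DP: 0.75,
}


@dataclass(frozen=True)
class BenchmarkEntry:
    """National benchmark of one indicator for one treatment group.

    ``p0`` is the patient-weighted pooled national event rate over the
    window; ``rate_min``/``rate_max`` are the extremes of per-hospital rates
    among hospitals with at least one eligible denominator case.  ``empty``
    flags a stratum with no eligible records (all rate fields are NaN then).
    """

    procedure: Procedure
    indicator: Indicator
    p0: float
    rate_min: float
    rate_max: float
    window: tuple[int, int]
    numerator: int = 0
    denominator: int = 0
    empty: bool = False


# Nationwide 2020-2021 benchmark rates (pooled national mean, with the
# across-hospital min-max) as published by the Dutch national HPB audits.
# Stored at the published 1-decimal percent precision, as fractions.
_NATIONAL_2020_2021 = [
    # (procedure, indicator, p0, min, max)
    (Procedure.MINOR_LR, Indicator.MORTALITY, 0.006, 0.000, 0.032),
    (Procedure.MAJOR_LR, Indicator.MORTALITY, 0.033, 0.000, 0.167),
    (Procedure.PD, Indicator.MORTALITY, 0.027, 0.000, 0.070),
    (Procedure.DP, Indicator.MORTALITY, 0.006, 0.000, 0.042),
    (Procedure.MINOR_LR, Indicator.MAJOR_MORBIDITY, 0.098, 0.000, 0.205),
    (Procedure.MAJOR_LR, Indicator.MAJOR_MORBIDITY, 0.281, 0.000, 0.471),
    (Procedure.PD, Indicator.MAJOR_MORBIDITY, 0.360, 0.158, 0.583),
    (Procedure.DP, Indicator.MAJOR_MORBIDITY, 0.223, 0.052, 0.461),
    (Procedure.MINOR_LR, Indicator.FTR, 0.054, 0.000, 0.333),
    (Procedure.MAJOR_LR, Indicator.FTR, 0.142, 0.000, 1.000),
    (Procedure.PD, Indicator.FTR, 0.075, 0.016, 0.285),
    (Procedure.DP, Indicator.FTR, 0.031, 0.000, 0.149),
    (Procedure.MINOR_LR, Indicator.COMPOSITE, 0.736, 0.613, 0.944),
    (Procedure.MAJOR_LR, Indicator.COMPOSITE, 0.541, 0.353, 1.000),
    (Procedure.PD, Indicator.COMPOSITE, 0.468, 0.253, 0.594),
    (Procedure.DP, Indicator.COMPOSITE, 0.633, 0.307, 0.846),
]


def national_benchmarks() -> pd.DataFrame:
    """Published nationwide 2020-2021 benchmark table.

    Returns a tidy frame with columns ``procedure``, ``indicator``, ``p0``,
    ``rate_min``, ``rate_max``, ``window_start``, ``window_end``.  These are
    the rates a transcribed benchmark file would carry; the synthetic
    registry emulates them and the power analysis consumes them.
    """
    rows = [
        {
            "procedure": proc.value,
            "indicator": ind.value,
            "p0": p0,
            "rate_min": lo,
            "rate_max": hi,
            "window_start": 2020,
            "window_end": 2021,
        }
        for proc, ind, p0, lo, hi in _NATIONAL_2020_2021
    ]
    return pd.DataFrame(rows)
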