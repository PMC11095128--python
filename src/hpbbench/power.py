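"""Sample-size mathematics for outlier detection in hospital benchmarking.

Every quantity here derives from the one-sample proportion test on the
variance-stabilizing (arcsine) scale.  With benchmark rate ``p0`` and a
hospital rate ``p1``, Cohen's effect size

    h = 2*arcsin(sqrt(p1)) - 2*arcsin(sqrt(p0))

has approximate sampling standard deviation ``1/sqrt(n)`` for a hospital of
volume ``n``, so the total volume required to detect the deviation with
two-sided significance ``alpha`` and power ``1-beta`` is

    n = ((z_{1-alpha/2} + z_{1-beta}) / h)^2 .

The closed-form inverse — the smallest deviation a hospital of volume ``n``
can demonstrate — is

    p1 = sin^2( arcsin(sqrt(p0)) +/- (z_{1-alpha/2} + z_{1-beta}) / (2*sqrt(n)) ),

with ``+`` for adverse indicators (mortality, major morbidity, failure to
rescue: an outlier is *above* the benchmark) and ``-`` for composite
outcomes (textbook/ideal outcome: an outlier is *below*).  Annual minimum
volumes follow by dividing the required total by the number of pooled
registration years and taking the floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .definitions import Direction, Indicator, Procedure, outlier_direction

__all__ = [
    "PowerSpec",
    "ThresholdCell",
    "VolumeRequirement",
    "effect_size_h",
    "required_n",
    "detectable_difference",
    "min_annual_volume",
    "adequacy_report",
    "threshold_table",
    "volume_requirement_table",
    "SCENARIOS",
]

#: Default volume grid: the current Dutch minimum annual volume (20), the
#: proposed new minimums (50-100), and one- and two-year accumulations.
DEFAULT_VOLUMES = (20, 40, 50, 100, 200)

#: Named deviation scenarios: a rate at two-fold the benchmark, and absolute
#: 2-, 5- and 15-percentage-point deviations (increases for adverse
#: indicators, decreases for composite outcomes).
SCENARIOS = ("two_fold", "2pt", "5pt", "15pt")

#: Pooled registration-year horizons considered for volume adequacy.
DEFAULT_POOLING_YEARS = (1, 2, 3, 5, 8)


def _round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, matching printed-table formatting."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PowerSpec:
    """Significance level and power governing all sample-size math.

    Parameters
    ----------
    alpha
        Two-sided significance level of the one-sample proportion test.
    power
        Target power ``1 - beta`` against the design alternative.

    The normal quantiles are computed at double precision
    (``z_alpha ~= 1.959964``, ``z_beta ~= 0.841621`` at the defaults), not
    the two-decimal textbook values.
    """

    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 < self.power < 1.0:
            raise ValueError(f"power must be in (0, 1), got {self.power}")

    @property
    def z_alpha(self) -> float:
        """Upper ``alpha/2`` standard-normal quantile."""
        return float(norm.ppf(1.0 - self.alpha / 2.0))

    @property
    def z_beta(self) -> float:
        """Upper ``1 - power`` standard-normal quantile."""
        return float(norm.ppf(self.power))


@dataclass(frozen=True)
class ThresholdCell:
    """Smallest detectable absolute deviation at one volume.

    ``difference`` is the unrounded absolute deviation ``|p1 - p0|`` as a
    fraction; ``difference_points`` is the reporting value in percentage
    points, rounded half-up to one decimal.  ``saturated`` marks cells where
    the arcsine inversion left [0, 1] before clipping (no rate that extreme
    exists), in which case the difference is reported at the clipped
    boundary.
    """

    p0: float
    n: int
    direction: Direction
    p1: float
    difference: float
    saturated: bool = False
    procedure: Procedure | None = None
    indicator: Indicator | None = None

    @property
    def difference_points(self) -> float:
        return _round_half_up(100.0 * self.difference, 1)


@dataclass(frozen=True)
class VolumeRequirement:
    """Total and annual volume needed to detect a given deviation.

    ``annual_volume = floor(n_total / years)``: the smallest constant annual
    caseload that accumulates the required total within the pooling window.
    """

    p0: float
    delta: float
    direction: Direction
    years: int
    n_total: float
    annual_volume: int
    scenario: str = ""
    procedure: Procedure | None = None
    indicator: Indicator | None = None


def _check_proportion(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be a proportion in [0, 1], got {p}")


def effect_size_h(p0: float, p1: float) -> float:
    """Cohen's h, the arcsine-transformed difference of two proportions.

    Antisymmetric in its arguments; ranges over ``[-pi, pi]``.
    """
    _check_proportion("p0", p0)
    _check_proportion("p1", p1)
    return 2.0 * math.asin(math.sqrt(p1)) - 2.0 * math.asin(math.sqrt(p0))


def required_n(p0: float, p1: float, spec: PowerSpec = PowerSpec()) -> float:
    """Continuous total sample size to detect ``p1`` against benchmark ``p0``.

    Returns ``math.inf`` when ``p0 == p1`` (no deviation is detectable at
    any volume); callers decide how to round.
    """
    h = effect_size_h(p0, p1)
    if h == 0.0:
        return math.inf
    return ((spec.z_alpha + spec.z_beta) / h) ** 2


def detectable_difference(
    p0: float,
    n: int,
    direction: Direction = Direction.INCREASE,
    spec: PowerSpec = PowerSpec(),
    *,
    procedure: Procedure | None = None,
    indicator: Indicator | None = None,
) -> ThresholdCell:
    """Smallest detectable absolute deviation from ``p0`` at total volume ``n``.

    Closed-form inversion of :func:`required_n` on the arcsine scale; the
    deviation is upward for ``Direction.INCREASE`` and downward for
    ``Direction.DECREASE``.  When the shifted arcsine argument leaves
    ``[0, pi/2]`` the returned ``p1`` is clipped to {0, 1} and the cell is
    flagged ``saturated``.
    """
    _check_proportion("p0", p0)
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    direction = Direction(direction)
    shift = (spec.z_alpha + spec.z_beta) / (2.0 * math.sqrt(n))
    theta = math.asin(math.sqrt(p0)) + direction.sign * shift
    saturated = not 0.0 <= theta <= math.pi / 2.0
    theta_c = min(max(theta, 0.0), math.pi / 2.0)
    p1 = math.sin(theta_c) ** 2
    return ThresholdCell(
        p0=p0,
        n=n,
        direction=direction,
        p1=p1,
        difference=abs(p1 - p0),
        saturated=saturated,
        procedure=procedure,
        indicator=indicator,
    )


def min_annual_volume(
    p0: float,
    delta: float,
    direction: Direction = Direction.INCREASE,
    years: int = 1,
    spec: PowerSpec = PowerSpec(),
    *,
    scenario: str = "",
    procedure: Procedure | None = None,
    indicator: Indicator | None = None,
) -> VolumeRequirement:
    """Minimum constant annual volume to detect an absolute deviation ``delta``
    from ``p0`` when pooling ``years`` consecutive registration years."""
    if delta <= 0.0:
        raise ValueError(f"delta must be > 0, got {delta}")
    if years < 1:
        raise ValueError(f"years must be >= 1, got {years}")
    direction = Direction(direction)
    p1 = p0 + direction.sign * delta
    _check_proportion("p1 = p0 +/- delta", p1)
    n_total = required_n(p0, p1, spec)
    return VolumeRequirement(
        p0=p0,
        delta=delta,
        direction=direction,
        years=years,
        n_total=n_total,
        annual_volume=int(math.floor(n_total / years)),
        scenario=scenario,
        procedure=procedure,
        indicator=indicator,
    )


def adequacy_report(
    annual_volumes: Mapping[str, Sequence[int]],
    requirement: VolumeRequirement,
    pooling_years: int | None = None,
) -> pd.DataFrame:
    """Which hospitals accumulate the required total volume.

    Parameters
    ----------
    annual_volumes
        Per-hospital sequences of annual caseloads (most recent years; only
        the last ``pooling_years`` entries are summed).
    requirement
        The volume requirement to test against (its ``n_total`` is the bar).
    pooling_years
        Number of years pooled; defaults to ``requirement.years``.

    Returns a frame with one row per hospital (``hospital_id``,
    ``pooled_volume``, ``meets_requirement``) carrying the overall
    proportion in ``df.attrs["proportion_meeting"]`` (NaN when the hospital
    list is empty, flagged via ``df.attrs["empty"]``).
    """
    k = requirement.years if pooling_years is None else pooling_years
    rows = []
    for hospital_id in sorted(annual_volumes):
        vols = list(annual_volumes[hospital_id])
        if any(v < 0 for v in vols):
            raise ValueError(f"negative volume for hospital {hospital_id!r}")
        pooled = int(sum(vols[-k:]))
        rows.append(
            {
                "hospital_id": hospital_id,
                "pooled_volume": pooled,
                "meets_requirement": pooled >= requirement.n_total,
            }
        )
    df = pd.DataFrame(rows, columns=["hospital_id", "pooled_volume", "meets_requirement"])
    df.attrs["empty"] = df.empty
    df.attrs["proportion_meeting"] = float(df["meets_requirement"].mean()) if len(df) else float("nan")
    df.attrs["required_total"] = requirement.n_total
    return df


def _benchmark_lookup(benchmarks: pd.DataFrame) -> dict[tuple[Procedure, Indicator], float]:
    out: dict[tuple[Procedure, Indicator], float] = {}
    for row in benchmarks.itertuples(index=False):
        out[(Procedure(row.procedure), Indicator(row.indicator))] = float(row.p0)
    return out


def threshold_table(
    benchmarks: pd.DataFrame,
    volumes: Iterable[int] = DEFAULT_VOLUMES,
    spec: PowerSpec = PowerSpec(),
) -> pd.DataFrame:
    """Detectable-difference grid over indicators, volumes and procedures.

    ``benchmarks`` is a tidy frame with ``procedure``, ``indicator`` and
    ``p0`` columns (e.g. :func:`~hpbbench.definitions.national_benchmarks`
    or the output of the indicators stage).  Adverse indicators are inverted
    upward, composite outcomes downward.  Missing benchmark entries yield
    rows with NaN differences flagged ``absent`` so the grid shape is always
    complete.
    """
    lookup = _benchmark_lookup(benchmarks)
    rows = []
    for indicator in Indicator:
        for n in volumes:
            for procedure in Procedure:
                key = (procedure, indicator)
                if key not in lookup:
                    rows.append(
                        {
                            "indicator": indicator.value,
                            "volume": int(n),
                            "procedure": procedure.value,
                            "p0": float("nan"),
                            "p1": float("nan"),
                            "difference": float("nan"),
                            "difference_points": float("nan"),
                            "direction": outlier_direction(indicator).value,
                            "saturated": False,
                            "absent": True,
                        }
                    )
                    continue
                cell = detectable_difference(
                    lookup[key],
                    int(n),
                    outlier_direction(indicator),
                    spec,
                    procedure=procedure,
                    indicator=indicator,
                )
                rows.append(
                    {
                        "indicator": indicator.value,
                        "volume": int(n),
                        "procedure": procedure.value,
                        "p0": cell.p0,
                        "p1": cell.p1,
                        "difference": cell.difference,
                        "difference_points": cell.difference_points,
                        "direction": cell.direction.value,
                        "saturated": cell.saturated,
                        "absent": False,
                    }
                )
    return pd.DataFrame(rows)


def _scenario_delta(scenario: str, p0: float) -> float:
    if scenario == "two_fold":
        return p0
    if scenario.endswith("pt"):
        return float(scenario[:-2]) / 100.0
    raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")


def volume_requirement_table(
    benchmarks: pd.DataFrame,
    scenarios: Iterable[str] = SCENARIOS,
    years: Iterable[int] = DEFAULT_POOLING_YEARS,
    spec: PowerSpec = PowerSpec(),
) -> pd.DataFrame:
    """Minimum annual volumes for the named deviation scenarios.

    Scenario deltas apply as increases to adverse indicators and decreases
    to composite outcomes; combinations where the shifted rate leaves
    [0, 1] (e.g. a two-fold composite rate above 50%) are emitted with NaN
    and flagged ``infeasible``.
    """
    lookup = _benchmark_lookup(benchmarks)
    rows = []
    for (procedure, indicator), p0 in lookup.items():
        direction = outlier_direction(indicator)
        for scenario in scenarios:
            delta = _scenario_delta(scenario, p0)
            p1 = p0 + direction.sign * delta
            # a two-fold rate is an *adverse* scenario; for composites the
            # doubling would move in the better direction, so it is skipped
            feasible = (
                delta > 0.0
                and 0.0 <= p1 <= 1.0
                and not (scenario == "two_fold" and direction is Direction.DECREASE)
            )
            for k in years:
                if not feasible:
                    rows.append(
                        {
                            "procedure": procedure.value,
                            "indicator": indicator.value,
                            "scenario": scenario,
                            "years": int(k),
                            "n_total": float("nan"),
                            "annual_volume": np.nan,
                            "infeasible": True,
                        }
                    )
                    continue
                req = min_annual_volume(
                    p0, delta, direction, int(k), spec,
                    scenario=scenario, procedure=procedure, indicator=indicator,
                )
                rows.append(
                    {
                        "procedure": procedure.value,
                        "indicator": indicator.value,
                        "scenario": scenario,
                        "years": int(k),
                        "n_total": req.n_total,
                        "annual_volume": req.annual_volume,
                        "infeasible": False,
                    }
                )
    return pd.DataFrame(rows)
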