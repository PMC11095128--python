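"""Funnel-plot prediction limits and outlier classification.

Limits around the benchmark ``p0`` as a function of hospital volume ``n``,
at a configurable level (default 95%).  Two constructions:

* ``exact`` (default): the two-sided exact-binomial region with at most
  ``alpha/2`` tail mass strictly outside each limit.  The upper limit count
  is the largest ``c`` with ``P(X >= c) > alpha/2`` under Binomial(n, p0)
  (so ``P(X > upper) <= alpha/2``), and symmetrically below.  At the small
  volumes and rare events typical of HPB audits (n ~ 20, p0 ~ 0.6%) this is
  the only construction with guaranteed coverage.
* ``normal``: ``p0 +/- z * sqrt(p0 (1 - p0) / n)``, for comparability with
  common funnel-plot software; anticonservative for rare events.

A hospital is an outlier only when *strictly* outside the limits; counts
exactly on a limit are within.  Worse performance is above the upper limit
for adverse indicators and below the lower limit for composite outcomes;
better-side deviations are reported but flagged informational.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom, norm

from .definitions import Indicator, LOS_PERCENTILE, Procedure
from .indicators import IndicatorSummary
from .power import PowerSpec
from .registry import ProcedureParams, _nbinom_params_for_median, expected_rates

__all__ = [
    "FunnelMethod",
    "OutlierStatus",
    "FunnelCurve",
    "OutlierCall",
    "funnel_limits",
    "limit_counts",
    "classify",
    "detection_rate",
]


class FunnelMethod(str, enum.Enum):
    EXACT = "exact"
    NORMAL = "normal"


class OutlierStatus(str, enum.Enum):
    WITHIN = "WITHIN"
    WORSE = "WORSE"
    BETTER = "BETTER"


@dataclass(frozen=True)
class FunnelCurve:
    """Volume-indexed prediction limits around a benchmark."""

    p0: float
    level: float
    method: FunnelMethod
    table: pd.DataFrame  # columns: volume, lower, upper

    def limits_at(self, n: int) -> tuple[float, float]:
        """Lower/upper limit rates at volume ``n`` (computed on demand when
        ``n`` is absent from the grid)."""
        hit = self.table[self.table["volume"] == n]
        if len(hit):
            row = hit.iloc[0]
            return float(row["lower"]), float(row["upper"])
        lo, up = _limits_one(self.p0, int(n), self.level, self.method)
        return lo, up


@dataclass(frozen=True)
class OutlierCall:
    hospital_id: str
    procedure: Procedure
    indicator: Indicator
    observed_rate: float
    volume: int
    status: OutlierStatus
    lower: float
    upper: float


def limit_counts(p0: float, n: int, level: float = 0.95) -> tuple[int, int]:
    """Exact-binomial limit *counts* (lower, upper) at volume ``n``.

    ``upper`` is the largest count with upper-tail mass above ``alpha/2``;
    ``lower`` the smallest count with lower-tail mass above ``alpha/2``.
    Counts strictly outside [lower, upper] have total probability at most
    ``1 - level`` under Binomial(n, p0).
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    a2 = (1.0 - level) / 2.0
    upper = int(binom.isf(a2, n, p0))
    lower = int(binom.ppf(a2, n, p0))
    return lower, upper


def _limits_one(p0: float, n: int, level: float, method: FunnelMethod) -> tuple[float, float]:
    if FunnelMethod(method) is FunnelMethod.EXACT:
        lo_c, up_c = limit_counts(p0, n, level)
        return lo_c / n, up_c / n
    z = float(norm.ppf(1.0 - (1.0 - level) / 2.0))
    half = z * math.sqrt(p0 * (1.0 - p0) / n)
    return max(p0 - half, 0.0), min(p0 + half, 1.0)


def funnel_limits(
    p0: float,
    volumes: Iterable[int],
    level: float = 0.95,
    method: FunnelMethod = FunnelMethod.EXACT,
) -> FunnelCurve:
    """Prediction limits over a volume grid."""
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0 must be in [0, 1], got {p0}")
    method = FunnelMethod(method)
    rows = []
    for n in volumes:
        n = int(n)
        if n < 1:
            raise ValueError(f"volumes must be >= 1, got {n}")
        lo, up = _limits_one(p0, n, level, method)
        rows.append({"volume": n, "lower": lo, "upper": up})
    return FunnelCurve(p0=p0, level=level, method=method, table=pd.DataFrame(rows))


def classify(
    summaries: Sequence[IndicatorSummary],
    curve: FunnelCurve,
) -> list[OutlierCall]:
    """Classify hospital summaries against a funnel curve.

    Classification is performed on counts for the exact method (no floating
    drift across the limit) and on rates for the normal method.  WORSE is
    the policy-relevant side: above the upper limit for adverse indicators,
    below the lower limit for composite outcomes; the opposite side is
    reported as BETTER (informational).
    """
    calls: list[OutlierCall] = []
    for s in summaries:
        if s.undefined:
            continue
        n = s.denominator
        lower, upper = curve.limits_at(n)
        if curve.method is FunnelMethod.EXACT:
            lo_c, up_c = limit_counts(curve.p0, n, curve.level)
            above = s.numerator > up_c
            below = s.numerator < lo_c
        else:
            above = s.rate > upper
            below = s.rate < lower
        if s.indicator.adverse:
            status = (
                OutlierStatus.WORSE if above
                else OutlierStatus.BETTER if below
                else OutlierStatus.WITHIN
            )
        else:
            status = (
                OutlierStatus.WORSE if below
                else OutlierStatus.BETTER if above
                else OutlierStatus.WITHIN
            )
        calls.append(
            OutlierCall(
                hospital_id=s.hospital_id,
                procedure=s.procedure,
                indicator=s.indicator,
                observed_rate=s.rate,
                volume=n,
                status=status,
                lower=lower,
                upper=upper,
            )
        )
    return calls


def _arcsine_reject(counts: np.ndarray, n: np.ndarray, p0: float, spec: PowerSpec) -> np.ndarray:
    """Two-sided one-sample proportion test on the arcsine scale."""
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (2.0 * np.arcsin(np.sqrt(counts / n)) - 2.0 * np.arcsin(np.sqrt(p0))) * np.sqrt(n)
    return np.abs(z) > spec.z_alpha


def detection_rate(
    params: ProcedureParams,
    procedure: Procedure,
    indicator: Indicator,
    p0: float,
    n: int,
    replicates: int = 2000,
    seed: int = 0,
    classifier: str = "ztest",
    level: float = 0.95,
    spec: PowerSpec = PowerSpec(),
    los_threshold: int | None = None,
) -> float:
    """Empirical probability that an outlier hospital is flagged.

    Simulates ``replicates`` realisations of one hospital's counts at
    volume ``n`` from the generative model in ``params`` and classifies
    each against benchmark ``p0``:

    * ``classifier="ztest"`` — two-sided one-sample proportion test on the
      arcsine scale at the level in ``spec`` (rejection counted only on the
      worse side);
    * ``classifier="funnel"`` — strict exceedance of the exact-binomial
      funnel limit at ``level``.

    For FTR the volume ``n`` is the number of severely-complicated cases
    (the indicator's denominator).  For composites the event probability is
    the analytic composite rate of ``params``; ``los_threshold`` (with the
    LOS distribution of ``params``) overrides the nominal LOS pass
    probability when supplied.
    """
    indicator = Indicator(indicator)
    procedure = Procedure(procedure)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=[seed, n]))
    rates = expected_rates(params, procedure)
    if indicator is Indicator.FTR:
        counts = rng.binomial(n, params.p_death_given_severe, size=replicates)
    elif indicator is Indicator.COMPOSITE and los_threshold is not None:
        from scipy.stats import nbinom as _nb

        r, p = _nbinom_params_for_median(params.los_median, params.los_dispersion)
        los_pass = float(_nb.cdf(los_threshold, r, p))
        p_event = rates[indicator] / LOS_PERCENTILE[procedure] * los_pass
        counts = rng.binomial(n, p_event, size=replicates)
    else:
        counts = rng.binomial(n, rates[indicator], size=replicates)
    nn = np.full(replicates, n, dtype=float)
    if classifier == "ztest":
        reject = _arcsine_reject(counts, nn, p0, spec)
        worse = counts / nn > p0 if indicator.adverse else counts / nn < p0
        flagged = reject & worse
    elif classifier == "funnel":
        lo_c, up_c = limit_counts(p0, n, level)
        flagged = counts > up_c if indicator.adverse else counts < lo_c
    else:
        raise ValueError(f"unknown classifier {classifier!r}")
    return float(flagged.mean())
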