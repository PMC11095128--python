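"""Synthetic patient-level audit registries.

Generates seeded registries with the statistical structure of the Dutch
national HPB audits: per hospital, procedure group and year, a configured
number of resections with outcome components drawn from configurable
probabilities.  Death is generated *conditionally* on a severe
(Clavien-Dindo >= 3a) complication, so failure to rescue is a well-defined
free parameter; all other components are independent.  Length of stay is
negative-binomial (overdispersed counts), parameterized by its median and a
dispersion size.

Randomness is organised as one master seed with per-(hospital, procedure,
year) substreams derived from a stable hash of the hospital label, so adding
or removing a hospital never perturbs the records of the others.
"""

from __future__ import annotations

import copy
import functools
import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import nbinom

from .definitions import Indicator, LOS_PERCENTILE, Procedure

__all__ = [
    "ConfigError",
    "ProcedureParams",
    "HospitalProfile",
    "SimConfig",
    "PatientRecord",
    "simulate_registry",
    "scenario_with_outlier",
    "expected_rates",
    "study_config",
    "REGISTRY_COLUMNS",
]

#: Canonical column order of the registry CSV schema.
REGISTRY_COLUMNS = [
    "hospital_id",
    "year",
    "procedure",
    "tumour_type",
    "cd_grade_3a_plus",
    "death",
    "readmission",
    "los_days",
    "margin_adequate",
    "popf_bc",
    "reoperation",
]


class ConfigError(ValueError):
    """A simulation configuration field is invalid; the message names it."""


def _check_prob(name: str, p: float | None, required: bool) -> None:
    if p is None:
        if required:
            raise ConfigError(f"{name} is required for this procedure family")
        return
    if not 0.0 <= p <= 1.0:
        raise ConfigError(f"{name} must be in [0, 1], got {p}")


@dataclass
class ProcedureParams:
    """Generative parameters of one procedure group at one hospital.

    Liver groups require ``p_margin_adequate`` and must leave the pancreas
    fields unset; pancreas groups require ``p_popf_bc`` and
    ``p_reoperation``.  ``p_death_given_severe`` is the failure-to-rescue
    probability.  ``los_median``/``los_dispersion`` parameterize a negative
    binomial length-of-stay (dispersion is the nbinom size; smaller means
    heavier tail).
    """

    volume: int
    p_severe: float
    p_death_given_severe: float
    p_death_given_not_severe: float
    p_readmission: float
    p_margin_adequate: float | None = None
    p_popf_bc: float | None = None
    p_reoperation: float | None = None
    los_median: float = 7.0
    los_dispersion: float = 4.0

    def validate(self, procedure: Procedure) -> None:
        if int(self.volume) != self.volume or self.volume < 0:
            raise ConfigError(f"volume must be a non-negative integer, got {self.volume}")
        _check_prob("p_severe", self.p_severe, True)
        _check_prob("p_death_given_severe", self.p_death_given_severe, True)
        _check_prob("p_death_given_not_severe", self.p_death_given_not_severe, True)
        _check_prob("p_readmission", self.p_readmission, True)
        if procedure.is_liver:
            _check_prob("p_margin_adequate", self.p_margin_adequate, True)
            if self.p_popf_bc is not None or self.p_reoperation is not None:
                raise ConfigError(
                    "p_popf_bc/p_reoperation must be unset for liver procedures"
                )
        else:
            _check_prob("p_popf_bc", self.p_popf_bc, True)
            _check_prob("p_reoperation", self.p_reoperation, True)
            if self.p_margin_adequate is not None:
                raise ConfigError("p_margin_adequate must be unset for pancreas procedures")
        if self.los_median <= 0:
            raise ConfigError(f"los_median must be > 0, got {self.los_median}")
        if self.los_dispersion <= 0:
            raise ConfigError(f"los_dispersion must be > 0, got {self.los_dispersion}")


@dataclass
class HospitalProfile:
    hospital_id: str
    procedures: dict[Procedure, ProcedureParams] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.hospital_id:
            raise ConfigError("hospital_id must be non-empty")
        for proc, params in self.procedures.items():
            params.validate(Procedure(proc))


@dataclass
class SimConfig:
    """A complete registry scenario: hospitals, window and master seed."""

    hospitals: list[HospitalProfile]
    years: tuple[int, int] = (2020, 2021)
    seed: int = 0
    label: str = ""

    def validate(self) -> None:
        if self.years[1] < self.years[0]:
            raise ConfigError(f"empty year range {self.years}")
        seen: set[str] = set()
        for hosp in self.hospitals:
            hosp.validate()
            if hosp.hospital_id in seen:
                raise ConfigError(f"duplicate hospital_id {hosp.hospital_id!r}")
            seen.add(hosp.hospital_id)


@dataclass(frozen=True)
class PatientRecord:
    """One resection with its outcome components; the atomic audit row."""

    hospital_id: str
    year: int
    procedure: Procedure
    cd_grade_3a_plus: bool
    death: bool
    readmission: bool
    los_days: int
    tumour_type: str | None = None
    margin_adequate: bool | None = None
    popf_bc: bool | None = None
    reoperation: bool | None = None


def _stable_hash(label: str) -> int:
    return int.from_bytes(hashlib.sha256(label.encode()).digest()[:8], "little")


def _substream(seed: int, hospital_id: str, proc_index: int, year: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=[seed, _stable_hash(hospital_id), proc_index, year])
    return np.random.default_rng(ss)


@functools.lru_cache(maxsize=256)
def _nbinom_params_for_median(median: float, dispersion: float) -> tuple[float, float]:
    """Negative-binomial (n, p) whose median is (approximately) ``median``.

    The nbinom median is a step function of the mean, so the mean is located
    by bisection at the centre of the plateau achieving the target.
    """
    r = dispersion
    target = float(np.floor(median))

    def med(mu: float) -> float:
        return float(nbinom.median(r, r / (r + mu)))

    def smallest_mu_reaching(m: float) -> float:
        lo, hi = 1e-9, 10.0 * (m + 1.0) + 10.0
        while med(hi) < m:
            hi *= 2.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if med(mid) >= m:
                hi = mid
            else:
                lo = mid
        return hi

    mu = 0.5 * (smallest_mu_reaching(target) + smallest_mu_reaching(target + 1.0))
    return r, r / (r + mu)


_LIVER_TUMOURS = np.array(["CRLM", "HCC", "pCCA", "iCCA"])
_LIVER_TUMOUR_W = np.array([0.60, 0.20, 0.10, 0.10])  # CRLM-dominant case mix


def _simulate_block(
    hospital_id: str,
    procedure: Procedure,
    year: int,
    params: ProcedureParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = int(params.volume)
    severe = rng.random(n) < params.p_severe
    u_death = rng.random(n)
    death = np.where(
        severe,
        u_death < params.p_death_given_severe,
        u_death < params.p_death_given_not_severe,
    )
    readmission = rng.random(n) < params.p_readmission
    r, p = _nbinom_params_for_median(params.los_median, params.los_dispersion)
    los = rng.negative_binomial(r, p, size=n)
    out = {
        "hospital_id": np.repeat(hospital_id, n),
        "year": np.repeat(year, n),
        "procedure": np.repeat(procedure.value, n),
        "tumour_type": np.repeat(pd.NA, n).astype(object),
        "cd_grade_3a_plus": severe,
        "death": death,
        "readmission": readmission,
        "los_days": los.astype(np.int64),
        "margin_adequate": np.repeat(pd.NA, n).astype(object),
        "popf_bc": np.repeat(pd.NA, n).astype(object),
        "reoperation": np.repeat(pd.NA, n).astype(object),
    }
    if procedure.is_liver:
        out["tumour_type"] = rng.choice(_LIVER_TUMOURS, size=n, p=_LIVER_TUMOUR_W).astype(object)
        out["margin_adequate"] = (rng.random(n) < params.p_margin_adequate).astype(object)
    else:
        out["popf_bc"] = (rng.random(n) < params.p_popf_bc).astype(object)
        out["reoperation"] = (rng.random(n) < params.p_reoperation).astype(object)
    return pd.DataFrame(out, columns=REGISTRY_COLUMNS)


def simulate_registry(config: SimConfig) -> pd.DataFrame:
    """Generate the registry described by ``config``.

    Returns a frame in the canonical column order with one row per
    resection; record count equals the sum of configured volumes over
    hospitals, procedures and years.  Deterministic under a fixed seed,
    record-wise.
    """
    config.validate()
    procs = list(Procedure)
    blocks = []
    for hosp in config.hospitals:
        for pi, procedure in enumerate(procs):
            if procedure not in hosp.procedures:
                continue
            params = hosp.procedures[procedure]
            for year in range(config.years[0], config.years[1] + 1):
                rng = _substream(config.seed, hosp.hospital_id, pi, year)
                blocks.append(_simulate_block(hosp.hospital_id, procedure, year, params, rng))
    if not blocks:
        return pd.DataFrame(columns=REGISTRY_COLUMNS)
    return pd.concat(blocks, ignore_index=True)


def expected_rates(params: ProcedureParams, procedure: Procedure) -> dict[Indicator, float]:
    """Analytic indicator rates implied by generative parameters.

    The composite rate uses the *nominal* length-of-stay pass probability
    (0.90 for liver, 0.75 for pancreas); in a simulated registry the
    realised pass fraction can exceed the nominal level because stays are
    integer-valued and tie heavily at the percentile threshold.
    """
    p_sev = params.p_severe
    mortality = p_sev * params.p_death_given_severe + (1 - p_sev) * params.p_death_given_not_severe
    los_pass = LOS_PERCENTILE[procedure]
    no_event = (1 - p_sev) * (1 - params.p_death_given_not_severe) * (1 - params.p_readmission)
    if procedure.is_liver:
        composite = no_event * los_pass * params.p_margin_adequate
    else:
        composite = no_event * los_pass * (1 - params.p_popf_bc) * (1 - params.p_reoperation)
    return {
        Indicator.MORTALITY: mortality,
        Indicator.MAJOR_MORBIDITY: p_sev,
        Indicator.FTR: params.p_death_given_severe,
        Indicator.COMPOSITE: composite,
    }


def scenario_with_outlier(
    base: SimConfig,
    procedure: Procedure,
    indicator: Indicator,
    delta: float,
    hospital_id: str | None = None,
) -> SimConfig:
    """Copy of ``base`` with one hospital's generative rate shifted by ``delta``.

    Adverse indicators are shifted *up*: mortality by raising both
    conditional death probabilities by ``delta`` (so the marginal rises by
    exactly ``delta``), major morbidity by raising ``p_severe``, FTR by
    raising ``p_death_given_severe``.  The composite outcome is shifted
    *down* by inflating the readmission probability until the analytic
    composite rate drops by ``delta``.  All other hospitals are untouched;
    ``delta = 0`` returns an identical configuration.
    """
    procedure = Procedure(procedure)
    indicator = Indicator(indicator)
    out = copy.deepcopy(base)
    candidates = [h for h in out.hospitals if procedure in h.procedures]
    if not candidates:
        raise ConfigError(f"no hospital performs {procedure.value}")
    if hospital_id is None:
        target = min(candidates, key=lambda h: h.hospital_id)
    else:
        match = [h for h in candidates if h.hospital_id == hospital_id]
        if not match:
            raise ConfigError(f"hospital {hospital_id!r} does not perform {procedure.value}")
        target = match[0]
    params = target.procedures[procedure]

    def bump(name: str) -> None:
        new = getattr(params, name) + delta
        if not 0.0 <= new <= 1.0:
            raise ConfigError(f"{name} + delta = {new} leaves [0, 1]")
        setattr(params, name, new)

    if indicator is Indicator.MORTALITY:
        bump("p_death_given_severe")
        bump("p_death_given_not_severe")
    elif indicator is Indicator.MAJOR_MORBIDITY:
        bump("p_severe")
    elif indicator is Indicator.FTR:
        bump("p_death_given_severe")
    else:  # composite: deflate via readmission inflation
        base_rate = expected_rates(params, procedure)[Indicator.COMPOSITE]
        if not 0.0 <= delta <= base_rate:
            raise ConfigError(
                f"composite delta {delta} exceeds the analytic composite rate {base_rate:.4f}"
            )
        q = delta / base_rate
        params.p_readmission = params.p_readmission + q * (1 - params.p_readmission)
    if delta != 0.0:
        out.label = f"{base.label}+outlier({target.hospital_id},{procedure.value},{indicator.value},{delta})"
    return out


# ---------------------------------------------------------------------------
# Study-shaped default scenario
# ---------------------------------------------------------------------------

def _volume_ladder(n_hosp: int, vmin: int, vmed: int, vmax: int) -> list[int]:
    """Deterministic annual volumes with the exact min, median and max.

    Two geometric segments (min -> median -> max), i.e. a discretized
    log-normal-like spread through the published per-hospital statistics.
    """
    mid = n_hosp // 2
    lower = np.geomspace(vmin, vmed, mid + 1)
    upper = np.geomspace(vmed, vmax, n_hosp - mid)
    v = np.round(np.concatenate([lower[:-1], upper])).astype(int)
    v[0], v[mid], v[-1] = vmin, vmed, vmax
    return [int(x) for x in v]


def _national_params(procedure: Procedure, volume: int) -> ProcedureParams:
    # Event probabilities at the published nationwide 2020-2021 benchmarks.
    # Where the printed marginal mortality is smaller than p_severe * FTR
    # (arithmetically impossible, since deaths after severe complications
    # are a subset of all deaths), p_death_given_not_severe clips at 0 and
    # the implied marginal is p_severe * FTR.
    if procedure is Procedure.MINOR_LR:
        return ProcedureParams(
            volume=volume, p_severe=0.098, p_death_given_severe=0.054,
            p_death_given_not_severe=(0.006 - 0.098 * 0.054) / (1 - 0.098),
            p_readmission=0.08, p_margin_adequate=0.96,
            los_median=5, los_dispersion=4.0,
        )
    if procedure is Procedure.MAJOR_LR:
        return ProcedureParams(
            volume=volume, p_severe=0.281, p_death_given_severe=0.142,
            p_death_given_not_severe=0.0,
            p_readmission=0.10, p_margin_adequate=0.95,
            los_median=7, los_dispersion=4.0,
        )
    if procedure is Procedure.PD:
        return ProcedureParams(
            volume=volume, p_severe=0.360, p_death_given_severe=0.075,
            p_death_given_not_severe=0.0,
            p_readmission=0.12, p_popf_bc=0.12, p_reoperation=0.05,
            los_median=10, los_dispersion=4.0,
        )
    return ProcedureParams(
        volume=volume, p_severe=0.223, p_death_given_severe=0.031,
        p_death_given_not_severe=0.0,
        p_readmission=0.10, p_popf_bc=0.18, p_reoperation=0.04,
        los_median=6, los_dispersion=4.0,
    )


def study_config(seed: int = 0, years: tuple[int, int] = (2020, 2021)) -> SimConfig:
    """Registry scenario shaped like the Dutch national HPB audits.

    24 hospitals: 12 performing both liver and pancreatic surgery, 9 liver
    only, 3 pancreas only (21 liver and 15 pancreas centres).  Annual
    volumes span the published per-hospital ranges with the published
    medians (minor LR 44 (9-84), major LR 9 (1-54), PD 39 (22-144),
    DP 13 (5-30)); event probabilities sit at the national benchmarks, so
    every hospital is null (no true outlier).
    """
    minor = _volume_ladder(21, 9, 44, 84)
    major = _volume_ladder(21, 1, 9, 54)
    pd_v = _volume_ladder(15, 22, 39, 144)
    dp_v = _volume_ladder(15, 5, 13, 30)
    hospitals: list[HospitalProfile] = []
    liver_i = pancreas_i = 0
    for i in range(24):
        hid = f"H{i + 1:02d}"
        does_liver = i < 21  # H01-H12 both, H13-H21 liver only, H22-H24 pancreas only
        does_pancreas = i < 12 or i >= 21
        procedures: dict[Procedure, ProcedureParams] = {}
        if does_liver:
            procedures[Procedure.MINOR_LR] = _national_params(Procedure.MINOR_LR, minor[liver_i])
            procedures[Procedure.MAJOR_LR] = _national_params(Procedure.MAJOR_LR, major[liver_i])
            liver_i += 1
        if does_pancreas:
            procedures[Procedure.PD] = _national_params(Procedure.PD, pd_v[pancreas_i])
            procedures[Procedure.DP] = _national_params(Procedure.DP, dp_v[pancreas_i])
            pancreas_i += 1
        hospitals.append(HospitalProfile(hospital_id=hid, procedures=procedures))
    return SimConfig(hospitals=hospitals, years=years, seed=seed, label="study-null")
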