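import pandas as pd
import pytest

from hpbbench import (
    HospitalProfile,
    Procedure,
    ProcedureParams,
    SimConfig,
    simulate_registry,
)


def liver_params(volume=100, **overrides):
    base = dict(
        volume=volume,
        p_severe=0.098,
        p_death_given_severe=0.054,
        p_death_given_not_severe=0.0008,
        p_readmission=0.08,
        p_margin_adequate=0.96,
        los_median=5,
        los_dispersion=4.0,
    )
    base.update(overrides)
    return ProcedureParams(**base)


def pancreas_params(volume=100, **overrides):
    base = dict(
        volume=volume,
        p_severe=0.36,
        p_death_given_severe=0.075,
        p_death_given_not_severe=0.0,
        p_readmission=0.12,
        p_popf_bc=0.12,
        p_reoperation=0.05,
        los_median=10,
        los_dispersion=4.0,
    )
    base.update(overrides)
    return ProcedureParams(**base)


@pytest.fixture(scope="session")
def small_config():
    """Three hospitals, both families, two years; quick to simulate."""
    hospitals = [
        HospitalProfile(
            f"H{i}",
            {
                Procedure.MINOR_LR: liver_params(60),
                Procedure.MAJOR_LR: liver_params(15, p_severe=0.281, p_death_given_severe=0.142,
                                                 p_death_given_not_severe=0.0, los_median=7),
                Procedure.PD: pancreas_params(40),
                Procedure.DP: pancreas_params(15, p_severe=0.223, p_death_given_severe=0.031,
                                              p_popf_bc=0.18, p_reoperation=0.04, los_median=6),
            },
        )
        for i in range(3)
    ]
    return SimConfig(hospitals=hospitals, years=(2020, 2021), seed=7, label="small")


@pytest.fixture(scope="session")
def small_registry(small_config):
    return simulate_registry(small_config)


@pytest.fixture()
def toy_pd_cohort():
    """Six hand-enumerable pancreatoduodenectomy records.

    One record is fully favourable; each of the other five fails exactly
    one ideal-outcome component, so the IO rate is exactly 1/6 at an LOS
    threshold of 10 days.
    """
    rows = [
        # death, severe, popf, reop, los, readm
        dict(death=False, cd_grade_3a_plus=False, popf_bc=False, reoperation=False, los_days=8, readmission=False),
        dict(death=True, cd_grade_3a_plus=False, popf_bc=False, reoperation=False, los_days=8, readmission=False),
        dict(death=False, cd_grade_3a_plus=True, popf_bc=False, reoperation=False, los_days=8, readmission=False),
        dict(death=False, cd_grade_3a_plus=False, popf_bc=True, reoperation=False, los_days=8, readmission=False),
        dict(death=False, cd_grade_3a_plus=False, popf_bc=False, reoperation=True, los_days=8, readmission=False),
        dict(death=False, cd_grade_3a_plus=False, popf_bc=False, reoperation=False, los_days=11, readmission=False),
    ]
    df = pd.DataFrame(rows)
    df["hospital_id"] = "H1"
    df["year"] = 2021
    df["procedure"] = Procedure.PD.value
    df["tumour_type"] = pd.NA
    df["margin_adequate"] = pd.NA
    return df
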