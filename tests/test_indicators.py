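"""Indicator engine: flags, conditional FTR, benchmarks, LOS percentiles."""

import math

import numpy as np
import pandas as pd
import pytest

from hpbbench import (
    Indicator,
    LOSThresholds,
    Procedure,
    WrongProcedureError,
    benchmark,
    benchmark_table,
    ftr_summary,
    ideal_outcome_flag,
    los_thresholds,
    major_morbidity_flag,
    mortality_flag,
    summarize,
    textbook_outcome_flag,
)
from hpbbench.indicators import NATIONAL, indicator_flags
from hpbbench.registry import PatientRecord


def liver_record(**overrides):
    base = dict(
        hospital_id="H1", year=2021, procedure=Procedure.MINOR_LR,
        cd_grade_3a_plus=False, death=False, readmission=False, los_days=4,
        margin_adequate=True, tumour_type="CRLM",
    )
    base.update(overrides)
    return PatientRecord(**base)


def pancreas_record(**overrides):
    base = dict(
        hospital_id="H1", year=2021, procedure=Procedure.PD,
        cd_grade_3a_plus=False, death=False, readmission=False, los_days=8,
        popf_bc=False, reoperation=False,
    )
    base.update(overrides)
    return PatientRecord(**base)


LIVER_T = LOSThresholds({Procedure.MINOR_LR: 10, Procedure.MAJOR_LR: 12})
PANC_T = LOSThresholds({Procedure.PD: 10, Procedure.DP: 8})


class TestSimpleFlags:
    def test_mortality_is_the_death_component(self):
        assert mortality_flag(liver_record(death=True))
        assert not mortality_flag(liver_record(death=False))

    def test_death_alone_is_not_major_morbidity(self):
        assert not major_morbidity_flag(liver_record(death=True, cd_grade_3a_plus=False))
        assert major_morbidity_flag(liver_record(cd_grade_3a_plus=True))


class TestTextbookOutcome:
    def test_all_components_favourable(self):
        assert textbook_outcome_flag(liver_record(), LIVER_T)

    @pytest.mark.parametrize(
        "spoiler",
        [dict(cd_grade_3a_plus=True), dict(death=True), dict(readmission=True),
         dict(los_days=11), dict(margin_adequate=False)],
    )
    def test_any_single_failure_breaks_it(self, spoiler):
        assert not textbook_outcome_flag(liver_record(**spoiler), LIVER_T)

    def test_los_threshold_is_inclusive(self):
        assert textbook_outcome_flag(liver_record(los_days=10), LIVER_T)

    def test_pancreas_record_rejected(self):
        with pytest.raises(WrongProcedureError):
            textbook_outcome_flag(pancreas_record(), PANC_T)


class TestIdealOutcome:
    def test_all_components_favourable(self):
        assert ideal_outcome_flag(pancreas_record(), PANC_T)

    @pytest.mark.parametrize(
        "spoiler",
        [dict(death=True), dict(cd_grade_3a_plus=True), dict(popf_bc=True),
         dict(reoperation=True), dict(los_days=11), dict(readmission=True)],
    )
    def test_any_single_failure_breaks_it(self, spoiler):
        assert not ideal_outcome_flag(pancreas_record(**spoiler), PANC_T)

    def test_liver_record_rejected(self):
        with pytest.raises(WrongProcedureError):
            ideal_outcome_flag(liver_record(), LIVER_T)

    def test_toy_cohort_rate_matches_enumeration(self, toy_pd_cohort):
        thresholds = LOSThresholds({Procedure.PD: 10})
        records = [
            PatientRecord(
                hospital_id=r.hospital_id, year=r.year, procedure=Procedure(r.procedure),
                cd_grade_3a_plus=r.cd_grade_3a_plus, death=r.death,
                readmission=r.readmission, los_days=r.los_days,
                popf_bc=r.popf_bc, reoperation=r.reoperation,
            )
            for r in toy_pd_cohort.itertuples(index=False)
        ]
        flags = [ideal_outcome_flag(r, thresholds) for r in records]
        assert sum(flags) == 1 and len(flags) == 6
        eligible, event = indicator_flags(toy_pd_cohort, Indicator.COMPOSITE, Procedure.PD, thresholds)
        assert list(event) == flags  # vectorized path agrees record-wise
        assert event.sum() / eligible.sum() == pytest.approx(1 / 6)


class TestFTR:
    def test_conditional_rate(self, toy_pd_cohort):
        df = toy_pd_cohort.copy()
        # 2 severe cases, 1 of whom died
        df.loc[1, "cd_grade_3a_plus"] = True  # the death row becomes severe too
        s = ftr_summary(df, Procedure.PD)
        assert (s.numerator, s.denominator) == (1, 2)
        assert s.rate == pytest.approx(0.5)

    def test_no_severe_cases_flags_undefined(self, toy_pd_cohort):
        df = toy_pd_cohort.copy()
        df["cd_grade_3a_plus"] = False
        s = ftr_summary(df, Procedure.PD)
        assert s.undefined and math.isnan(s.rate)

    def test_empty_input_flags_empty_not_raises(self):
        df = pd.DataFrame(columns=toy_columns())
        s = ftr_summary(df, Procedure.PD)
        assert s.undefined


def toy_columns():
    from hpbbench.registry import REGISTRY_COLUMNS

    return REGISTRY_COLUMNS


class TestBenchmark:
    def test_single_hospital_collapses_to_its_rate(self, toy_pd_cohort):
        entry = benchmark(toy_pd_cohort, (2021, 2021), Indicator.MORTALITY, Procedure.PD)
        assert entry.p0 == entry.rate_min == entry.rate_max == pytest.approx(1 / 6)

    def test_pooling_is_patient_weighted(self):
        rows = []
        for hid, n, deaths in [("A", 50, 0), ("B", 50, 5)]:
            for i in range(n):
                rows.append(
                    dict(hospital_id=hid, year=2021, procedure="PD", tumour_type=pd.NA,
                         cd_grade_3a_plus=False, death=i < deaths, readmission=False,
                         los_days=5, margin_adequate=pd.NA, popf_bc=False, reoperation=False)
                )
        df = pd.DataFrame(rows)
        entry = benchmark(df, (2021, 2021), Indicator.MORTALITY, Procedure.PD)
        assert entry.p0 == pytest.approx(0.05)
        assert entry.rate_min == 0.0 and entry.rate_max == pytest.approx(0.10)

    def test_empty_stratum_is_flagged_not_raised(self, toy_pd_cohort):
        entry = benchmark(toy_pd_cohort, (2021, 2021), Indicator.MORTALITY, Procedure.DP)
        assert entry.empty and math.isnan(entry.p0)


class TestCohortInvariants:
    def test_composite_dominated_by_every_component(self, small_registry):
        window = (2020, 2021)
        thresholds = los_thresholds(small_registry, window)
        for procedure in Procedure:
            sub = small_registry[small_registry.procedure == procedure.value]
            eligible, event = indicator_flags(small_registry, Indicator.COMPOSITE, procedure, thresholds)
            comp_rate = event.sum() / eligible.sum()
            passes = {
                "no_severe": (~sub.cd_grade_3a_plus.astype(bool)).mean(),
                "no_death": (~sub.death.astype(bool)).mean(),
                "no_readmission": (~sub.readmission.astype(bool)).mean(),
                "los": (sub.los_days <= thresholds[procedure]).mean(),
            }
            if procedure.is_liver:
                passes["margin"] = sub.margin_adequate.astype(bool).mean()
            else:
                passes["no_popf"] = (~sub.popf_bc.astype(bool)).mean()
                passes["no_reop"] = (~sub.reoperation.astype(bool)).mean()
            for name, rate in passes.items():
                assert comp_rate <= rate + 1e-12, name

    def test_ftr_denominator_equals_morbidity_numerator(self, small_registry):
        window = (2020, 2021)
        for procedure in Procedure:
            morb = summarize(small_registry, window, Indicator.MAJOR_MORBIDITY, procedure)
            ftr = summarize(small_registry, window, Indicator.FTR, procedure)
            morb_by_h = {s.hospital_id: s for s in morb}
            for s in ftr:
                assert s.denominator == morb_by_h[s.hospital_id].numerator
                # deaths after severe complications are a subset of all deaths
                mort = summarize(small_registry, window, Indicator.MORTALITY, procedure)
                mort_by_h = {m.hospital_id: m for m in mort}
                assert s.numerator <= mort_by_h[s.hospital_id].numerator

    def test_national_row_sums_hospital_rows(self, small_registry):
        for indicator in (Indicator.MORTALITY, Indicator.FTR, Indicator.COMPOSITE):
            for procedure in (Procedure.MINOR_LR, Procedure.PD):
                rows = summarize(small_registry, (2020, 2021), indicator, procedure)
                national = [s for s in rows if s.hospital_id == NATIONAL][0]
                hospitals = [s for s in rows if s.hospital_id != NATIONAL]
                assert national.numerator == sum(s.numerator for s in hospitals)
                assert national.denominator == sum(s.denominator for s in hospitals)

    def test_nearest_rank_percentile_boundary(self, small_registry):
        thresholds = los_thresholds(small_registry, (2020, 2021))
        from hpbbench.definitions import LOS_PERCENTILE

        for procedure in Procedure:
            sub = small_registry[small_registry.procedure == procedure.value]
            q = LOS_PERCENTILE[procedure]
            frac = (sub.los_days <= thresholds[procedure]).mean()
            assert frac >= q


class TestMissingComponentExclusion:
    def test_incomplete_records_leave_composite_denominator(self, toy_pd_cohort):
        df = toy_pd_cohort.copy()
        df["popf_bc"] = df["popf_bc"].astype(object)
        df.loc[0, "popf_bc"] = pd.NA
        thresholds = LOSThresholds({Procedure.PD: 10})
        eligible, event = indicator_flags(df, Indicator.COMPOSITE, Procedure.PD, thresholds)
        assert eligible.sum() == 5  # the incomplete row is excluded
        # but it still counts for non-composite indicators
        elig_mort, _ = indicator_flags(df, Indicator.MORTALITY, Procedure.PD)
        assert elig_mort.sum() == 6


class TestBenchmarkTable:
    def test_covers_all_strata_and_flags_missing_groups(self, small_registry):
        liver_only = small_registry[small_registry.procedure.isin(["MINOR_LR", "MAJOR_LR"])]
        table = benchmark_table(liver_only, (2020, 2021))
        assert len(table) == 16
        pancreas = table[table.procedure.isin(["PD", "DP"])]
        assert pancreas["empty"].all()
        liver = table[table.procedure.isin(["MINOR_LR", "MAJOR_LR"])]
        assert not liver["empty"].any()
        assert liver["p0"].between(0, 1).all()
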