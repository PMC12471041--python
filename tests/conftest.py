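"""Shared fixtures: hand-built and generated cohorts.

The Table-3-style fixtures mirror the composition of the source cohorts
(20 individuals per replicate) so that survivorship, female fraction and
offspring totals close exactly under the printed identities.
"""

import pytest

from twosexlt.cohort import CohortTable, IndividualRecord


def make_control_cohort() -> CohortTable:
    """Control composition: 9 females, 10 males, 1 larval death (n = 20).

    Female totals sum to 1874 eggs, so F = 1874/9 = 208.22 eggs per female
    and R0 = 1874/20 = 93.7 offspring per newborn.
    """
    records = []
    # 7 females laying 208 eggs, 2 laying 209 (total 1874)
    for i in range(9):
        total = 209 if i < 2 else 208
        # lay over 6 days starting adult day 3 (APOP = 2)
        per, extra = divmod(total, 6)
        fec = {3 + d: per + (1 if d < extra else 0) for d in range(6)}
        records.append(
            IndividualRecord(
                id=f"F{i}", treatment="0", egg_d=3, larva_d=7, pupa_d=6,
                sex="female", death_stage="adult", adult_longevity_d=14,
                fecundity=fec,
            )
        )
    for i in range(10):
        records.append(
            IndividualRecord(
                id=f"M{i}", treatment="0", egg_d=3, larva_d=8, pupa_d=5,
                sex="male", death_stage="adult", adult_longevity_d=13,
            )
        )
    records.append(
        IndividualRecord(id="D0", treatment="0", egg_d=3, larva_d=4,
                         pupa_d=None, sex="undetermined", death_stage="larva")
    )
    return CohortTable(tuple(records))


def make_mid_dose_cohort() -> CohortTable:
    """30 mg/L composition: 4 females, 6 males, 10 preadult deaths (n = 20).

    Female totals sum to 287 eggs: F = 71.75, R0 = 287/20 = 14.35.
    """
    records = []
    for i in range(4):
        total = 72 if i < 3 else 71  # 287
        per, extra = divmod(total, 5)
        fec = {4 + d: per + (1 if d < extra else 0) for d in range(5)}
        records.append(
            IndividualRecord(
                id=f"F{i}", treatment="30", egg_d=4, larva_d=11, pupa_d=7,
                sex="female", death_stage="adult", adult_longevity_d=13,
                fecundity=fec,
            )
        )
    for i in range(6):
        records.append(
            IndividualRecord(
                id=f"M{i}", treatment="30", egg_d=4, larva_d=11, pupa_d=8,
                sex="male", death_stage="adult", adult_longevity_d=12,
            )
        )
    for i in range(10):
        records.append(
            IndividualRecord(id=f"D{i}", treatment="30", egg_d=4,
                             larva_d=3 + i % 5, pupa_d=None,
                             sex="undetermined", death_stage="larva")
        )
    return CohortTable(tuple(records))


def make_high_dose_cohort() -> CohortTable:
    """300 mg/L composition: 3 females, 5 males, 12 deaths (n = 20).

    Female totals sum to 142 eggs: F = 47.33, R0 = 142/20 = 7.1.
    """
    records = []
    for i in range(3):
        total = 48 if i < 1 else 47  # 142
        per, extra = divmod(total, 5)
        fec = {4 + d: per + (1 if d < extra else 0) for d in range(5)}
        records.append(
            IndividualRecord(
                id=f"F{i}", treatment="300", egg_d=4, larva_d=12, pupa_d=7,
                sex="female", death_stage="adult", adult_longevity_d=10,
                fecundity=fec,
            )
        )
    for i in range(5):
        records.append(
            IndividualRecord(
                id=f"M{i}", treatment="300", egg_d=4, larva_d=12, pupa_d=6,
                sex="male", death_stage="adult", adult_longevity_d=9,
            )
        )
    for i in range(12):
        records.append(
            IndividualRecord(id=f"D{i}", treatment="300", egg_d=4,
                             larva_d=2 + i % 7, pupa_d=None,
                             sex="undetermined", death_stage="larva")
        )
    return CohortTable(tuple(records))


@pytest.fixture
def control_cohort() -> CohortTable:
    return make_control_cohort()


@pytest.fixture
def mid_dose_cohort() -> CohortTable:
    return make_mid_dose_cohort()


@pytest.fixture
def high_dose_cohort() -> CohortTable:
    return make_high_dose_cohort()


@pytest.fixture
def two_individual_cohort() -> CohortTable:
    """One egg death after 1 day; one surviving egg 2 d then larval death at 3 d."""
    return CohortTable(
        (
            IndividualRecord(id="a", treatment="t", egg_d=1, larva_d=None,
                             pupa_d=None, sex="undetermined", death_stage="egg"),
            IndividualRecord(id="b", treatment="t", egg_d=2, larva_d=3,
                             pupa_d=None, sex="undetermined", death_stage="larva"),
        )
    )
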