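"""Individual life-history records and cohort tables.

A cohort is a group of insects followed from the egg stage (age 0 = day the
egg was laid) through daily census until death.  Each individual carries the
number of whole days it spent in each developmental stage it reached
(egg -> larva -> pupa -> adult), its sex (determined only at adult
emergence), the stage in which it died, and — for females — a daily egg
count indexed by adult day.

Stage-occupancy convention (half-open days): an individual with ``egg_d = 3``
is in the egg stage on ages 0, 1, 2 and enters the larval stage on age 3.
For the stage in which an individual died, the stored duration is the number
of days it actually survived in that stage.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

__all__ = [
    "STAGES",
    "PREADULT_STAGES",
    "CohortError",
    "IndividualRecord",
    "CohortTable",
    "read_cohort",
    "write_cohort",
    "lifespan",
]

#: Stage labels of the age-stage matrix, in developmental order.  Adults are
#: split by sex, so the two-sex life table has beta = 5 stages.
STAGES: tuple[str, ...] = ("egg", "larva", "pupa", "female", "male")
PREADULT_STAGES: tuple[str, ...] = ("egg", "larva", "pupa")
_SEXES = ("female", "male", "undetermined")
_DEATH_STAGES = ("egg", "larva", "pupa", "adult")

COHORT_COLUMNS = [
    "id",
    "treatment",
    "egg_d",
    "larva_d",
    "pupa_d",
    "sex",
    "death_stage",
    "adult_longevity_d",
]
FECUNDITY_COLUMNS = ["id", "adult_day", "eggs"]


class CohortError(ValueError):
    """Raised for malformed life-history data."""


@dataclass(frozen=True)
class IndividualRecord:
    """Complete life history of one insect under daily census.

    Parameters
    ----------
    id : str
        Unique identifier within a cohort.
    treatment : str
        Treatment label, e.g. an MSN dose in mg/L ("0", "3", "30", "300").
    egg_d, larva_d, pupa_d : int or None
        Whole days spent in each preadult stage.  ``None`` marks a stage the
        individual never reached (it died earlier); for the fatal stage the
        value is the number of days survived in it.
    sex : str
        "female", "male", or "undetermined" (preadult deaths only).
    death_stage : str
        Stage in which the individual died: egg, larva, pupa or adult.
    adult_longevity_d : int
        Days lived as an adult; 0 if the individual never emerged.
    fecundity : mapping of int to int
        Eggs laid per adult day, keyed by adult-day index starting at 1 on
        the day of emergence.  Empty for males and non-emergers.
    """

    id: str
    treatment: str
    egg_d: int | None
    larva_d: int | None
    pupa_d: int | None
    sex: str
    death_stage: str
    adult_longevity_d: int = 0
    fecundity: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise CohortError(f"unknown sex {self.sex!r} for id {self.id!r}")
        if self.death_stage not in _DEATH_STAGES:
            raise CohortError(
                f"unknown death_stage {self.death_stage!r} for id {self.id!r}"
            )
        preadult_death = self.death_stage in PREADULT_STAGES
        if preadult_death != (self.sex == "undetermined"):
            raise CohortError(
                f"id {self.id!r}: sex must be undetermined for preadult deaths "
                "and determined for adults"
            )
        # durations must exist for every stage reached, be absent afterwards
        reached = _DEATH_STAGES.index(self.death_stage)
        for k, dur in enumerate((self.egg_d, self.larva_d, self.pupa_d)):
            name = PREADULT_STAGES[k]
            if k <= reached:
                if dur is None:
                    raise CohortError(
                        f"id {self.id!r}: missing {name} duration for a stage "
                        "the individual reached"
                    )
                if not isinstance(dur, int) or dur < 1:
                    raise CohortError(
                        f"id {self.id!r}: {name} duration must be a whole "
                        f"number of days >= 1, got {dur!r}"
                    )
            elif dur is not None:
                raise CohortError(
                    f"id {self.id!r}: {name} duration given although the "
                    f"individual died in the {self.death_stage} stage"
                )
        if self.death_stage == "adult":
            if not isinstance(self.adult_longevity_d, int) or self.adult_longevity_d < 1:
                raise CohortError(
                    f"id {self.id!r}: emerged adults need adult_longevity_d >= 1"
                )
        elif self.adult_longevity_d != 0:
            raise CohortError(
                f"id {self.id!r}: adult_longevity_d must be 0 for non-emergers"
            )
        if self.fecundity:
            if self.sex != "female" or self.death_stage != "adult":
                raise CohortError(
                    f"id {self.id!r}: fecundity recorded for a male or "
                    "non-emerged individual"
                )
            for day, eggs in self.fecundity.items():
                if not isinstance(day, int) or not 1 <= day <= self.adult_longevity_d:
                    raise CohortError(
                        f"id {self.id!r}: fecundity day {day!r} outside "
                        f"[1, {self.adult_longevity_d}]"
                    )
                if not isinstance(eggs, int) or eggs < 0:
                    raise CohortError(
                        f"id {self.id!r}: egg count must be a non-negative "
                        f"integer, got {eggs!r}"
                    )

    # -- derived quantities -------------------------------------------------

    @property
    def preadult_duration(self) -> int:
        """Days from age 0 to adult emergence (sum of completed preadult stages)."""
        return sum(d for d in (self.egg_d, self.larva_d, self.pupa_d) if d is not None)

    @property
    def total_eggs(self) -> int:
        return sum(self.fecundity.values())

    def stage_intervals(self) -> list[tuple[str, int, int]]:
        """Half-open age intervals ``(stage, start, stop)`` occupied in life."""
        out: list[tuple[str, int, int]] = []
        age = 0
        for name, dur in zip(PREADULT_STAGES, (self.egg_d, self.larva_d, self.pupa_d)):
            if dur is None:
                break
            out.append((name, age, age + dur))
            age += dur
        if self.death_stage == "adult":
            out.append((self.sex, age, age + self.adult_longevity_d))
        return out

    def eggs_by_age(self) -> dict[int, int]:
        """Eggs laid keyed by the mother's age-day of laying."""
        emergence = self.preadult_duration
        return {emergence + day - 1: n for day, n in self.fecundity.items() if n > 0}


def lifespan(rec: IndividualRecord) -> int:
    """Total days alive: completed stage durations plus adult longevity."""
    return rec.preadult_duration + rec.adult_longevity_d


@dataclass(frozen=True)
class CohortTable:
    """A cohort of individuals reared under one treatment, censused daily."""

    records: tuple[IndividualRecord, ...]
    census_interval: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if not self.records:
            raise CohortError("cohort must contain at least one individual")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortError(f"duplicate ids in cohort: {dup}")
        treatments = {r.treatment for r in self.records}
        if len(treatments) > 1:
            raise CohortError(
                f"cohort mixes treatment labels {sorted(treatments)}; analyse "
                "one treatment group at a time"
            )
        if self.census_interval != 1:
            raise CohortError("only daily census (interval 1) is supported")

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def treatment(self) -> str:
        return self.records[0].treatment

    def __iter__(self) -> Iterator[IndividualRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return self.n

    def max_age(self) -> int:
        """Largest age-day index anyone was alive on, plus one (schedule length)."""
        return max(lifespan(r) for r in self.records)

    def subset(self, indices: Sequence[int]) -> "CohortTable":
        """Resampled cohort; ids are suffixed to stay unique."""
        recs = []
        for k, i in enumerate(indices):
            base = self.records[i]
            recs.append(
                IndividualRecord(
                    id=f"{base.id}#{k}",
                    treatment=base.treatment,
                    egg_d=base.egg_d,
                    larva_d=base.larva_d,
                    pupa_d=base.pupa_d,
                    sex=base.sex,
                    death_stage=base.death_stage,
                    adult_longevity_d=base.adult_longevity_d,
                    fecundity=dict(base.fecundity),
                )
            )
        return CohortTable(tuple(recs))


# -- CSV input/output -------------------------------------------------------
#
# Missing values are empty fields; explicit "NA"/"NaN" tokens are rejected to
# keep the dialect unambiguous across writers.

_NA_TOKENS = {"NA", "N/A", "NaN", "nan", "null", "None"}


def _parse_int(value: str, column: str, row_id: str) -> int | None:
    value = value.strip()
    if value == "":
        return None
    if value in _NA_TOKENS:
        raise CohortError(
            f"id {row_id!r}: explicit missing-value token {value!r} in "
            f"column {column!r}; use an empty field"
        )
    try:
        return int(value)
    except ValueError as exc:
        raise CohortError(
            f"id {row_id!r}: column {column!r} must be an integer, got {value!r}"
        ) from exc


def read_cohort(path: str | Path, fecundity_path: str | Path) -> CohortTable:
    """Read a cohort CSV plus its long-format fecundity CSV.

    Fecundity rows are joined to cohort rows by id; a fecundity row whose id
    has no cohort row is an error, as is fecundity for a male or a
    non-emerged individual (enforced by :class:`IndividualRecord`).
    """
    fecundity: dict[str, dict[int, int]] = {}
    with open(fecundity_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or list(reader.fieldnames) != FECUNDITY_COLUMNS:
            raise CohortError(
                f"fecundity file must have header {','.join(FECUNDITY_COLUMNS)}"
            )
        for row in reader:
            rid = row["id"]
            day = _parse_int(row["adult_day"], "adult_day", rid)
            eggs = _parse_int(row["eggs"], "eggs", rid)
            if day is None or eggs is None:
                raise CohortError(f"id {rid!r}: incomplete fecundity row")
            per = fecundity.setdefault(rid, {})
            if day in per:
                raise CohortError(f"id {rid!r}: duplicate fecundity day {day}")
            per[day] = eggs

    records: list[IndividualRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or list(reader.fieldnames) != COHORT_COLUMNS:
            raise CohortError(f"cohort file must have header {','.join(COHORT_COLUMNS)}")
        for row in reader:
            rid = row["id"]
            longevity = _parse_int(row["adult_longevity_d"], "adult_longevity_d", rid)
            records.append(
                IndividualRecord(
                    id=rid,
                    treatment=row["treatment"],
                    egg_d=_parse_int(row["egg_d"], "egg_d", rid),
                    larva_d=_parse_int(row["larva_d"], "larva_d", rid),
                    pupa_d=_parse_int(row["pupa_d"], "pupa_d", rid),
                    sex=row["sex"],
                    death_stage=row["death_stage"],
                    adult_longevity_d=0 if longevity is None else longevity,
                    fecundity=fecundity.pop(rid, {}),
                )
            )
    if fecundity:
        raise CohortError(
            f"fecundity rows with no matching cohort id: {sorted(fecundity)}"
        )
    return CohortTable(tuple(records))


def write_cohort(
    cohort: CohortTable, path: str | Path, fecundity_path: str | Path
) -> None:
    """Write the cohort and fecundity CSVs; round-trips via :func:`read_cohort`."""

    def fmt(v: int | None) -> str:
        return "" if v is None else str(v)

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for r in cohort:
            writer.writerow(
                [
                    r.id,
                    r.treatment,
                    fmt(r.egg_d),
                    fmt(r.larva_d),
                    fmt(r.pupa_d),
                    r.sex,
                    r.death_stage,
                    r.adult_longevity_d,
                ]
            )
    with open(fecundity_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(FECUNDITY_COLUMNS)
        for r in cohort:
            for day in sorted(r.fecundity):
                writer.writerow([r.id, day, r.fecundity[day]])
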