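"""Synthetic cohorts and replicate-level endpoint tables.

Emulates the dose-dependent life-history structure of *Tuta absoluta*
cohorts reared on tomato foliage sprayed with mesoporous silica
nanoparticles (MSN) at 0, 3, 30 and 300 mg/L: preadult survivorship falling
from 0.95 to 0.40, larval development stretching from 7.4 to 11.8 days,
per-female fecundity dropping from 208.22 to 47.33 eggs, and the female
fraction of the cohort shrinking from 0.45 to 0.15.

Stage durations are discretised gamma draws (continuous gamma, rounded up,
floor one day; the continuous mean is calibrated on the daily lattice so
the discrete expectation equals the target mean exactly).  Preadult death is Bernoulli per stage with the
death day uniform within the fatal stage.  Egg-stage survival defaults to 1
because bioassays start with newly hatched larvae.  A female's laying
schedule starts after a gamma-distributed adult pre-oviposition period and
spreads her expected total fecundity over a window of consecutive days with
a unimodal triangular daily weight; daily counts are Poisson, so the
expected total equals the fecundity target exactly.

The per-treatment defaults in :func:`default_params` ARE the study
conditions; they are calibration targets, not tuning knobs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable, IndividualRecord

__all__ = [
    "TreatmentParams",
    "EndpointParams",
    "TREATMENTS",
    "default_params",
    "default_endpoint_params",
    "simulate_cohort",
    "simulate_endpoints",
]

TREATMENTS = ("0", "3", "30", "300")


@dataclass(frozen=True)
class TreatmentParams:
    """Generator parameters for one treatment group.

    ``stage_surv`` are per-stage survival probabilities whose product is the
    preadult survivorship target Sa.  ``p_female`` is the female fraction
    among emerged adults; the expected female fraction of the whole cohort
    is therefore ``Sa * p_female``.
    """

    label: str
    n: int = 20
    stage_mean_d: tuple[float, float, float] = (3.4, 7.4, 5.58)  # egg, larva, pupa
    stage_surv: tuple[float, float, float] = (1.0, 1.0, 0.95)
    p_female: float = 0.45 / 0.95
    adult_longevity_mean_d: Mapping[str, float] = field(
        default_factory=lambda: {"female": 13.63, "male": 13.63}
    )
    apop_mean_d: float = 2.11
    total_eggs_mean: float = 208.22
    ovi_days_mean: float = 6.56
    stage_cv: float = 0.15
    longevity_cv: float = 0.20
    apop_cv: float = 0.30
    ovi_days_cv: float = 0.25

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size n must be >= 1")
        if not all(0.0 <= s <= 1.0 for s in self.stage_surv):
            raise ValueError("stage survival probabilities must lie in [0, 1]")
        if not 0.0 <= self.p_female <= 1.0:
            raise ValueError("p_female must lie in [0, 1]")
        if any(m <= 0 for m in self.stage_mean_d) or self.total_eggs_mean <= 0:
            raise ValueError("means must be positive")

    @property
    def preadult_survival(self) -> float:
        """Sa target: probability of reaching adulthood."""
        return float(np.prod(self.stage_surv))

    @property
    def expected_female_fraction(self) -> float:
        """Expected emerged females over the whole cohort (Nf/N target)."""
        return self.preadult_survival * self.p_female


# Calibration targets per treatment (dose in mg/L).  Durations, Sa, female
# fraction, fecundity, APOP and oviposition days follow the bootstrap means
# of the source cohort study; p_female is the cohort female-fraction target
# divided by Sa so both close simultaneously.
_DEFAULTS: dict[str, dict] = {
    "0": dict(
        stage_mean_d=(3.4, 7.4, 5.58),
        sa=0.95,
        female_fraction=0.45,
        longevity=13.63,
        apop=2.11,
        eggs=208.22,
        ovi=6.56,
    ),
    "3": dict(
        stage_mean_d=(3.6, 8.45, 6.4),
        sa=0.75,
        female_fraction=0.35,
        longevity=11.87,
        apop=1.14,
        eggs=97.71,
        ovi=9.14,
    ),
    "30": dict(
        stage_mean_d=(3.75, 10.9, 7.5),
        sa=0.50,
        female_fraction=0.20,
        longevity=13.10,
        apop=3.75,
        eggs=71.75,
        ovi=8.00,
    ),
    "300": dict(
        stage_mean_d=(3.7, 11.8, 6.62),
        sa=0.40,
        female_fraction=0.15,
        longevity=9.50,
        apop=3.00,
        eggs=47.33,
        ovi=5.67,
    ),
}

#: Pupal survival held at this value (except where Sa exceeds it); the
#: remaining mortality is assigned to the larval stage, where leaf-mining
#: exposure to the treated foliage is concentrated.
_PUPAL_SURVIVAL = 0.95


def default_params(treatment: str, n: int = 20) -> TreatmentParams:
    """Calibrated parameter set for one of the four MSN doses (mg/L)."""
    if treatment not in _DEFAULTS:
        raise ValueError(
            f"unknown treatment {treatment!r}; expected one of {TREATMENTS}"
        )
    d = _DEFAULTS[treatment]
    pupa_surv = min(_PUPAL_SURVIVAL, 1.0) if d["sa"] < _PUPAL_SURVIVAL else d["sa"]
    larva_surv = d["sa"] / pupa_surv
    return TreatmentParams(
        label=treatment,
        n=n,
        stage_mean_d=tuple(d["stage_mean_d"]),
        stage_surv=(1.0, larva_surv, pupa_surv),
        p_female=d["female_fraction"] / d["sa"],
        adult_longevity_mean_d={"female": d["longevity"], "male": d["longevity"]},
        apop_mean_d=d["apop"],
        total_eggs_mean=d["eggs"],
        ovi_days_mean=d["ovi"],
    )


@lru_cache(maxsize=None)
def _continuous_mean_for(target: float, cv: float) -> float:
    """Continuous gamma mean whose ceiled-draw expectation equals ``target``.

    Rounding up adds about half a day in expectation, so ``target - 0.5`` is
    the starting guess; a short bisection on the exact lattice expectation
    E[max(1, ceil(X))] removes the residual bias (a few hundredths of a day
    for short stages).
    """
    from scipy import stats as _st

    shape = 1.0 / (cv * cv)
    ks = np.arange(0, max(200, int(target * 10)))

    def discrete_mean(m: float) -> float:
        upper = _st.gamma.cdf(ks + 1, shape, scale=m / shape)
        lower = _st.gamma.cdf(ks, shape, scale=m / shape)
        return float(np.sum(np.maximum(ks + 1, 1) * (upper - lower)))

    lo, hi = max(target - 1.0, 0.05), target + 0.5
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if discrete_mean(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _gamma_days(rng: np.random.Generator, mean: float, cv: float) -> int:
    """Discretised gamma day count: ceil of a continuous gamma, floor 1 day.

    The continuous mean is pre-calibrated so the discrete expectation equals
    ``mean`` exactly.
    """
    m = _continuous_mean_for(mean, cv)
    shape = 1.0 / (cv * cv)
    draw = rng.gamma(shape, m / shape)
    return max(1, math.ceil(draw))


def _nonneg_gamma_days(rng: np.random.Generator, mean: float, cv: float) -> int:
    """Rounded gamma, floor zero (for pre-oviposition periods)."""
    if mean <= 0:
        return 0
    shape = 1.0 / (cv * cv)
    return max(0, round(rng.gamma(shape, mean / shape)))


def _fecundity_schedule(
    rng: np.random.Generator, params: TreatmentParams, longevity: int, apop: int
) -> tuple[dict[int, int], int]:
    """Poisson daily egg counts over a triangular window; returns (schedule, longevity).

    Longevity is extended if needed so the drawn laying window fits; the
    expected total over the window equals ``total_eggs_mean``.
    """
    window = max(1, round(rng.gamma(1.0 / params.ovi_days_cv**2,
                                    params.ovi_days_mean * params.ovi_days_cv**2)))
    first = apop + 1
    longevity = max(longevity, first + window - 1)
    days = np.arange(window, dtype=float)
    peak = (window - 1) / 3.0  # early-peaked unimodal profile
    w = np.where(
        days <= peak,
        (days + 1.0) / (peak + 1.0),
        1.0 - (days - peak) / (window - peak) if window > peak else 1.0,
    )
    w = np.clip(w, 1e-9, None)
    mu = params.total_eggs_mean * w / w.sum()
    counts = rng.poisson(mu)
    sched = {first + k: int(c) for k, c in enumerate(counts) if c > 0}
    return sched, longevity


def simulate_cohort(params: TreatmentParams, seed: int) -> CohortTable:
    """Simulate a cohort of ``params.n`` individuals; identical seed, identical cohort."""
    if seed is None:
        raise ValueError("an explicit seed is mandatory")
    rng = np.random.default_rng(seed)
    records: list[IndividualRecord] = []
    stage_names = ("egg", "larva", "pupa")
    for i in range(params.n):
        rid = f"{params.label}-{i + 1:04d}"
        durations: dict[str, int | None] = {s: None for s in stage_names}
        died_in: str | None = None
        for j, name in enumerate(stage_names):
            full = _gamma_days(rng, params.stage_mean_d[j], params.stage_cv)
            if rng.random() < params.stage_surv[j]:
                durations[name] = full
            else:
                durations[name] = int(rng.integers(1, full + 1))
                died_in = name
                break
        if died_in is not None:
            records.append(
                IndividualRecord(
                    id=rid,
                    treatment=params.label,
                    egg_d=durations["egg"],
                    larva_d=durations["larva"],
                    pupa_d=durations["pupa"],
                    sex="undetermined",
                    death_stage=died_in,
                )
            )
            continue
        sex = "female" if rng.random() < params.p_female else "male"
        longevity = _gamma_days(
            rng, params.adult_longevity_mean_d[sex], params.longevity_cv
        )
        fecundity: dict[int, int] = {}
        if sex == "female":
            apop = _nonneg_gamma_days(rng, params.apop_mean_d, params.apop_cv)
            fecundity, longevity = _fecundity_schedule(rng, params, longevity, apop)
        records.append(
            IndividualRecord(
                id=rid,
                treatment=params.label,
                egg_d=durations["egg"],
                larva_d=durations["larva"],
                pupa_d=durations["pupa"],
                sex=sex,
                death_stage="adult",
                adult_longevity_d=longevity,
                fecundity=fecundity,
            )
        )
    return CohortTable(tuple(records))


# -- replicate-level endpoints ---------------------------------------------


@dataclass(frozen=True)
class EndpointParams:
    """Normal replicate model for one measured endpoint across treatments."""

    name: str
    means: Mapping[str, float]
    sds: Mapping[str, float]
    replicates: int = 3
    hormetic: bool = False  # peak at 30 mg/L, decline at 300 mg/L

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates per treatment")
        if any(s < 0 for s in self.sds.values()):
            raise ValueError("SDs must be non-negative")
        if set(self.means) != set(self.sds):
            raise ValueError("means and sds must cover the same treatments")


# Plant (leaf, 30 days after transplanting) and insect (larval) endpoint
# means by dose.  Values not printed in the source tables (POD and MDA at
# 3 mg/L; most insect enzyme means) are synthetic stand-ins consistent with
# the described dose-response shapes.  SDs are SE*sqrt(3) where an SE was
# printed, otherwise 3% of the mean.
_ENDPOINT_DEFAULTS: dict[str, tuple[dict[str, float], dict[str, float], bool]] = {
    "SOD": (
        {"0": 125.3, "3": 138.6, "30": 165.7, "300": 105.6},
        {"0": 4.85, "3": 5.54, "30": 6.24, "300": 5.02},
        True,
    ),
    "POD": (
        {"0": 103.2, "3": 114.0, "30": 125.4, "300": 84.5},
        {"0": 4.50, "3": 4.80, "30": 5.02, "300": 3.81},
        True,
    ),
    "CAT": (
        {"0": 88.4, "3": 102.3, "30": 116.7, "300": 69.1},
        {"0": 3.46, "3": 4.16, "30": 4.85, "300": 3.29},
        True,
    ),
    "MDA": (
        {"0": 6.73, "3": 6.10, "30": 5.28, "300": 8.64},
        {"0": 0.36, "3": 0.33, "30": 0.31, "300": 0.42},
        False,
    ),
    "protease": (
        {"0": 5.5, "3": 5.2, "30": 4.6, "300": 3.9},
        {"0": 0.17, "3": 0.16, "30": 0.14, "300": 0.12},
        False,
    ),
    "lipase": (
        {"0": 0.44, "3": 0.46, "30": 0.48, "300": 0.40},
        {"0": 0.013, "3": 0.014, "30": 0.014, "300": 0.012},
        True,
    ),
    "amylase": (
        {"0": 0.30, "3": 0.31, "30": 0.29, "300": 0.27},
        {"0": 0.009, "3": 0.009, "30": 0.009, "300": 0.008},
        False,
    ),
    "P450": (
        {"0": 22.0, "3": 26.0, "30": 32.0, "300": 18.0},
        {"0": 0.66, "3": 0.78, "30": 0.96, "300": 0.54},
        True,
    ),
    "GST": (
        {"0": 45.0, "3": 55.0, "30": 63.0, "300": 35.0},
        {"0": 1.35, "3": 1.65, "30": 1.89, "300": 1.05},
        True,
    ),
    "AChE": (
        {"0": 0.52, "3": 0.45, "30": 0.33, "300": 0.18},
        {"0": 0.016, "3": 0.014, "30": 0.010, "300": 0.005},
        False,
    ),
    "CarE": (
        {"0": 20.0, "3": 23.0, "30": 26.0, "300": 15.0},
        {"0": 0.60, "3": 0.69, "30": 0.78, "300": 0.45},
        True,
    ),
}

PLANT_ENDPOINTS = ("SOD", "POD", "CAT", "MDA")
INSECT_ENDPOINTS = ("protease", "lipase", "amylase", "P450", "GST", "AChE", "CarE")


def default_endpoint_params(name: str, replicates: int = 3) -> EndpointParams:
    """Calibrated endpoint model (plant antioxidants/MDA, insect enzymes)."""
    if name not in _ENDPOINT_DEFAULTS:
        raise ValueError(
            f"unknown endpoint {name!r}; known: {sorted(_ENDPOINT_DEFAULTS)}"
        )
    means, sds, hormetic = _ENDPOINT_DEFAULTS[name]
    return EndpointParams(
        name=name, means=dict(means), sds=dict(sds),
        replicates=replicates, hormetic=hormetic,
    )


def simulate_endpoints(
    params: EndpointParams | Sequence[EndpointParams], seed: int
) -> pd.DataFrame:
    """Draw replicate values ~ Normal(mean, SD) truncated at 0, long format.

    Returns a DataFrame with columns ``endpoint, treatment, replicate, value``.
    """
    if seed is None:
        raise ValueError("an explicit seed is mandatory")
    plist = [params] if isinstance(params, EndpointParams) else list(params)
    rng = np.random.default_rng(seed)
    rows = []
    for p in plist:
        for trt in p.means:
            for rep in range(1, p.replicates + 1):
                value = -1.0
                while value < 0:  # truncate at zero by redraw
                    value = rng.normal(p.means[trt], p.sds[trt])
                    if p.sds[trt] == 0:
                        value = max(value, 0.0)
                rows.append(
                    {"endpoint": p.name, "treatment": trt,
                     "replicate": rep, "value": float(value)}
                )
    return pd.DataFrame(rows, columns=["endpoint", "treatment", "replicate", "value"])
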