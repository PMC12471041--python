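"""Age-stage, two-sex life table engine.

Implements the standard age-stage two-sex framework for daily-census insect
cohorts (Chi & Liu's age-stage survival matrix; Chi & Su's hypothetical-
cohort life expectancy and reproductive value):

* ``s_xj`` — probability a newborn is alive and in stage ``j`` at age ``x``
  (proportion of the initial cohort; stages egg, larva, pupa, female adult,
  male adult).
* ``l_x = sum_j s_xj`` — age-specific survival.
* ``m_x = sum_j s_xj f_xj / sum_j s_xj`` — age-specific fecundity, where
  ``f_xj`` is nonzero only for the female-adult stage (eggs per living
  female per day).
* ``R0 = sum_x l_x m_x`` and ``GRR = sum_x m_x``.
* ``r`` solving the discrete Euler-Lotka equation
  ``sum_x exp(-r (x+1)) l_x m_x = 1`` (age indexed from 0, reproduction
  credited at the end of the day); ``lambda = exp(r)``; ``T = ln(R0)/r``.
* ``e_xj`` — expected remaining days for an (age, stage) occupant, from a
  hypothetical cohort started with certainty at ``(x, j)`` and propagated
  with the empirical daily stage-transition/survival frequencies.
* ``v_xj`` — expected discounted future offspring of an (age, stage)
  occupant at discount rate ``r`` (same hypothetical cohort).

The model front-end is :class:`TwoSexLifeTable`; ``fit`` returns a
:class:`LifeTableResults` carrying point estimates, bootstrap standard
errors and percentile intervals, with ``summary()`` in the spirit of
statsmodels results.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Mapping

import numpy as np
import pandas as pd

from .cohort import STAGES, CohortError, CohortTable

if TYPE_CHECKING:  # pragma: no cover
    from .bootstrap import BootstrapResult

__all__ = [
    "AgeStageMatrix",
    "LifeTableCurves",
    "PopulationParameters",
    "StageExpectancy",
    "ReproductiveValueMatrix",
    "ReproductionSummary",
    "compute_sxj",
    "compute_lx",
    "compute_mx",
    "compute_R0_GRR",
    "euler_lotka_r",
    "solve_r",
    "life_expectancy",
    "reproductive_value",
    "summarize_reproduction",
    "TwoSexLifeTable",
    "LifeTableResults",
]

_FEMALE = STAGES.index("female")

#: Provenance note attached to e_xj / v_xj outputs: the hypothetical-cohort
#: construction follows the standard age-stage method (Chi & Su 2006).
EXPECTANCY_METHOD = "hypothetical-cohort (Chi & Su 2006 convention)"


@dataclass(frozen=True)
class AgeStageMatrix:
    """Age-stage survival proportions ``s_xj`` of the initial cohort.

    ``values`` is a DataFrame indexed by age ``x`` (0..x_max-1) with one
    column per stage; ``n`` is the cohort size used as denominator, so every
    entry times ``n`` is an integer head count.
    """

    values: pd.DataFrame
    n: int

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any() or (self.values.to_numpy() > 1).any():
            raise ValueError("s_xj proportions must lie in [0, 1]")
        if (self.values.sum(axis=1) > 1 + 1e-12).any():
            raise ValueError("sum_j s_xj must not exceed 1 at any age")

    @property
    def ages(self) -> np.ndarray:
        return self.values.index.to_numpy()


@dataclass(frozen=True)
class LifeTableCurves:
    """Per-age schedules: l_x, female-stage f_xj, m_x and l_x m_x."""

    lx: np.ndarray
    fx_female: np.ndarray
    mx: np.ndarray
    lxmx: np.ndarray
    ages: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.ages, "lx": self.lx, "fx_female": self.fx_female,
             "mx": self.mx, "lxmx": self.lxmx}
        )


@dataclass(frozen=True)
class PopulationParameters:
    """Population growth parameters with definedness flags.

    ``r`` and friends are undefined when the cohort produced no offspring
    (R0 = 0); ``notes`` records edge-case handling (e.g. the R0 = 1 limit
    where T is the mean age of maternity).
    """

    R0: float
    GRR: float
    r: float = math.nan
    lambda_: float = math.nan
    T: float = math.nan
    defined: bool = True
    notes: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {"r": self.r, "lambda": self.lambda_, "R0": self.R0,
                "GRR": self.GRR, "T": self.T}


@dataclass(frozen=True)
class StageExpectancy:
    """Life expectancy e_xj (expected remaining days) per (age, stage).

    Unoccupied (x, j) cells are NaN.  ``method`` records the
    hypothetical-cohort construction used.
    """

    exj: pd.DataFrame
    method: str = EXPECTANCY_METHOD


@dataclass(frozen=True)
class ReproductiveValueMatrix:
    """Reproductive value v_xj per (age, stage); NaN where unoccupied."""

    vxj: pd.DataFrame
    r: float
    method: str = EXPECTANCY_METHOD


@dataclass(frozen=True)
class ReproductionSummary:
    """Cohort reproduction/survival bookkeeping (Table-3-style summaries)."""

    Fn: int
    RepF: int
    male_count: int
    APOP: float
    TPOP: float
    Sa: float
    ovi_days: float
    F: float
    female_fraction: float

    def as_dict(self) -> dict[str, float]:
        return {
            "Fn": self.Fn, "RepF": self.RepF, "male_count": self.male_count,
            "APOP": self.APOP, "TPOP": self.TPOP, "Sa": self.Sa,
            "ovi_days": self.ovi_days, "F": self.F,
            "female_fraction": self.female_fraction,
        }


# -- core schedules ---------------------------------------------------------


def compute_sxj(cohort: CohortTable) -> AgeStageMatrix:
    """Daily roll-call: s_xj = (alive in stage j on age-day x) / n."""
    x_max = cohort.max_age()
    counts = np.zeros((x_max, len(STAGES)), dtype=float)
    for rec in cohort:
        for stage, start, stop in rec.stage_intervals():
            counts[start:stop, STAGES.index(stage)] += 1.0
    values = pd.DataFrame(counts / cohort.n, columns=list(STAGES))
    values.index.name = "x"
    return AgeStageMatrix(values=values, n=cohort.n)


def compute_lx(S: AgeStageMatrix) -> np.ndarray:
    """Age-specific survival l_x = sum over stages of s_xj."""
    return S.values.sum(axis=1).to_numpy()


def _eggs_by_age(cohort: CohortTable, x_max: int) -> np.ndarray:
    eggs = np.zeros(x_max, dtype=float)
    for rec in cohort:
        for age, n_eggs in rec.eggs_by_age().items():
            eggs[age] += n_eggs
    return eggs


def compute_mx(S: AgeStageMatrix, cohort: CohortTable) -> LifeTableCurves:
    """Population fecundity schedule.

    ``f_x,female`` is eggs laid on age-day x per living female adult;
    ``m_x`` is the s-weighted mean fecundity over all living individuals,
    which reduces to (eggs on day x / n) / l_x.  Ages with l_x = 0 get
    m_x = 0.
    """
    lx = compute_lx(S)
    eggs = _eggs_by_age(cohort, len(lx))
    s_female = S.values["female"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        fx = np.where(s_female > 0, eggs / (S.n * s_female), 0.0)
        mx = np.where(lx > 0, (eggs / S.n) / lx, 0.0)
    return LifeTableCurves(lx=lx, fx_female=fx, mx=mx, lxmx=lx * mx, ages=S.ages)


def compute_R0_GRR(curves: LifeTableCurves) -> tuple[float, float]:
    """Net and gross reproductive rates: R0 = sum l_x m_x, GRR = sum m_x."""
    return float(curves.lxmx.sum()), float(curves.mx.sum())


# -- Euler-Lotka ------------------------------------------------------------


def euler_lotka_r(
    ages: np.ndarray, lxmx: np.ndarray, tol: float = 1e-12
) -> float:
    """Root of ``sum exp(-r (age+1)) lxmx = 1`` on an arbitrary age grid.

    The residual is strictly decreasing in r, so bisection on [-1, 2]
    converges to the unique real root; a few Newton steps polish it.
    """
    ages = np.asarray(ages, dtype=float)
    lxmx = np.asarray(lxmx, dtype=float)
    mask = lxmx > 0
    a1 = ages[mask] + 1.0
    w = lxmx[mask]
    if w.size == 0:
        raise ValueError("no reproduction: Euler-Lotka r is undefined")

    def f(r: float) -> float:
        return float(np.exp(-r * a1) @ w) - 1.0

    lo, hi = -1.0, 2.0
    if f(lo) < 0 or f(hi) > 0:  # extremely fast growth/decline; widen
        lo, hi = -10.0, 10.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    r = 0.5 * (lo + hi)
    for _ in range(4):  # Newton polish
        fr = f(r)
        dfr = float(-(a1 * np.exp(-r * a1)) @ w)
        if dfr == 0:
            break
        step = fr / dfr
        r -= step
        if abs(step) < 1e-15:
            break
    return r


def solve_r(curves: LifeTableCurves) -> PopulationParameters:
    """Population parameters from the fecundity schedule.

    R0 = 0 leaves r, lambda, T undefined (flagged).  R0 = 1 exactly gives
    r = 0 and T equal to the mean age of maternity (the ln(R0)/r limit),
    flagged in ``notes``.
    """
    R0, GRR = compute_R0_GRR(curves)
    if R0 == 0:
        return PopulationParameters(R0=R0, GRR=GRR, defined=False,
                                    notes=("R0=0: growth rate undefined",))
    if math.isclose(R0, 1.0, rel_tol=0, abs_tol=1e-14):
        T = float(((curves.ages + 1.0) * curves.lxmx).sum() / R0)
        return PopulationParameters(
            R0=R0, GRR=GRR, r=0.0, lambda_=1.0, T=T,
            notes=("R0=1: r=0; T is the mean age of maternity (limit of ln R0 / r)",),
        )
    r = euler_lotka_r(curves.ages, curves.lxmx)
    if r == 0.0:
        T = float(((curves.ages + 1.0) * curves.lxmx).sum() / R0)
        notes = ("r=0: T is the mean age of maternity",)
    else:
        T = math.log(R0) / r
        notes = ()
    return PopulationParameters(R0=R0, GRR=GRR, r=r, lambda_=math.exp(r), T=T,
                                notes=notes)


# -- hypothetical-cohort quantities ----------------------------------------


def _transition_frequencies(
    cohort: CohortTable, x_max: int
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical daily dynamics: occupancy counts N[x, j] and one-day
    transition probability matrices P[x, j, j'] (rows of dead/unoccupied
    cells are zero)."""
    m = len(STAGES)
    N = np.zeros((x_max, m))
    M = np.zeros((x_max, m, m))
    for rec in cohort:
        intervals = rec.stage_intervals()
        stage_at: dict[int, int] = {}
        for stage, start, stop in intervals:
            j = STAGES.index(stage)
            for x in range(start, stop):
                stage_at[x] = j
        for x, j in stage_at.items():
            N[x, j] += 1
            nxt = stage_at.get(x + 1)
            if nxt is not None:
                M[x, j, nxt] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(N[:, :, None] > 0, M / N[:, :, None], 0.0)
    return N, P


def _female_daily_fecundity(cohort: CohortTable, x_max: int) -> np.ndarray:
    """f'_x,female: eggs on age-day x per female adult alive that day."""
    eggs = _eggs_by_age(cohort, x_max)
    females = np.zeros(x_max)
    for rec in cohort:
        for stage, start, stop in rec.stage_intervals():
            if stage == "female":
                females[start:stop] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(females > 0, eggs / females, 0.0)


def life_expectancy(S: AgeStageMatrix, cohort: CohortTable) -> StageExpectancy:
    """Expected remaining days e_xj per occupied (age, stage) cell.

    A hypothetical cohort is started with probability one at (x, j) and
    propagated with the empirical daily transition frequencies; e_xj is its
    total expected person-days from day x onward (the current day counts,
    so e_xj >= 1 for occupied cells).  e_0,egg equals the cohort mean
    lifespan exactly.
    """
    x_max = cohort.max_age()
    N, P = _transition_frequencies(cohort, x_max)
    m = len(STAGES)
    exj = np.full((x_max, m), np.nan)
    for x in range(x_max):
        for j in range(m):
            if N[x, j] == 0:
                continue
            w = np.zeros(m)
            w[j] = 1.0
            total = 0.0
            for i in range(x, x_max):
                total += w.sum()
                w = w @ P[i]
                if w.sum() <= 0:
                    break
            exj[x, j] = total
    frame = pd.DataFrame(exj, columns=list(STAGES))
    frame.index.name = "x"
    return StageExpectancy(exj=frame)


def reproductive_value(
    S: AgeStageMatrix,
    curves: LifeTableCurves,
    params: PopulationParameters,
    cohort: CohortTable,
) -> ReproductiveValueMatrix:
    """Expected discounted future offspring v_xj per (age, stage) occupant.

    v_xj = e^{r(x+1)} * sum_{i >= x} e^{-r(i+1)} sum_y s'_iy f'_iy with the
    same hypothetical cohort as the life expectancy; f' is nonzero only for
    the female-adult stage.  Male-adult v is identically zero (males sire
    no offspring in the two-sex bookkeeping).
    """
    if not params.defined or not math.isfinite(params.r):
        raise ValueError("reproductive value requires a finite growth rate r")
    r = params.r
    x_max = cohort.max_age()
    N, P = _transition_frequencies(cohort, x_max)
    fprime = _female_daily_fecundity(cohort, x_max)
    m = len(STAGES)
    vxj = np.full((x_max, m), np.nan)
    for x in range(x_max):
        for j in range(m):
            if N[x, j] == 0:
                continue
            w = np.zeros(m)
            w[j] = 1.0
            acc = 0.0
            for i in range(x, x_max):
                acc += math.exp(-r * (i + 1)) * w[_FEMALE] * fprime[i]
                w = w @ P[i]
                if w.sum() <= 0:
                    break
            vxj[x, j] = math.exp(r * (x + 1)) * acc
    vxj[:, STAGES.index("male")] = np.where(
        np.isnan(vxj[:, STAGES.index("male")]), np.nan, 0.0
    )
    frame = pd.DataFrame(vxj, columns=list(STAGES))
    frame.index.name = "x"
    return ReproductiveValueMatrix(vxj=frame, r=r)


# -- reproduction bookkeeping ----------------------------------------------


def summarize_reproduction(cohort: CohortTable) -> ReproductionSummary:
    """Counts and timing summaries: Fn, RepF, males, APOP, TPOP, Sa, F, ...

    APOP is days from adult emergence to first laying; TPOP is the age at
    first laying counted from age 0 (egg deposition).  Both are means over
    reproducing females and NaN when none reproduced.
    """
    females = [r for r in cohort if r.sex == "female"]
    males = [r for r in cohort if r.sex == "male"]
    repf = [r for r in females if r.total_eggs > 0]
    n = cohort.n
    Fn = len(females)
    adults = Fn + len(males)
    if repf:
        first_days = [min(d for d, e in r.fecundity.items() if e > 0) for r in repf]
        apop = float(np.mean([fd - 1 for fd in first_days]))
        tpop = float(
            np.mean([r.preadult_duration + fd - 1 for r, fd in zip(repf, first_days)])
        )
        ovi = float(np.mean([sum(1 for e in r.fecundity.values() if e > 0)
                             for r in repf]))
    else:
        apop = tpop = ovi = math.nan
    F = (sum(r.total_eggs for r in females) / Fn) if Fn else math.nan
    return ReproductionSummary(
        Fn=Fn,
        RepF=len(repf),
        male_count=len(males),
        APOP=apop,
        TPOP=tpop,
        Sa=adults / n,
        ovi_days=ovi,
        F=F,
        female_fraction=Fn / n,
    )


# -- model / results front-end ---------------------------------------------


class TwoSexLifeTable:
    """Age-stage two-sex life table model for a daily-census cohort.

    Parameters
    ----------
    cohort : CohortTable
        One treatment group's individual life histories.

    Examples
    --------
    >>> from twosexlt import simulate, TwoSexLifeTable
    >>> cohort = simulate.simulate_cohort(simulate.default_params("0"), seed=7)
    >>> res = TwoSexLifeTable(cohort).fit(bootstrap_reps=2000, seed=7)
    >>> float(res.params["R0"]) == res.curves.lxmx.sum()
    True
    """

    def __init__(self, cohort: CohortTable):
        self.cohort = cohort

    @classmethod
    def from_dataframe(
        cls, cohort_df: pd.DataFrame, fecundity_df: pd.DataFrame | None = None
    ) -> "TwoSexLifeTable":
        """Build from in-memory frames with the cohort/fecundity CSV schemas."""
        from .cohort import COHORT_COLUMNS, FECUNDITY_COLUMNS, IndividualRecord

        if list(cohort_df.columns) != COHORT_COLUMNS:
            raise CohortError(f"cohort frame must have columns {COHORT_COLUMNS}")
        fec: dict[str, dict[int, int]] = {}
        if fecundity_df is not None and len(fecundity_df):
            if list(fecundity_df.columns) != FECUNDITY_COLUMNS:
                raise CohortError(
                    f"fecundity frame must have columns {FECUNDITY_COLUMNS}"
                )
            for row in fecundity_df.itertuples(index=False):
                fec.setdefault(str(row.id), {})[int(row.adult_day)] = int(row.eggs)

        def opt(v) -> int | None:
            return None if pd.isna(v) or v == "" else int(v)

        records = []
        for row in cohort_df.itertuples(index=False):
            rid = str(row.id)
            records.append(
                IndividualRecord(
                    id=rid,
                    treatment=str(row.treatment),
                    egg_d=opt(row.egg_d),
                    larva_d=opt(row.larva_d),
                    pupa_d=opt(row.pupa_d),
                    sex=str(row.sex),
                    death_stage=str(row.death_stage),
                    adult_longevity_d=opt(row.adult_longevity_d) or 0,
                    fecundity=fec.pop(rid, {}),
                )
            )
        if fec:
            raise CohortError(f"fecundity rows with no matching cohort id: {sorted(fec)}")
        return cls(CohortTable(tuple(records)))

    @classmethod
    def from_csv(cls, path: str | Path, fecundity_path: str | Path) -> "TwoSexLifeTable":
        from .cohort import read_cohort

        return cls(read_cohort(path, fecundity_path))

    def fit(
        self,
        bootstrap_reps: int | None = None,
        seed: int | None = None,
        alpha: float = 0.05,
    ) -> "LifeTableResults":
        """Compute all life-table quantities; optionally bootstrap SEs.

        ``bootstrap_reps`` individuals-with-replacement resamples are used
        for standard errors when given (a seed is then mandatory).
        """
        S = compute_sxj(self.cohort)
        curves = compute_mx(S, self.cohort)
        pop = solve_r(curves)
        summary = summarize_reproduction(self.cohort)
        exj = life_expectancy(S, self.cohort)
        vxj = (
            reproductive_value(S, curves, pop, self.cohort)
            if pop.defined and math.isfinite(pop.r)
            else None
        )
        boot = None
        if bootstrap_reps:
            from .bootstrap import bootstrap_lifetable

            if seed is None:
                raise ValueError("bootstrapping requires an explicit seed")
            boot = bootstrap_lifetable(self.cohort, B=bootstrap_reps, seed=seed,
                                       alpha=alpha)
        return LifeTableResults(
            model=self, sxj=S, curves=curves, population=pop,
            reproduction=summary, expectancy=exj, repro_value=vxj,
            bootstrap=boot, alpha=alpha,
        )


_PARAM_ORDER = [
    "r", "lambda", "R0", "GRR", "T",
    "Fn", "RepF", "male_count", "APOP", "TPOP", "Sa", "ovi_days", "F",
    "female_fraction",
]


@dataclass
class LifeTableResults:
    """Fitted life-table results: point estimates, SEs, diagnostics.

    Attributes
    ----------
    params : pandas.Series
        Point estimates of the population parameters and reproduction
        summaries, in the cohort (not bootstrap-mean) sense.
    bse : pandas.Series
        Bootstrap standard errors (NaN when fitted without bootstrap).
    """

    model: TwoSexLifeTable
    sxj: AgeStageMatrix
    curves: LifeTableCurves
    population: PopulationParameters
    reproduction: ReproductionSummary
    expectancy: StageExpectancy
    repro_value: ReproductiveValueMatrix | None
    bootstrap: Mapping[str, "BootstrapResult"] | None = None
    alpha: float = 0.05
    params: pd.Series = field(init=False)
    bse: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        vals = {**self.population.as_dict(), **self.reproduction.as_dict()}
        self.params = pd.Series({k: float(vals[k]) for k in _PARAM_ORDER})
        if self.bootstrap:
            self.bse = pd.Series(
                {k: self.bootstrap[k].se if k in self.bootstrap else math.nan
                 for k in _PARAM_ORDER}
            )
        else:
            self.bse = pd.Series(math.nan, index=_PARAM_ORDER)

    def conf_int(self) -> pd.DataFrame:
        """Bootstrap percentile intervals (NaN without a bootstrap)."""
        lo, hi = {}, {}
        for k in _PARAM_ORDER:
            if self.bootstrap and k in self.bootstrap:
                lo[k] = self.bootstrap[k].ci_low
                hi[k] = self.bootstrap[k].ci_high
            else:
                lo[k] = hi[k] = math.nan
        return pd.DataFrame({"ci_low": lo, "ci_high": hi})

    def summary(self) -> str:
        """Readable parameter table, statsmodels-results style."""
        ci = self.conf_int()
        lines = [
            "Age-stage two-sex life table results",
            f"  treatment: {self.model.cohort.treatment}    "
            f"n = {self.model.cohort.n}    census: daily",
            f"  e_xj / v_xj method: {self.expectancy.method}",
        ]
        if self.bootstrap:
            any_res = next(iter(self.bootstrap.values()))
            lines.append(f"  bootstrap: B = {any_res.B} (individual resampling), "
                         f"seed = {any_res.seed}")
        lines.append(
            f"  {'parameter':<16}{'estimate':>12}{'boot SE':>12}"
            f"{'ci low':>12}{'ci high':>12}"
        )
        for k in _PARAM_ORDER:
            lines.append(
                f"  {k:<16}{self.params[k]:>12.4f}{self.bse[k]:>12.4f}"
                f"{ci.loc[k, 'ci_low']:>12.4f}{ci.loc[k, 'ci_high']:>12.4f}"
            )
        for note in self.population.notes:
            lines.append(f"  note: {note}")
        return "\n".join(lines)

    # -- exports ------------------------------------------------------------

    def curves_frame(self) -> pd.DataFrame:
        return self.curves.frame()

    def matrix_frame(self) -> pd.DataFrame:
        """Long (x, stage) frame of s_xj, e_xj and v_xj."""
        s_long = self.sxj.values.stack().rename("sxj")
        e_long = self.expectancy.exj.stack(future_stack=True).rename("exj")
        if self.repro_value is not None:
            v_long = self.repro_value.vxj.stack(future_stack=True).rename("vxj")
        else:
            v_long = pd.Series(math.nan, index=s_long.index, name="vxj")
        out = pd.concat([s_long, e_long, v_long], axis=1).reset_index()
        out.columns = ["x", "stage", "sxj", "exj", "vxj"]
        return out

    def to_tsv(self, curves_path: str | Path, matrix_path: str | Path) -> None:
        self.curves_frame().to_csv(curves_path, sep="\t", index=False)
        self.matrix_frame().to_csv(matrix_path, sep="\t", index=False)

    def params_json(self) -> str:
        payload = {
            "treatment": self.model.cohort.treatment,
            "n": self.model.cohort.n,
            "parameters": {k: _jsonable(self.params[k]) for k in _PARAM_ORDER},
            "bootstrap_se": {k: _jsonable(self.bse[k]) for k in _PARAM_ORDER},
            "defined": self.population.defined,
            "notes": list(self.population.notes),
            "expectancy_method": self.expectancy.method,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def plot_curves(self, ax=None):
        """Plot l_x, m_x and l_x m_x against age (matplotlib axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.curves.ages, self.curves.lx, label="$l_x$")
        ax.plot(self.curves.ages, self.curves.mx, label="$m_x$")
        ax.plot(self.curves.ages, self.curves.lxmx, label="$l_x m_x$")
        ax.set_xlabel("age (days)")
        ax.set_title(f"treatment {self.model.cohort.treatment}")
        ax.legend()
        return ax


def _jsonable(v: float) -> float | None:
    return None if (isinstance(v, float) and math.isnan(v)) else float(v)
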