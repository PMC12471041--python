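"""Life-table engine: schedules, growth parameters, expectancy, reproductive value.

Expected values come from hand enumeration, closed forms, or brute-force
oracles independent of the engine's code path.
"""

import math

import numpy as np
import pytest

from twosexlt.cohort import CohortError, CohortTable, IndividualRecord, lifespan
from twosexlt.lifetable import (
    PopulationParameters,
    TwoSexLifeTable,
    compute_R0_GRR,
    compute_lx,
    compute_mx,
    compute_sxj,
    euler_lotka_r,
    life_expectancy,
    reproductive_value,
    solve_r,
    summarize_reproduction,
)
from twosexlt.simulate import TREATMENTS, default_params, simulate_cohort


def _egg_death(rid, days, treatment="t"):
    return IndividualRecord(id=rid, treatment=treatment, egg_d=days,
                            larva_d=None, pupa_d=None, sex="undetermined",
                            death_stage="egg")


class TestAgeStageMatrix:
    def test_single_individual_two_day_egg(self):
        cohort = CohortTable((_egg_death("a", 2),))
        S = compute_sxj(cohort)
        assert S.values.loc[0, "egg"] == 1.0
        assert S.values.loc[1, "egg"] == 1.0
        assert S.values.drop(columns="egg").to_numpy().sum() == 0.0
        assert len(S.values) == 2

    def test_two_individual_hand_enumeration(self, two_individual_cohort):
        S = compute_sxj(two_individual_cohort)
        assert S.values.loc[0, "egg"] == 1.0
        assert S.values.loc[1, "egg"] == 0.5
        assert S.values.loc[2, "larva"] == 0.5
        lx = compute_lx(S)
        np.testing.assert_allclose(lx, [1.0, 0.5, 0.5, 0.5, 0.5])

    def test_matrix_matches_brute_force_roll_call(self):
        """s_xj equals an independent per-day roll call over the records."""
        cohort = simulate_cohort(default_params("0"), seed=17)
        S = compute_sxj(cohort)
        stages = list(S.values.columns)
        for x in S.ages:
            for j, stage in enumerate(stages):
                count = 0
                for rec in cohort:
                    age = 0
                    here = None
                    for name, start, stop in rec.stage_intervals():
                        if start <= x < stop:
                            here = name
                    if here == stage:
                        count += 1
                assert S.values.iloc[x, j] * cohort.n == pytest.approx(count)

    def test_lx_non_increasing_over_seeds(self):
        for seed in range(100):
            cohort = simulate_cohort(default_params("300", n=10), seed=seed)
            lx = compute_lx(compute_sxj(cohort))
            assert (np.diff(lx) <= 1e-12).all()

    def test_counts_are_integers_over_n(self):
        cohort = simulate_cohort(default_params("3"), seed=2)
        S = compute_sxj(cohort)
        counts = S.values.to_numpy() * cohort.n
        np.testing.assert_allclose(counts, np.round(counts), atol=1e-9)


class TestFecunditySchedules:
    def test_mx_weighted_mean_arithmetic(self):
        # one female and one male alive on the laying day: s_f = s_m = 0.5,
        # female lays 10 -> m_x = (0.5 * 10) / 1.0 = 5
        f = IndividualRecord(id="f", treatment="t", egg_d=1, larva_d=1,
                             pupa_d=1, sex="female", death_stage="adult",
                             adult_longevity_d=2, fecundity={1: 10})
        m = IndividualRecord(id="m", treatment="t", egg_d=1, larva_d=1,
                             pupa_d=1, sex="male", death_stage="adult",
                             adult_longevity_d=2)
        cohort = CohortTable((f, m))
        curves = compute_mx(compute_sxj(cohort), cohort)
        assert curves.fx_female[3] == pytest.approx(10.0)
        assert curves.mx[3] == pytest.approx(5.0)
        assert curves.lxmx[3] == pytest.approx(5.0)

    def test_no_females_means_zero_reproduction(self):
        cohort = CohortTable(
            tuple(
                IndividualRecord(id=f"m{i}", treatment="t", egg_d=2, larva_d=3,
                                 pupa_d=2, sex="male", death_stage="adult",
                                 adult_longevity_d=4)
                for i in range(5)
            )
        )
        curves = compute_mx(compute_sxj(cohort), cohort)
        assert (curves.mx == 0).all()
        R0, GRR = compute_R0_GRR(curves)
        assert R0 == 0.0 and GRR == 0.0

    def test_offspring_conservation_identity(self, control_cohort):
        """sum l_x m_x equals total eggs / n, computed from raw records."""
        curves = compute_mx(compute_sxj(control_cohort), control_cohort)
        total = sum(r.total_eggs for r in control_cohort)
        assert curves.lxmx.sum() == pytest.approx(total / control_cohort.n,
                                                  abs=1e-12)

    def test_handmade_five_individual_conservation(self):
        recs = [
            IndividualRecord(id=f"f{i}", treatment="t", egg_d=1 + i,
                             larva_d=2, pupa_d=2, sex="female",
                             death_stage="adult", adult_longevity_d=3,
                             fecundity={1: 4 + i, 3: 2})
            for i in range(3)
        ] + [_egg_death(f"d{i}", 1 + i) for i in range(2)]
        cohort = CohortTable(tuple(recs))
        curves = compute_mx(compute_sxj(cohort), cohort)
        assert curves.lxmx.sum() == pytest.approx(
            sum(r.total_eggs for r in cohort) / 5
        )


class TestEulerLotka:
    def test_reproduction_at_age_zero_r_zero(self):
        # all reproduction in the first interval with R0 = 1 -> r = 0
        assert euler_lotka_r(np.array([0]), np.array([1.0])) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_single_age_closed_form(self):
        # lxmx = 2 at age 1: exp(-2r) * 2 = 1 -> r = ln(2) / 2
        r = euler_lotka_r(np.array([1]), np.array([2.0]))
        assert r == pytest.approx(math.log(2) / 2, abs=1e-12)

    @pytest.mark.parametrize("age, R0", [(3, 5.0), (10, 0.3), (25, 93.7)])
    def test_single_age_family(self, age, R0):
        """Closed form r = ln(R0) / (a+1) for reproduction at a single age."""
        r = euler_lotka_r(np.array([age]), np.array([R0]))
        assert r == pytest.approx(math.log(R0) / (age + 1), abs=1e-12)

    def test_residual_below_1e10_and_identities(self, control_cohort):
        curves = compute_mx(compute_sxj(control_cohort), control_cohort)
        pop = solve_r(curves)
        residual = abs(
            np.sum(np.exp(-pop.r * (curves.ages + 1)) * curves.lxmx) - 1.0
        )
        assert residual < 1e-10
        assert pop.lambda_ == pytest.approx(math.exp(pop.r), rel=1e-15)
        assert pop.T == pytest.approx(math.log(pop.R0) / pop.r, rel=1e-15)

    def test_r0_zero_flagged_undefined(self):
        cohort = CohortTable(
            (IndividualRecord(id="m", treatment="t", egg_d=2, larva_d=3,
                              pupa_d=2, sex="male", death_stage="adult",
                              adult_longevity_d=4),)
        )
        pop = solve_r(compute_mx(compute_sxj(cohort), cohort))
        assert not pop.defined
        assert math.isnan(pop.r) and math.isnan(pop.T)

    def test_r0_exactly_one_limit_convention(self):
        # one female (n=1) laying exactly one egg at age 4
        f = IndividualRecord(id="f", treatment="t", egg_d=1, larva_d=1,
                             pupa_d=1, sex="female", death_stage="adult",
                             adult_longevity_d=3, fecundity={2: 1})
        pop = solve_r(compute_mx(compute_sxj(CohortTable((f,))),
                                 CohortTable((f,))))
        assert pop.R0 == 1.0
        assert pop.r == 0.0 and pop.lambda_ == 1.0
        assert pop.T == pytest.approx(5.0)  # mean age of maternity, (x+1)
        assert pop.notes

    def test_growth_sign_equivalences(self):
        for seed in range(10):
            cohort = simulate_cohort(default_params("300", n=30), seed=seed)
            pop = solve_r(compute_mx(compute_sxj(cohort), cohort))
            if not pop.defined:
                continue
            assert (pop.R0 > 1) == (pop.r > 0) == (pop.lambda_ > 1)

    def test_adding_eggs_weakly_increases_r0_and_r(self):
        base = simulate_cohort(default_params("30"), seed=9)
        females = [r for r in base if r.sex == "female" and r.fecundity]
        assert females
        boosted_records = []
        for r in base:
            if r.id == females[0].id:
                fec = dict(r.fecundity)
                day = max(fec)
                fec[day] += 50
                r = IndividualRecord(id=r.id, treatment=r.treatment,
                                     egg_d=r.egg_d, larva_d=r.larva_d,
                                     pupa_d=r.pupa_d, sex=r.sex,
                                     death_stage=r.death_stage,
                                     adult_longevity_d=r.adult_longevity_d,
                                     fecundity=fec)
            boosted_records.append(r)
        boosted = CohortTable(tuple(boosted_records))
        p0 = solve_r(compute_mx(compute_sxj(base), base))
        p1 = solve_r(compute_mx(compute_sxj(boosted), boosted))
        assert p1.R0 > p0.R0
        assert p1.r >= p0.r


class TestLifeExpectancy:
    def test_uniform_ten_day_lifespan(self):
        cohort = CohortTable(
            tuple(_egg_death(f"a{i}", 10) for i in range(4))
        )
        exj = life_expectancy(compute_sxj(cohort), cohort).exj
        assert exj.loc[0, "egg"] == pytest.approx(10.0)

    def test_two_lifespans_mean(self):
        cohort = CohortTable((_egg_death("a", 2), _egg_death("b", 5)))
        exj = life_expectancy(compute_sxj(cohort), cohort).exj
        assert exj.loc[0, "egg"] == pytest.approx(3.5)

    def test_e0_equals_mean_lifespan_arbitrary_cohorts(self):
        for seed in (1, 5, 12):
            cohort = simulate_cohort(default_params("30", n=40), seed=seed)
            exj = life_expectancy(compute_sxj(cohort), cohort).exj
            assert exj.loc[0, "egg"] == pytest.approx(
                np.mean([lifespan(r) for r in cohort]), abs=1e-9
            )

    def test_occupied_cells_at_least_one_day(self):
        cohort = simulate_cohort(default_params("300", n=30), seed=3)
        S = compute_sxj(cohort)
        exj = life_expectancy(S, cohort).exj
        occupied = S.values.to_numpy() > 0
        vals = exj.to_numpy()
        assert np.all(vals[occupied] >= 1.0 - 1e-12)
        assert np.all(np.isnan(vals[~occupied]))


class TestReproductiveValue:
    def _solo_female(self, fecundity, longevity=3):
        rec = IndividualRecord(id="f", treatment="t", egg_d=1, larva_d=1,
                               pupa_d=1, sex="female", death_stage="adult",
                               adult_longevity_d=longevity,
                               fecundity=fecundity)
        return CohortTable((rec,))

    def test_undiscounted_future_eggs(self):
        # r = 0: v today is simply all future eggs (5 laid tomorrow)
        cohort = self._solo_female({2: 5}, longevity=2)
        S = compute_sxj(cohort)
        curves = compute_mx(S, cohort)
        pop = PopulationParameters(R0=5.0, GRR=5.0, r=0.0, lambda_=1.0, T=1.0)
        v = reproductive_value(S, curves, pop, cohort).vxj
        assert v.loc[3, "female"] == pytest.approx(5.0)
        assert v.loc[4, "female"] == pytest.approx(5.0)

    def test_male_stage_identically_zero(self):
        cohort = simulate_cohort(default_params("0"), seed=6)
        S = compute_sxj(cohort)
        curves = compute_mx(S, cohort)
        pop = solve_r(curves)
        v = reproductive_value(S, curves, pop, cohort).vxj
        male = v["male"].dropna()
        assert len(male) > 0 and (male == 0).all()

    def test_peak_near_reproduction_onset(self):
        cohort = simulate_cohort(default_params("0"), seed=6)
        S = compute_sxj(cohort)
        curves = compute_mx(S, cohort)
        pop = solve_r(curves)
        v = reproductive_value(S, curves, pop, cohort).vxj["female"].dropna()
        assert v.iloc[0] >= v.iloc[-1]

    def test_matches_brute_force_markov_enumeration(self):
        """v equals an independently coded discounted-offspring enumeration."""
        cohort = simulate_cohort(default_params("3", n=12), seed=21)
        S = compute_sxj(cohort)
        curves = compute_mx(S, cohort)
        pop = solve_r(curves)
        v = reproductive_value(S, curves, pop, cohort).vxj
        # independent oracle: dict-based day-by-day state distribution
        x_max = cohort.max_age()
        occupants: dict[tuple[int, str], list] = {}
        for rec in cohort:
            for stage, start, stop in rec.stage_intervals():
                for x in range(start, stop):
                    occupants.setdefault((x, stage), []).append(rec)
        eggs_at = {}
        females_at = {}
        for rec in cohort:
            for age, k in rec.eggs_by_age().items():
                eggs_at[age] = eggs_at.get(age, 0) + k
        for (x, stage), recs in occupants.items():
            if stage == "female":
                females_at[x] = len(recs)

        def stage_of(rec, x):
            for stage, start, stop in rec.stage_intervals():
                if start <= x < stop:
                    return stage
            return None

        for (x, j), recs in occupants.items():
            dist = {(x, j): 1.0}
            acc = 0.0
            for i in range(x, x_max):
                fem = dist.get((i, "female"), 0.0)
                if fem and i in eggs_at:
                    acc += math.exp(-pop.r * (i + 1)) * fem * (
                        eggs_at[i] / females_at[i]
                    )
                nxt: dict[tuple[int, str], float] = {}
                for (age, stage), w in dist.items():
                    members = occupants[(age, stage)]
                    for rec in members:
                        s2 = stage_of(rec, age + 1)
                        if s2 is not None:
                            key = (age + 1, s2)
                            nxt[key] = nxt.get(key, 0.0) + w / len(members)
                dist = nxt
            expected = math.exp(pop.r * (x + 1)) * acc
            assert v.loc[x, j] == pytest.approx(expected, abs=1e-9), (x, j)


class TestReproductionSummary:
    def test_control_bookkeeping(self, control_cohort):
        s = summarize_reproduction(control_cohort)
        assert s.Fn == 9 and s.RepF == 9 and s.male_count == 10
        assert s.Sa == pytest.approx(0.95)
        assert s.female_fraction == pytest.approx(0.45)
        assert s.F == pytest.approx(1874 / 9)

    def test_mid_dose_bookkeeping(self, mid_dose_cohort):
        s = summarize_reproduction(mid_dose_cohort)
        assert s.Sa == pytest.approx(0.50)
        assert s.female_fraction == pytest.approx(0.20)

    def test_apop_tpop_single_female(self):
        # emergence at age 16, first egg at age 18 -> APOP 2, TPOP 18
        rec = IndividualRecord(id="f", treatment="t", egg_d=3, larva_d=7,
                               pupa_d=6, sex="female", death_stage="adult",
                               adult_longevity_d=10, fecundity={3: 5, 5: 2})
        s = summarize_reproduction(CohortTable((rec,)))
        assert s.APOP == pytest.approx(2.0)
        assert s.TPOP == pytest.approx(18.0)
        assert s.ovi_days == pytest.approx(2.0)

    def test_no_reproducers_flagged_nan(self):
        rec = IndividualRecord(id="m", treatment="t", egg_d=3, larva_d=7,
                               pupa_d=6, sex="male", death_stage="adult",
                               adult_longevity_d=10)
        s = summarize_reproduction(CohortTable((rec,)))
        assert s.RepF == 0
        assert math.isnan(s.APOP) and math.isnan(s.TPOP)
        assert math.isnan(s.ovi_days)

    def test_r0_equals_f_times_female_fraction(self):
        """Offspring conservation for arbitrary cohorts (both sides from eggs)."""
        for seed in range(8):
            cohort = simulate_cohort(default_params("3", n=25), seed=seed)
            s = summarize_reproduction(cohort)
            if s.Fn == 0:
                continue
            curves = compute_mx(compute_sxj(cohort), cohort)
            assert curves.lxmx.sum() == pytest.approx(
                s.F * s.female_fraction, abs=1e-10
            )


class TestModelResults:
    def test_fit_exports_and_summary(self, control_cohort, tmp_path):
        res = TwoSexLifeTable(control_cohort).fit(bootstrap_reps=500, seed=1)
        text = res.summary()
        assert "R0" in text and "bootstrap" in text
        res.to_tsv(tmp_path / "curves.tsv", tmp_path / "matrix.tsv")
        assert (tmp_path / "curves.tsv").exists()
        back = (tmp_path / "matrix.tsv").read_text()
        assert back.splitlines()[0] == "x\tstage\tsxj\texj\tvxj"
        ci = res.conf_int()
        assert (ci.loc["Sa", "ci_low"] <= res.params["Sa"]
                <= ci.loc["Sa", "ci_high"])

    def test_from_dataframe_roundtrip(self, control_cohort, tmp_path):
        from twosexlt.cohort import write_cohort
        import pandas as pd

        write_cohort(control_cohort, tmp_path / "c.csv", tmp_path / "f.csv")
        cdf = pd.read_csv(tmp_path / "c.csv", dtype={"treatment": str})
        fdf = pd.read_csv(tmp_path / "f.csv", dtype={"id": str})
        model = TwoSexLifeTable.from_dataframe(cdf, fdf)
        assert model.cohort.records == control_cohort.records

    def test_empty_cohort_rejected(self):
        with pytest.raises(CohortError):
            CohortTable(())

    def test_dose_ordering_of_intrinsic_rate(self):
        """Estimated r strictly decreases across the four default doses (n=2000)."""
        rs = []
        for trt in TREATMENTS:
            cohort = simulate_cohort(default_params(trt, n=2000), seed=5)
            rs.append(TwoSexLifeTable(cohort).fit().params["r"])
        assert all(a > b for a, b in zip(rs, rs[1:]))

    def test_parameter_recovery_at_n5000(self):
        """Engine recovers Sa, female fraction, durations and F within 3 MC sigma."""
        n = 5000
        params = default_params("0", n=n)
        cohort = simulate_cohort(params, seed=0)
        s = summarize_reproduction(cohort)
        assert abs(s.Sa - 0.95) < 3 * math.sqrt(0.95 * 0.05 / n)
        assert abs(s.female_fraction - 0.45) < 3 * math.sqrt(0.45 * 0.55 / n)
        lar = np.array([r.larva_d for r in cohort
                        if r.death_stage not in ("egg", "larva")], float)
        assert abs(lar.mean() - 7.4) < 3 * lar.std(ddof=1) / math.sqrt(len(lar))
        eggs = np.array([r.egg_d for r in cohort], float)
        assert abs(eggs.mean() - 3.4) < 3 * eggs.std(ddof=1) / math.sqrt(n)
        totals = np.array([r.total_eggs for r in cohort if r.sex == "female"],
                          float)
        assert abs(totals.mean() - 208.22) < 3 * totals.std(ddof=1) / math.sqrt(
            len(totals)
        )
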