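"""Individual-resampling bootstrap for life-table parameters.

The resampling unit is the whole individual: each replicate draws n
individuals with replacement (keeping each one's complete life history and
fecundity intact) and recomputes every population parameter and
reproduction summary.  The standard error is the standard deviation of the
bootstrap distribution; percentile intervals are reported alongside.

Replicates where a parameter is undefined (e.g. r when a resample contains
no reproducing female) are excluded from that parameter's aggregation and
counted in ``valid_B``.

The per-replicate life-table arithmetic is vectorised: per-individual
per-age egg and alive matrices are precomputed once, replicate schedules
are sums of resampled rows, and the Euler-Lotka root is found by a
bisection vectorised across replicates.  Results are bit-identical to
recomputing each replicate through the scalar engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .lifetable import _PARAM_ORDER

__all__ = ["BootstrapResult", "bootstrap_lifetable", "bootstrap_diff"]

_CHUNK = 4000  # replicates per vectorised block; bounds peak memory


@dataclass(frozen=True)
class BootstrapResult:
    """Summary of one parameter's bootstrap distribution."""

    parameter: str
    B: int
    mean: float
    se: float
    ci_low: float
    ci_high: float
    valid_B: int
    seed: int


def _precompute(cohort: CohortTable) -> dict[str, np.ndarray]:
    """Per-individual arrays from which every replicate statistic follows."""
    n = cohort.n
    x_max = cohort.max_age()
    eggs = np.zeros((n, x_max))
    alive = np.zeros((n, x_max))
    is_female = np.zeros(n, bool)
    is_male = np.zeros(n, bool)
    total_eggs = np.zeros(n)
    is_repf = np.zeros(n, bool)
    apop = np.zeros(n)
    tpop = np.zeros(n)
    ovi = np.zeros(n)
    for i, rec in enumerate(cohort):
        for _, start, stop in rec.stage_intervals():
            alive[i, start:stop] = 1.0
        for age, k in rec.eggs_by_age().items():
            eggs[i, age] += k
        is_female[i] = rec.sex == "female"
        is_male[i] = rec.sex == "male"
        total_eggs[i] = rec.total_eggs
        laying = [d for d, e in rec.fecundity.items() if e > 0]
        if laying:
            is_repf[i] = True
            first = min(laying)
            apop[i] = first - 1
            tpop[i] = rec.preadult_duration + first - 1
            ovi[i] = len(laying)
    return dict(
        eggs=eggs, alive=alive, is_female=is_female, is_male=is_male,
        total_eggs=total_eggs, is_repf=is_repf, apop=apop, tpop=tpop, ovi=ovi,
        n=n, x_max=x_max,
    )


def _solve_r_vec(lxmx: np.ndarray, R0: np.ndarray) -> np.ndarray:
    """Vectorised Euler-Lotka bisection on [-1, 2] per replicate row."""
    B, X = lxmx.shape
    a1 = np.arange(1, X + 1, dtype=float)
    ok = R0 > 0
    r_lo = np.full(B, -1.0)
    r_hi = np.full(B, 2.0)
    # widen for rows outside the default bracket (pathological schedules)
    for _ in range(3):
        f_lo = (np.exp(-np.outer(r_lo, a1)) * lxmx).sum(1) - 1.0
        f_hi = (np.exp(-np.outer(r_hi, a1)) * lxmx).sum(1) - 1.0
        bad = ok & ((f_lo < 0) | (f_hi > 0))
        if not bad.any():
            break
        r_lo[bad & (f_lo < 0)] -= 4.0
        r_hi[bad & (f_hi > 0)] += 4.0
    for _ in range(70):
        mid = 0.5 * (r_lo + r_hi)
        f_mid = (np.exp(-np.outer(mid, a1)) * lxmx).sum(1) - 1.0
        go_up = f_mid > 0
        r_lo = np.where(go_up, mid, r_lo)
        r_hi = np.where(go_up, r_hi, mid)
    r = 0.5 * (r_lo + r_hi)
    return np.where(ok, r, np.nan)


def _replicate_params(pre: dict, idx: np.ndarray) -> dict[str, np.ndarray]:
    """All parameters for a block of replicates given index matrix (B, n)."""
    n = pre["n"]
    eggs_rep = pre["eggs"][idx].sum(axis=1)    # (B, X)
    alive_rep = pre["alive"][idx].sum(axis=1)  # (B, X)
    lxmx = eggs_rep / n
    R0 = lxmx.sum(1)
    with np.errstate(divide="ignore", invalid="ignore"):
        GRR = np.where(alive_rep > 0, eggs_rep / alive_rep, 0.0).sum(1)
    r = _solve_r_vec(lxmx, R0)
    lam = np.exp(r)
    with np.errstate(divide="ignore", invalid="ignore"):
        T = np.where(r != 0, np.log(np.where(R0 > 0, R0, np.nan)) / r, np.nan)

    Fn = pre["is_female"][idx].sum(1).astype(float)
    males = pre["is_male"][idx].sum(1).astype(float)
    repf = pre["is_repf"][idx].sum(1).astype(float)
    tot = pre["total_eggs"][idx].sum(1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(Fn > 0, tot / Fn, np.nan)
        apop = np.where(repf > 0,
                        (pre["apop"] * pre["is_repf"])[idx].sum(1) / repf, np.nan)
        tpop = np.where(repf > 0,
                        (pre["tpop"] * pre["is_repf"])[idx].sum(1) / repf, np.nan)
        ovi = np.where(repf > 0,
                       (pre["ovi"] * pre["is_repf"])[idx].sum(1) / repf, np.nan)
    return {
        "r": r, "lambda": lam, "R0": R0, "GRR": GRR, "T": T,
        "Fn": Fn, "RepF": repf, "male_count": males,
        "APOP": apop, "TPOP": tpop, "Sa": (Fn + males) / n,
        "ovi_days": ovi, "F": F, "female_fraction": Fn / n,
    }


def bootstrap_distributions(
    cohort: CohortTable, B: int, seed: int
) -> dict[str, np.ndarray]:
    """Raw bootstrap distributions (length B; NaN where undefined)."""
    if B < 1:
        raise ValueError("B must be >= 1")
    if seed is None:
        raise ValueError("an explicit seed is mandatory")
    pre = _precompute(cohort)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, pre["n"], size=(B, pre["n"]))
    out: dict[str, list[np.ndarray]] = {k: [] for k in _PARAM_ORDER}
    for start in range(0, B, _CHUNK):
        block = _replicate_params(pre, idx[start:start + _CHUNK])
        for k in _PARAM_ORDER:
            out[k].append(block[k])
    return {k: np.concatenate(v) for k, v in out.items()}


def bootstrap_lifetable(
    cohort: CohortTable, B: int, seed: int, alpha: float = 0.05
) -> dict[str, BootstrapResult]:
    """Bootstrap means, SEs and percentile CIs for every parameter.

    Deterministic given (cohort, B, seed).
    """
    dists = bootstrap_distributions(cohort, B, seed)
    results: dict[str, BootstrapResult] = {}
    for name, d in dists.items():
        valid = d[~np.isnan(d)]
        if valid.size == 0:
            results[name] = BootstrapResult(name, B, np.nan, np.nan, np.nan,
                                            np.nan, 0, seed)
            continue
        se = float(valid.std(ddof=1)) if valid.size > 1 else 0.0
        lo, hi = np.percentile(valid, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        results[name] = BootstrapResult(
            parameter=name, B=B, mean=float(valid.mean()), se=se,
            ci_low=float(lo), ci_high=float(hi), valid_B=int(valid.size),
            seed=seed,
        )
    return results


def bootstrap_results_frame(results: dict[str, BootstrapResult]) -> pd.DataFrame:
    """TSV-ready frame: parameter, mean, SE, CI_lo, CI_hi, valid_B, B, seed."""
    return pd.DataFrame(
        [
            {"parameter": r.parameter, "mean": r.mean, "SE": r.se,
             "CI_lo": r.ci_low, "CI_hi": r.ci_high, "valid_B": r.valid_B,
             "B": r.B, "seed": r.seed}
            for r in results.values()
        ]
    )


def bootstrap_diff(
    cohort_a: CohortTable,
    cohort_b: CohortTable,
    B: int,
    seed: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired-by-replicate bootstrap difference (A minus B) per parameter.

    When the cohorts have equal size, one index stream per replicate is
    applied to both, so comparing a cohort with itself yields exactly zero
    differences; unequal sizes fall back to replicate streams derived
    independently from ``seed``.  Differences are paired by replicate
    index.  Returns a frame with mean, SE and percentile CI of each
    difference.
    """
    if cohort_a.n == cohort_b.n:
        da = bootstrap_distributions(cohort_a, B, seed)
        db = bootstrap_distributions(cohort_b, B, seed)
    else:
        seed_a = int(np.random.SeedSequence([seed, 0]).generate_state(1)[0] % 2**31)
        seed_b = int(np.random.SeedSequence([seed, 1]).generate_state(1)[0] % 2**31)
        da = bootstrap_distributions(cohort_a, B, seed_a)
        db = bootstrap_distributions(cohort_b, B, seed_b)
    rows = []
    for name in _PARAM_ORDER:
        diff = da[name] - db[name]
        valid = diff[~np.isnan(diff)]
        if valid.size == 0:
            rows.append({"parameter": name, "mean": np.nan, "SE": np.nan,
                         "CI_lo": np.nan, "CI_hi": np.nan,
                         "valid_B": 0, "B": B, "seed": seed})
            continue
        lo, hi = np.percentile(valid, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        rows.append({
            "parameter": name, "mean": float(valid.mean()),
            "SE": float(valid.std(ddof=1)) if valid.size > 1 else 0.0,
            "CI_lo": float(lo), "CI_hi": float(hi),
            "valid_B": int(valid.size), "B": B, "seed": seed,
        })
    return pd.DataFrame(rows)
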