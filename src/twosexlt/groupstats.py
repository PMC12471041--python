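"""Assumption-screened group comparisons for replicate-level endpoints.

Decision procedure for one endpoint measured in a few biological replicates
per treatment: screen ANOVA assumptions (Shapiro-Wilk on residuals,
median-centred Levene across groups, alpha = 0.05); if the screen fails,
apply the variance-stabilising transform (ln(x+1) for activities and
physiological measurements, arcsine-square-root for proportions) and
re-screen; if the transformed data still fail, fall back to Kruskal-Wallis
with Dunn's pairwise z-tests under the Holm adjustment; otherwise one-way
ANOVA with Tukey's HSD.  Group separation is reported as a compact letter
display on the adjusted pairwise p-values.

Shapiro-Wilk runs on residuals (value minus group mean) rather than per
group: with n = 3 replicates per group, per-group normality tests have
essentially no power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssumptionReport",
    "ComparisonResult",
    "apply_transform",
    "screen_assumptions",
    "compare_groups",
    "dunn_holm",
    "compact_letter_display",
]

ALPHA = 0.05
TRANSFORMS = ("none", "log1p", "arcsine_sqrt")


def apply_transform(values: Sequence[float], kind: str) -> np.ndarray:
    """Elementwise transform: none, log1p, or arcsine-square-root.

    The arcsine transform requires proportions in [0, 1]; divide
    percentages by 100 first.
    """
    x = np.asarray(values, dtype=float)
    if kind == "none":
        return x
    if kind == "log1p":
        return np.log1p(x)
    if kind == "arcsine_sqrt":
        if ((x < 0) | (x > 1)).any():
            raise ValueError("arcsine-sqrt requires values in [0, 1]")
        return np.arcsin(np.sqrt(x))
    raise ValueError(f"unknown transform {kind!r}; expected one of {TRANSFORMS}")


@dataclass(frozen=True)
class AssumptionReport:
    """Shapiro-Wilk / Levene screen for one endpoint table."""

    shapiro_p: float
    levene_p: float
    assessable: bool
    normal_ok: bool
    variance_ok: bool

    @property
    def passed(self) -> bool:
        return self.assessable and self.normal_ok and self.variance_ok


def _groups(table: pd.DataFrame) -> list[np.ndarray]:
    return [g["value"].to_numpy(float) for _, g in table.groupby("treatment", sort=True)]


def _validate(table: pd.DataFrame) -> None:
    required = {"treatment", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"endpoint table needs columns {sorted(required)}")
    sizes = table.groupby("treatment").size()
    if len(sizes) < 2:
        raise ValueError("need at least 2 treatment groups")
    if (sizes < 2).any():
        raise ValueError("need at least 2 replicates per treatment")


def screen_assumptions(table: pd.DataFrame, alpha: float = ALPHA) -> AssumptionReport:
    """Normality of residuals and homogeneity of variances at level alpha.

    Degenerate inputs (all residuals identical) make the Shapiro-Wilk
    statistic undefined; the screen is then reported non-assessable, which
    routes the comparison to the nonparametric branch.
    """
    _validate(table)
    groups = _groups(table)
    residuals = np.concatenate([g - g.mean() for g in groups])
    if np.ptp(residuals) < 1e-12 * max(1.0, np.abs(residuals).max(initial=0.0)):
        return AssumptionReport(math.nan, math.nan, assessable=False,
                                normal_ok=False, variance_ok=False)
    shapiro_p = float(stats.shapiro(residuals).pvalue)
    levene_p = float(stats.levene(*groups, center="median").pvalue)
    return AssumptionReport(
        shapiro_p=shapiro_p,
        levene_p=levene_p,
        assessable=True,
        normal_ok=shapiro_p >= alpha,
        variance_ok=levene_p >= alpha,
    )


def dunn_holm(table: pd.DataFrame) -> pd.DataFrame:
    """Dunn's pairwise mean-rank z-tests with tie correction, Holm-adjusted.

    Returns one row per unordered treatment pair: z, raw two-sided p and
    Holm-adjusted p.
    """
    _validate(table)
    values = table["value"].to_numpy(float)
    labels = table["treatment"].astype(str).to_numpy()
    ranks = stats.rankdata(values)
    N = len(values)
    # tie correction to the rank variance
    _, counts = np.unique(values, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (N - 1)) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - tie_term
    names = sorted(set(labels))
    mean_rank = {g: ranks[labels == g].mean() for g in names}
    n_g = {g: (labels == g).sum() for g in names}
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            sd = math.sqrt(var_base * (1.0 / n_g[a] + 1.0 / n_g[b]))
            z = (mean_rank[a] - mean_rank[b]) / sd if sd > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append({"group1": a, "group2": b, "stat": z, "p_raw": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p_raw"], method="holm")[1]
    return out


def _tukey_pairs(table: pd.DataFrame) -> pd.DataFrame:
    groups = _groups(table)
    names = sorted(table["treatment"].astype(str).unique())
    res = stats.tukey_hsd(*groups)
    rows = []
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            rows.append({
                "group1": a, "group2": names[j],
                "stat": float(res.statistic[i, j]),
                "p_raw": float(res.pvalue[i, j]),
                "p_adj": float(res.pvalue[i, j]),  # HSD p is family-adjusted
            })
    return pd.DataFrame(rows)


def compact_letter_display(
    pairs: pd.DataFrame, groups: Sequence[str], alpha: float = ALPHA
) -> dict[str, str]:
    """Shared-letter labelling from adjusted pairwise p-values.

    Groups not significantly different share a letter.  Standard insertion
    algorithm; ties are broken by sorting treatment labels alphabetically.
    """
    groups = sorted(groups)
    differ = sorted(
        {
            tuple(sorted((row.group1, row.group2)))
            for row in pairs.itertuples(index=False)
            if row.p_adj < alpha
        }
    )
    # insert-and-absorb sweep: split every letter set containing a
    # significantly different pair, then drop sets contained in others
    letter_sets: list[set[str]] = [set(groups)]
    for a, b in differ:
        nxt: list[set[str]] = []
        for s in letter_sets:
            if a in s and b in s:
                nxt.append(s - {a})
                nxt.append(s - {b})
            else:
                nxt.append(s)
        letter_sets = [
            s for i, s in enumerate(nxt)
            if s and not any(
                (s < t) or (s == t and i > j) for j, t in enumerate(nxt)
            )
        ]
    letter_sets.sort(key=lambda s: sorted(s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for k, s in enumerate(letter_sets):
        for g in sorted(s):
            out[g] += alphabet[k % len(alphabet)]
    return out


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of the full decision procedure for one endpoint."""

    endpoint: str
    test_used: str                      # "ANOVA+TukeyHSD" or "KruskalWallis+Dunn-Holm"
    transform_used: str
    screen_raw: AssumptionReport
    screen_transformed: AssumptionReport | None
    statistic: float
    pvalue: float
    pairwise: pd.DataFrame
    letters: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        base = {
            "endpoint": self.endpoint,
            "test_used": self.test_used,
            "transform_used": self.transform_used,
            "shapiro_p": self.screen_raw.shapiro_p,
            "levene_p": self.screen_raw.levene_p,
            "omnibus_stat": self.statistic,
            "omnibus_p": self.pvalue,
        }
        rows = []
        for row in self.pairwise.itertuples(index=False):
            rows.append({**base, "group1": row.group1, "group2": row.group2,
                         "p_adj": row.p_adj,
                         "letters1": self.letters.get(row.group1, ""),
                         "letters2": self.letters.get(row.group2, "")})
        return pd.DataFrame(rows)


def compare_groups(
    table: pd.DataFrame,
    transform: str = "log1p",
    alpha: float = ALPHA,
    endpoint: str | None = None,
) -> ComparisonResult:
    """Run the screen -> transform -> re-screen -> test decision tree.

    ``transform`` names the fallback applied only when the untransformed
    screen fails ("log1p" for measurements, "arcsine_sqrt" for
    proportions).  The branch actually taken is recorded in the result, not
    asserted in advance.
    """
    _validate(table)
    if transform not in TRANSFORMS or transform == "none":
        raise ValueError("transform must be 'log1p' or 'arcsine_sqrt'")
    name = endpoint or str(table.get("endpoint", pd.Series(["endpoint"])).iloc[0])
    work = table[["treatment", "value"]].copy()
    work["treatment"] = work["treatment"].astype(str)

    screen_raw = screen_assumptions(work, alpha)
    screen_tr: AssumptionReport | None = None
    transform_used = "none"
    data = work
    parametric = screen_raw.passed
    if not parametric and screen_raw.assessable:
        transformed = work.copy()
        transformed["value"] = apply_transform(work["value"].to_numpy(), transform)
        screen_tr = screen_assumptions(transformed, alpha)
        if screen_tr.passed:
            parametric = True
            transform_used = transform
            data = transformed

    groups = _groups(data)
    names = sorted(data["treatment"].unique())
    if parametric:
        stat, p = stats.f_oneway(*groups)
        pairs = _tukey_pairs(data)
        test_used = "ANOVA+TukeyHSD"
    else:
        if np.ptp(data["value"].to_numpy(float)) == 0:
            # all values identical: no evidence of any difference
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.kruskal(*groups)
        pairs = dunn_holm(data)
        test_used = "KruskalWallis+Dunn-Holm"
    letters = compact_letter_display(pairs, names, alpha)
    return ComparisonResult(
        endpoint=name,
        test_used=test_used,
        transform_used=transform_used,
        screen_raw=screen_raw,
        screen_transformed=screen_tr,
        statistic=float(stat),
        pvalue=float(p),
        pairwise=pairs,
        letters=letters,
    )
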