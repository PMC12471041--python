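"""Pearson correlation of treatment-wise mean variables, with heatmap export.

With only four treatment groups these correlations are exploratory
descriptions of dose-response co-movement (e.g. plant antioxidant activity
versus insect digestive-enzyme activity), not inferential statistics; the
matrix carries the per-pair n in its metadata and no p-values are attached.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "treatment_means_table",
    "pearson_matrix",
    "CorrelationMatrix",
    "render_heatmap",
    "export_heatmap",
]


def treatment_means_table(long: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long ``treatment, variable, value`` frame to treatments x variables.

    Replicate-level input (several rows per treatment/variable) is averaged.
    """
    required = {"treatment", "variable", "value"}
    if not required.issubset(long.columns):
        raise ValueError(f"long table needs columns {sorted(required)}")
    wide = long.pivot_table(index="treatment", columns="variable",
                            values="value", aggfunc="mean")
    if wide.isna().any().any():
        missing = [
            f"{v}@{t}" for t in wide.index for v in wide.columns
            if pd.isna(wide.loc[t, v])
        ]
        raise ValueError(f"missing cells in treatment-means table: {missing}")
    return wide


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric Pearson matrix with degenerate columns flagged, not zeroed."""

    matrix: pd.DataFrame
    n: int
    degenerate: tuple[str, ...] = ()
    note: str = "exploratory; treatment-wise means"

    def __post_init__(self) -> None:
        m = self.matrix.to_numpy(float)
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValueError("correlation matrix must be symmetric")


def pearson_matrix(table: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise Pearson coefficients over treatment-mean vectors.

    Requires at least 3 treatments.  Zero-variance variables yield NaN rows
    and are listed in ``degenerate`` rather than silently set to 0.
    """
    n = len(table)
    if n < 3:
        raise ValueError("need >= 3 treatments for a defined correlation")
    x = table.to_numpy(float)
    sd = x.std(axis=0)
    degenerate = tuple(table.columns[sd == 0])
    centred = x - x.mean(axis=0)
    cov = centred.T @ centred
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(np.outer(np.diag(cov), np.diag(cov)))
        rho = np.where(denom > 0, cov / denom, np.nan)
    ok = sd > 0
    np.fill_diagonal(rho, np.where(ok, 1.0, np.nan))
    rho = np.clip(rho, -1.0, 1.0)
    matrix = pd.DataFrame(rho, index=table.columns, columns=table.columns)
    return CorrelationMatrix(matrix=matrix, n=n, degenerate=degenerate)


def render_heatmap(M: CorrelationMatrix, order: list[str] | None = None):
    """Diverging heatmap figure; colour limits are exactly -1 and +1.

    ``order`` reorders variables (e.g. plant block first, insect block
    second).  Returns the matplotlib figure.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    mat = M.matrix
    if order is not None:
        mat = mat.loc[order, order]
    fig, ax = plt.subplots(figsize=(1.0 + 0.6 * len(mat), 0.8 + 0.6 * len(mat)))
    sns.heatmap(
        mat, vmin=-1.0, vmax=1.0, cmap="vlag", center=0.0, square=True,
        annot=len(mat) <= 12, fmt=".2f", cbar_kws={"label": "Pearson r"},
        ax=ax,
    )
    ax.set_title(f"Treatment-mean correlations (n = {M.n}; {M.note})")
    fig.tight_layout()
    return fig


def export_heatmap(
    M: CorrelationMatrix,
    path: str | Path,
    order: list[str] | None = None,
) -> Path:
    """Write the heatmap of :func:`render_heatmap` to ``path`` (PNG/SVG)."""
    import matplotlib.pyplot as plt

    fig = render_heatmap(M, order=order)
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
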