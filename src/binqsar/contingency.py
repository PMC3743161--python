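"""Univariate contingency-based descriptor screening.

Each descriptor is binned (equal-frequency) and crossed with the binary
activity label; four association statistics — the contingency coefficient
C, Cramer's V, the uncertainty coefficient U and the squared Pearson
correlation R^2 of the raw values with the 0/1 label — are combined into a
single relative importance (unweighted mean by default; the combiner is
pluggable because no single convention exists).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .descriptors import DescriptorMatrix

DEFAULT_N_BINS = 10
DEFAULT_IMPORTANCE_THRESHOLD = 0.2

Combiner = Callable[[float, float, float, float], float]


def mean_combiner(c: float, v: float, u: float, r2: float) -> float:
    return float(np.mean([c, v, u, r2]))


@dataclass(frozen=True)
class ContingencyScores:
    """Association statistics of one descriptor with the activity label."""

    name: str
    C: float
    V: float
    U: float
    R2: float
    rel_importance: float


def bin_descriptor(values: Sequence[float], n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Equal-frequency bin ids for a descriptor column.

    Duplicate quantile edges collapse (fewer effective bins); a constant
    vector yields a single bin.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty descriptor vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("descriptor vector has non-finite values")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="left")


def contingency_scores(
    x: Sequence[float],
    y: Sequence[int],
    n_bins: int = DEFAULT_N_BINS,
    name: str = "",
    combiner: Combiner = mean_combiner,
) -> ContingencyScores:
    """Score one descriptor column against the 0/1 activity label.

    C = sqrt(chi2/(chi2+n)); V = sqrt(chi2/(n*(min(r,c)-1))); U = I(X;Y)/H(Y)
    from the binned joint distribution; R2 = squared Pearson correlation of
    the raw values with the label.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if x.shape != y.shape:
        raise ValueError("x and y lengths differ")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")

    bins = bin_descriptor(x, n_bins)
    table = pd.crosstab(bins, y).to_numpy()
    r, c = table.shape
    if r < 2:
        chi2 = 0.0
    else:
        chi2 = float(stats.chi2_contingency(table, correction=False)[0])
    C = float(np.sqrt(chi2 / (chi2 + n)))
    V = float(np.sqrt(chi2 / (n * (min(r, c) - 1)))) if min(r, c) > 1 else 0.0
    U = _uncertainty_coefficient(table)
    if np.std(x) == 0:
        R2 = 0.0
    else:
        R2 = float(np.corrcoef(x, y)[0, 1] ** 2)
    return ContingencyScores(
        name=name, C=C, V=V, U=U, R2=R2, rel_importance=combiner(C, V, U, R2)
    )


def _uncertainty_coefficient(table: np.ndarray) -> float:
    """Theil's U = I(X;Y) / H(Y) from a bin-by-class count table."""
    p = table / table.sum()
    py = p.sum(axis=0)
    hy = -np.sum(py[py > 0] * np.log(py[py > 0]))
    if hy == 0:
        return 0.0
    px = p.sum(axis=1)
    outer = np.outer(px, py)
    mask = p > 0
    mi = float(np.sum(p[mask] * np.log(p[mask] / outer[mask])))
    return float(min(max(mi / hy, 0.0), 1.0))


def score_matrix(
    matrix: DescriptorMatrix,
    labels: Sequence[int],
    n_bins: int = DEFAULT_N_BINS,
    combiner: Combiner = mean_combiner,
) -> pd.DataFrame:
    """Score table (one row per descriptor) sorted by relative importance."""
    rows = []
    for name in matrix.names:
        col = matrix.frame[name].to_numpy(dtype=float)
        if np.std(col) == 0:
            rows.append(ContingencyScores(name, 0.0, 0.0, 0.0, 0.0, 0.0))
        else:
            rows.append(contingency_scores(col, labels, n_bins, name, combiner))
    frame = pd.DataFrame(
        [(s.name, s.C, s.V, s.U, s.R2, s.rel_importance) for s in rows],
        columns=["descriptor", "C", "V", "U", "R2", "rel_importance"],
    )
    return frame.sort_values(
        ["rel_importance", "descriptor"], ascending=[False, True]
    ).reset_index(drop=True)


def select_descriptors(
    matrix: DescriptorMatrix,
    labels: Sequence[int],
    importance_threshold: float = DEFAULT_IMPORTANCE_THRESHOLD,
    n_bins: int = DEFAULT_N_BINS,
    combiner: Combiner = mean_combiner,
) -> tuple[list[str], pd.DataFrame]:
    """Descriptors with relative importance >= threshold, ranked descending.

    Returns the selected names and the full score table for reporting.
    """
    if not 0.0 <= importance_threshold <= 1.0:
        raise ValueError("importance threshold must be in [0, 1]")
    if len(labels) != len(matrix.ids):
        raise ValueError("labels and matrix are not aligned")
    table = score_matrix(matrix, labels, n_bins, combiner)
    selected = table.loc[table["rel_importance"] >= importance_threshold, "descriptor"]
    return list(selected), table
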