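"""Detection of strictly monotone expression trends across ordered stages.

A gene is monotonically upregulated when its group means satisfy
control < I < II < III < IV (strictly), and downregulated under the
reversed chain. The ordered trend is quantified by the numeric-stage
linear model y = a*X + b with X in {0..4}; the significant monotone set
is the intersection of the strict mean ordering with a moderated slope
adjusted p-value below the cutoff, ranked by that adjusted p. Strict
monotonicity implies the maximal absolute departure from the control
mean is reached in stage IV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .groups import GROUPS
from .ingest import ExpressionDataset
from .linmod import GeneFitResults, LinModError, ModeratedStats


@dataclass
class MonotonicCall:
    gene: str
    means: np.ndarray  # over (control, I, II, III, IV)
    direction: str  # UP | DOWN | none
    slope: float
    intercept: float
    adj_p: float


def group_means(dataset: ExpressionDataset) -> pd.DataFrame:
    """Arithmetic mean expression per group per gene (genes x 5)."""
    sizes = dataset.group_sizes()
    empty = [g for g, n in sizes.items() if n == 0]
    if empty:
        raise LinModError(f"cannot compute group means: empty groups {empty}")
    out = {}
    for g in GROUPS:
        cols = dataset.sample_ids[dataset.groups == g]
        out[g] = dataset.values[cols].mean(axis=1)
    return pd.DataFrame(out)


def classify_monotonic(means) -> str:
    """'UP'/'DOWN' for strictly ordered group means, 'none' otherwise."""
    m = np.asarray(means, dtype=float)
    if m.shape != (len(GROUPS),):
        raise LinModError(f"expected {len(GROUPS)} group means, got shape {m.shape}")
    if not np.all(np.isfinite(m)):
        raise LinModError(f"non-finite group means: {m}")
    d = np.diff(m)
    if np.all(d > 0):
        return "UP"
    if np.all(d < 0):
        return "DOWN"
    return "none"


def classify_monotonic_frame(means: pd.DataFrame) -> pd.Series:
    """Vectorized strict-monotonicity classification of a genes x 5 frame."""
    d = np.diff(means.to_numpy(), axis=1)
    out = np.where(
        np.all(d > 0, axis=1), "UP", np.where(np.all(d < 0, axis=1), "DOWN", "none")
    )
    return pd.Series(out, index=means.index, name="direction")


def rank_monotonic(
    dataset: ExpressionDataset,
    numeric_fits: GeneFitResults,
    numeric_stats: ModeratedStats,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Significant strictly monotone genes ranked by numeric-model adjusted p.

    Returns one row per surviving gene: group means, direction, the
    numeric-stage model's intercept and slope, and the moderated slope's
    BH-adjusted p-value; sorted ascending by adjusted p.
    """
    if numeric_fits.design.kind != "numeric":
        raise LinModError("rank_monotonic requires fits under the numeric-stage design")
    means = group_means(dataset)
    direction = classify_monotonic_frame(means)
    slope_col = numeric_fits.design.columns.index("stage_numeric")
    intercept_col = numeric_fits.design.columns.index("intercept")

    table = means.copy()
    table["direction"] = direction
    table["intercept"] = numeric_fits.coefficients[:, intercept_col]
    table["slope"] = numeric_fits.coefficients[:, slope_col]
    table["adj_p"] = numeric_stats.adj_p_t[:, slope_col]

    keep = (table["direction"] != "none") & (table["adj_p"] < p_max)
    return table[keep].sort_values("adj_p", kind="stable")
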