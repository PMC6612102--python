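"""Contrast matrices over the cell-means parameterization.

Two contrast families drive the stage-specificity analysis: the four
stage-versus-control contrasts (each stage's coefficient +1 against the
control's -1), whose estimates are the stagewise log fold-changes, and
the six pairwise inter-stage contrasts, which isolate whether a gene's
change in one stage differs from its change in every other stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .groups import CONTROL, GROUPS, STAGES
from .linmod import GeneFitResults, LinModError, ModeratedStats, adjust_bh


@dataclass(frozen=True)
class ContrastSpec:
    """A named zero-sum coefficient vector over (control, I, II, III, IV)."""

    name: str
    vector: tuple[float, ...]

    def __post_init__(self) -> None:
        if abs(sum(self.vector)) > 1e-12:
            raise LinModError(f"contrast {self.name!r} does not sum to zero")


def _unit_contrast(name: str, plus: str, minus: str) -> ContrastSpec:
    v = [0.0] * len(GROUPS)
    v[GROUPS.index(plus)] = 1.0
    v[GROUPS.index(minus)] = -1.0
    return ContrastSpec(name, tuple(v))


def control_contrasts() -> list[ContrastSpec]:
    """The four stage-vs-control contrasts, +1 on the stage, -1 on control."""
    return [_unit_contrast(f"{s}_vs_control", s, CONTROL) for s in STAGES]


def interstage_contrasts() -> list[ContrastSpec]:
    """The six pairwise inter-stage contrasts, +1 on the earlier stage.

    Orientation is a reporting convention only: the significance cascade
    uses |t| and the two-sided p-value, which are orientation-invariant.
    """
    return [_unit_contrast(f"{a}_vs_{b}", a, b) for a, b in combinations(STAGES, 2)]


@dataclass
class ContrastResult:
    """Per-gene, per-contrast estimates and moderated significance.

    Each frame is genes x contrasts; ``adj_p`` is BH-adjusted within each
    contrast family member (i.e. per column, across genes).
    """

    estimate: pd.DataFrame
    t: pd.DataFrame
    p: pd.DataFrame
    adj_p: pd.DataFrame

    @property
    def names(self) -> list[str]:
        return list(self.estimate.columns)

    def long_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.names:
            rows.append(
                pd.DataFrame(
                    {
                        "gene": self.estimate.index,
                        "contrast": name,
                        "lfc": self.estimate[name].to_numpy(),
                        "t": self.t[name].to_numpy(),
                        "p": self.p[name].to_numpy(),
                        "adj_p": self.adj_p[name].to_numpy(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def apply_contrasts(
    fits: GeneFitResults,
    specs: list[ContrastSpec],
    moderation: ModeratedStats,
) -> ContrastResult:
    """Propagate fitted coefficients through contrasts with moderated errors.

    estimate = c' beta-hat; unscaled SD = sqrt(c' (X'WX)^-1 c); the
    moderated t divides by the posterior residual SD and is referred to a
    t distribution on d0 + d degrees of freedom.
    """
    p_coef = fits.coefficients.shape[1]
    for spec in specs:
        if len(spec.vector) != p_coef:
            raise LinModError(
                f"contrast {spec.name!r} has length {len(spec.vector)}, "
                f"but the fit has {p_coef} coefficients"
            )
    C = np.array([spec.vector for spec in specs]).T  # p x c
    est = fits.coefficients @ C
    if fits.weighted:
        var_unscaled = np.einsum("pc,gpq,qc->gc", C, fits.cov_unscaled, C)
    else:
        var_unscaled = np.broadcast_to(
            np.einsum("pc,pq,qc->c", C, fits.cov_unscaled, C), est.shape
        )
    se = np.sqrt(var_unscaled * moderation.var_post[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = est / se
    p = 2.0 * stats.t.sf(np.abs(t), moderation.df_total[:, None])
    adj = np.column_stack([adjust_bh(p[:, j]) for j in range(p.shape[1])])

    names = [spec.name for spec in specs]
    idx = fits.gene_ids
    return ContrastResult(
        estimate=pd.DataFrame(est, index=idx, columns=names),
        t=pd.DataFrame(t, index=idx, columns=names),
        p=pd.DataFrame(p, index=idx, columns=names),
        adj_p=pd.DataFrame(adj, index=idx, columns=names),
    )
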