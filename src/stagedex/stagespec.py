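"""Stage-string classification, stage assignment, and the significance cascade.

Each gene gets a four-bit string over stages I-IV: bit k is 1 iff the
gene's |lfc| versus control in stage k exceeds the threshold (default 2,
i.e. a 4-fold change). Genes with string '0000' are eliminated; every
other gene is assigned to the stage with the highest |lfc|. A gene is
called stage-specific only if it passes a four-pronged significance
cascade: the BH-adjusted p of its control contrast must be < 0.001, and
the raw p of each of the three inter-stage contrasts involving its stage
must be < 0.05. Stage-IV calls may additionally be pruned to genes with a
monotone group-mean trajectory, ranked by genome-wide model significance,
to guard against the low power of a very small stage-IV group.
"""

from __future__ import annotations

import logging
from itertools import product

import numpy as np
import pandas as pd

from .contrasts import ContrastResult
from .groups import STAGES
from .linmod import LinModError

logger = logging.getLogger(__name__)

LFC_THRESHOLD = 2.0
P_CONTROL = 0.001
P_INTER = 0.05

ALL_BIT_STRINGS = ["".join(bits) for bits in product("01", repeat=len(STAGES))]


def stage_string(lfcs, threshold: float = LFC_THRESHOLD) -> str:
    """Four-character bit string: '1' where |lfc| strictly exceeds threshold."""
    lfc = np.asarray(lfcs, dtype=float)
    if lfc.shape != (len(STAGES),):
        raise LinModError(f"expected {len(STAGES)} lfc values, got shape {lfc.shape}")
    if not np.all(np.isfinite(lfc)):
        raise LinModError(f"non-finite lfc values: {lfc}")
    return "".join("1" if abs(v) > threshold else "0" for v in lfc)


def assign_stage(lfcs, threshold: float = LFC_THRESHOLD) -> tuple[str | None, bool]:
    """Assign the stage of maximal |lfc|, or None for an all-'0' string.

    Returns (stage, tie_flag). Ties on |lfc| are broken toward the
    earliest stage and flagged.
    """
    bits = stage_string(lfcs, threshold)
    if bits == "0000":
        return None, False
    abs_lfc = np.abs(np.asarray(lfcs, dtype=float))
    k = int(np.argmax(abs_lfc))
    tie = bool(np.sum(abs_lfc == abs_lfc[k]) > 1)
    if tie:
        logger.info("tie in |lfc| %s broken toward stage %s", abs_lfc, STAGES[k])
    return STAGES[k], tie


def build_stage_calls(
    control_results: ContrastResult, threshold: float = LFC_THRESHOLD
) -> pd.DataFrame:
    """Stage strings and argmax-stage assignment for every gene.

    ``control_results`` must hold the four stage-vs-control contrasts in
    stage order. Returns one row per gene with the stagewise lfc vector,
    bit string, assigned stage ('' when eliminated) and tie flag.
    """
    lfc = control_results.estimate.to_numpy()
    rows = []
    for g in range(lfc.shape[0]):
        stage, tie = assign_stage(lfc[g], threshold)
        rows.append((stage_string(lfc[g], threshold), stage or "", tie))
    out = pd.DataFrame(rows, columns=["bits", "stage", "tie"], index=control_results.estimate.index)
    for k, s in enumerate(STAGES):
        out[f"lfc_{s}"] = lfc[:, k]
    return out


def _inter_contrast_name(names: list[str], a: str, b: str) -> str:
    for cand in (f"{a}_vs_{b}", f"{b}_vs_{a}"):
        if cand in names:
            return cand
    raise LinModError(f"missing inter-stage contrast between {a} and {b}")


def significance_cascade(
    calls: pd.DataFrame,
    control_results: ContrastResult,
    inter_results: ContrastResult,
    p_control: float = P_CONTROL,
    p_inter: float = P_INTER,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the four-pronged significance filter to stage-assigned genes.

    Prong (i): BH-adjusted p of the assigned stage's control contrast
    < ``p_control``. Prongs (ii)-(iv): raw p of each inter-stage contrast
    involving the assigned stage < ``p_inter``. Returns the calls frame
    augmented with per-prong pass flags, the tested p-values and the final
    ``stage_specific`` flag, plus a survivor-count table recording how
    many candidates remain after each criterion, per stage.
    """
    calls = calls.copy()
    names = inter_results.names
    control_cols = {s: f"{s}_vs_control" for s in STAGES}

    calls["p_control_adj"] = np.nan
    calls["pass_control"] = False
    for j, s in enumerate(STAGES):
        others = [o for o in STAGES if o != s]
        for i, o in enumerate(others):
            calls.loc[calls["stage"] == s, f"inter_other_{i + 1}"] = o
    for i in range(3):
        calls[f"p_inter_{i + 1}"] = np.nan
        calls[f"pass_inter_{i + 1}"] = False

    assigned = calls.index[calls["stage"] != ""]
    for gene in assigned:
        s = calls.at[gene, "stage"]
        adj = control_results.adj_p.at[gene, control_cols[s]]
        calls.at[gene, "p_control_adj"] = adj
        calls.at[gene, "pass_control"] = bool(adj < p_control)
        for i, o in enumerate([o for o in STAGES if o != s]):
            name = _inter_contrast_name(names, s, o)
            p = inter_results.p.at[gene, name]
            calls.at[gene, f"p_inter_{i + 1}"] = p
            calls.at[gene, f"pass_inter_{i + 1}"] = bool(p < p_inter)

    pass_cols = ["pass_control", "pass_inter_1", "pass_inter_2", "pass_inter_3"]
    calls["stage_specific"] = (calls["stage"] != "") & calls[pass_cols].all(axis=1)

    counts = {}
    for s in STAGES:
        sub = calls[calls["stage"] == s]
        exclusive_bits = "".join("1" if t == s else "0" for t in STAGES)
        row = {
            "assigned": len(sub),
            "exclusive": int((sub["bits"] == exclusive_bits).sum()),
        }
        surviving = sub
        for step, col in zip(
            ("after_control", "after_inter_1", "after_inter_2", "after_inter_3"), pass_cols
        ):
            surviving = surviving[surviving[col]]
            row[step] = len(surviving)
        row["stage_specific"] = int(sub["stage_specific"].sum())
        counts[s] = row
    survivors = pd.DataFrame(counts).T
    survivors.index.name = "stage"
    return calls, survivors


def partition_report(calls: pd.DataFrame) -> pd.Series:
    """Gene counts per four-bit string over all 16 possible strings."""
    counts = calls["bits"].value_counts()
    out = pd.Series({b: int(counts.get(b, 0)) for b in ALL_BIT_STRINGS}, name="n_genes")
    out.index.name = "bits"
    return out


def prune_stage4(
    calls: pd.DataFrame,
    monotonic_direction: pd.Series,
    model_adj_p: pd.Series,
    top_n: int = 10,
) -> pd.Index:
    """Prune stage-IV specific genes to the top ``top_n`` smooth-trend genes.

    Keeps stage-IV stage-specific genes whose group-mean trajectory is
    strictly monotone (direction UP or DOWN), ranks them by the
    genome-wide linear model's adjusted p-value, and returns the best
    ``top_n`` gene ids. With fewer than ``top_n`` qualifying genes, all
    are returned.
    """
    if top_n < 1:
        raise LinModError(f"top_n must be >= 1, got {top_n}")
    stage4 = calls.index[(calls["stage"] == "IV") & calls["stage_specific"]]
    monotone = [g for g in stage4 if monotonic_direction.get(g, "none") in ("UP", "DOWN")]
    ranked = model_adj_p.loc[monotone].sort_values(kind="stable")
    return ranked.index[:top_n]
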