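"""Synthetic stagewise expression data with planted ground truth.

The generator emulates the statistical structure the analysis assumes: a
log2-scale expression matrix over controls and four cancer stages, with
per-gene residual variances drawn from a scaled-inverse-chi-square prior
(the hierarchical model underlying variance moderation) and planted gene
classes:

* ``null`` — no group effect anywhere;
* ``stage_I`` .. ``stage_IV`` — a single dominant log fold-change of
  magnitude ``effect_lfc`` (random sign) in the named stage, zero in the
  others;
* ``monotonic_up`` / ``monotonic_down`` — strictly ordered group means
  with an equal per-stage step of ``monotone_step`` log2 units (default a
  doubling per stage transition, so the planted trend is strong enough to
  survive the genome-wide sigma >= 1 variability filter);
* ``global_de`` — the same ``effect_lfc`` offset in all four stages, a
  confounder for stage-specificity calls.

Data are written out in the Firebrowse-style TSV layout the ingest module
reads, so the whole pipeline is exercisable end to end without any
download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .groups import CONTROL, GROUPS, STAGES
from .ingest import ExpressionDataset

GENE_CLASSES: tuple[str, ...] = (
    "null",
    "stage_I",
    "stage_II",
    "stage_III",
    "stage_IV",
    "monotonic_up",
    "monotonic_down",
    "global_de",
)

#: Default class mix: planted classes are a small minority, as in a real
#: genome-wide scan where most genes carry no stage-specific signal.
DEFAULT_CLASS_FRACTIONS: dict[str, float] = {
    "null": 0.80,
    "stage_I": 0.02,
    "stage_II": 0.02,
    "stage_III": 0.02,
    "stage_IV": 0.02,
    "monotonic_up": 0.04,
    "monotonic_down": 0.04,
    "global_de": 0.04,
}


class SimConfigError(ValueError):
    """Raised for an invalid simulation configuration."""


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults mimic the imbalance of the real cohort the pipeline targets:
    ~50 normal controls, stage sizes dominated by stage I, and a very
    small stage IV group. ``prior_df``/``prior_var`` parameterize the
    scaled-inverse-chi-square variance prior: gene variance is drawn as
    ``prior_var * prior_df / ChiSquare(prior_df)``.
    """

    n_genes: int = 2000
    group_sizes: tuple[int, int, int, int, int] = (50, 170, 85, 85, 6)
    baseline_mean_range: tuple[float, float] = (3.0, 12.0)
    prior_df: float = 4.0
    prior_var: float = 0.05
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    effect_lfc: float = 3.0
    monotone_step: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise SimConfigError("n_genes must be >= 1")
        if len(self.group_sizes) != len(GROUPS):
            raise SimConfigError(f"group_sizes needs {len(GROUPS)} entries (control, I..IV)")
        if any(n < 2 for n in self.group_sizes):
            raise SimConfigError("every group needs at least 2 samples")
        if self.prior_df <= 0 or self.prior_var <= 0:
            raise SimConfigError("prior_df and prior_var must be positive")
        unknown = set(self.class_fractions) - set(GENE_CLASSES)
        if unknown:
            raise SimConfigError(f"unknown gene classes: {sorted(unknown)}")
        total = float(sum(self.class_fractions.values()))
        if not np.isclose(total, 1.0, atol=1e-8):
            raise SimConfigError(f"class_fractions must sum to 1, got {total}")
        if any(f < 0 for f in self.class_fractions.values()):
            raise SimConfigError("class_fractions must be non-negative")
        lo, hi = self.baseline_mean_range
        if not lo < hi:
            raise SimConfigError("baseline_mean_range must be an increasing interval")


@dataclass
class SyntheticTruth:
    """Planted per-gene ground truth.

    ``table`` has one row per gene with columns: ``gene_class``, ``stage``
    (the stage of specificity, empty unless stage-specific),
    ``offset_I`` .. ``offset_IV`` (true log2 group-mean offsets vs
    control), ``baseline`` and ``variance``.
    """

    table: pd.DataFrame

    def genes_of_class(self, gene_class: str) -> pd.Index:
        return self.table.index[self.table["gene_class"] == gene_class]

    @property
    def offsets(self) -> pd.DataFrame:
        return self.table[[f"offset_{s}" for s in STAGES]]


def _class_counts(fractions: Mapping[str, float], n_genes: int) -> dict[str, int]:
    """Deterministic largest-remainder apportionment of genes to classes."""
    raw = {c: fractions.get(c, 0.0) * n_genes for c in GENE_CLASSES}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n_genes - sum(counts.values())
    remainders = sorted(raw, key=lambda c: raw[c] - counts[c], reverse=True)
    for c in remainders[:short]:
        counts[c] += 1
    return counts


def _stage_offsets(config: SimConfig, classes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    offsets = np.zeros((len(classes), len(STAGES)))
    signs = rng.choice([-1.0, 1.0], size=len(classes))
    for i, cls in enumerate(classes):
        if cls.startswith("stage_"):
            k = STAGES.index(cls.removeprefix("stage_"))
            offsets[i, k] = signs[i] * config.effect_lfc
        elif cls == "monotonic_up":
            offsets[i] = config.monotone_step * np.arange(1, 5)
        elif cls == "monotonic_down":
            offsets[i] = -config.monotone_step * np.arange(1, 5)
        elif cls == "global_de":
            offsets[i] = signs[i] * config.effect_lfc
    return offsets


def _barcodes(config: SimConfig) -> tuple[list[str], list[str]]:
    """Aliquot barcodes and group labels: 10-char patient id + 2-char type code."""
    barcodes, labels = [], []
    patient = 0
    for group, size in zip(GROUPS, config.group_sizes):
        code = "11" if group == CONTROL else "01"
        for _ in range(size):
            barcodes.append(f"TCGA-{patient:05d}{code}A")
            labels.append(group)
            patient += 1
    return barcodes, labels


def generate_dataset(config: SimConfig) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Simulate a stagewise log2 expression matrix with planted truth.

    Entry (g, s) = baseline_g + offset_{g, group(s)} + Normal(0, var_g),
    with var_g ~ prior_var * prior_df / ChiSquare(prior_df). The same
    config (including seed) reproduces the matrix bit for bit.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    counts = _class_counts(config.class_fractions, config.n_genes)
    classes = np.concatenate([np.repeat(c, n) for c, n in counts.items()])
    rng.shuffle(classes)

    baseline = rng.uniform(*config.baseline_mean_range, size=config.n_genes)
    variance = config.prior_var * config.prior_df / rng.chisquare(config.prior_df, config.n_genes)
    offsets = _stage_offsets(config, classes, rng)

    barcodes, labels = _barcodes(config)
    # offsets indexed by group code: control contributes 0
    offsets_full = np.hstack([np.zeros((config.n_genes, 1)), offsets])
    group_idx = np.array([GROUPS.index(g) for g in labels])
    mean_matrix = baseline[:, None] + offsets_full[:, group_idx]
    noise = rng.normal(size=mean_matrix.shape) * np.sqrt(variance)[:, None]

    gene_ids = pd.Index([f"G{i:05d}|{i + 1}" for i in range(config.n_genes)], name="gene")
    values = pd.DataFrame(mean_matrix + noise, index=gene_ids, columns=barcodes)
    groups = pd.Series(labels, index=values.columns, dtype=object)

    truth = pd.DataFrame(
        {
            "gene_class": classes,
            "stage": [
                c.removeprefix("stage_") if c.startswith("stage_") else "" for c in classes
            ],
            **{f"offset_{s}": offsets[:, k] for k, s in enumerate(STAGES)},
            "baseline": baseline,
            "variance": variance,
        },
        index=gene_ids,
    )
    return ExpressionDataset(values, groups), SyntheticTruth(truth)


def default_stage_text(stage: str) -> str:
    return f"stage {stage.lower()}"


def write_firebrowse_style(
    dataset: ExpressionDataset,
    expression_path: str | Path,
    clinical_path: str | Path,
    stage_text: Callable[[str], str] = default_stage_text,
) -> None:
    """Write a dataset in the Firebrowse-style two-file layout.

    The expression TSV carries a "Hybridization REF" barcode header and a
    second row of data-type labels; the clinical TSV has one row per
    patient with lowercase variable names including "pathologic stage".
    ``stage_text`` renders a collapsed stage into the raw clinical string
    (override it to plant substages like "stage iiia").
    """
    expression_path, clinical_path = Path(expression_path), Path(clinical_path)
    with expression_path.open("w") as fh:
        fh.write("Hybridization REF\t" + "\t".join(map(str, dataset.sample_ids)) + "\n")
        fh.write("gene\t" + "\t".join(["normalized_count"] * dataset.n_samples) + "\n")
        dataset.values.to_csv(fh, sep="\t", header=False)

    rows = []
    seen: set[str] = set()
    for barcode, group in dataset.groups.items():
        patient = str(barcode)[:10]
        if patient in seen:
            continue
        seen.add(patient)
        stage_str = "na" if (pd.isna(group) or group == CONTROL) else stage_text(str(group))
        rows.append({"aliquot_barcode": barcode, "pathologic stage": stage_str})
    pd.DataFrame(rows).to_csv(clinical_path, sep="\t", index=False)


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    truth.table.to_csv(path, sep="\t")
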