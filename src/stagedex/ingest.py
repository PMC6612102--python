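"""Reading and preprocessing of expression + clinical tables.

The input model follows TCGA/Firebrowse conventions: a genes-by-samples
TSV of normalized log2 expression whose header row is named
"Hybridization REF" and holds aliquot barcodes, and a clinical TSV with a
"pathologic stage" field. The first 10 barcode characters identify the
patient; the following two characters are the sample-type code (01-09
tumor, 10-19 normal).

Preprocessing applies, in order: clinical merge (substages collapsed to
the parent stage, normals labelled control), a low-variance gene filter
(sample standard deviation across all samples < sigma_min removed), and
removal of tumor samples lacking stage annotation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .groups import CONTROL, GROUPS, STAGES

logger = logging.getLogger(__name__)

PATIENT_ID_LEN = 10
_SAMPLE_TYPE_RE = re.compile(r"^\d{2}$")

_STAGE_PATTERN = re.compile(r"^(?:stage\s+)?(iv|iii|ii|i)([abc]?)$")


class BarcodeError(ValueError):
    """Raised when an aliquot barcode cannot be parsed."""


class IngestConfigError(ValueError):
    """Raised for invalid preprocessing parameters."""


@dataclass
class SampleAnnotation:
    """Per-sample annotation derived from a barcode and the clinical table."""

    barcode: str
    patient_id: str
    sample_type: str  # "tumor" | "normal"
    pathologic_stage: str | None = None
    stage: str | None = None  # collapsed parent stage, I..IV


@dataclass
class ExpressionDataset:
    """A log2 expression matrix (genes x samples) with per-sample group labels.

    ``groups`` is indexed by sample barcode with values in
    {control, I, II, III, IV}; tumors whose stage is unknown carry NaN
    until :func:`drop_missing_stage` removes them.
    """

    values: pd.DataFrame
    groups: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.groups.index):
            raise ValueError("sample ids of the matrix and the group labels disagree")
        bad = set(self.groups.dropna()) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_sizes(self) -> dict[str, int]:
        counts = self.groups.value_counts()
        return {g: int(counts.get(g, 0)) for g in GROUPS}

    def subset_samples(self, keep: Iterable[str]) -> "ExpressionDataset":
        keep = list(keep)
        return ExpressionDataset(self.values[keep], self.groups.loc[keep])


def parse_barcode(barcode: str) -> SampleAnnotation:
    """Parse an aliquot barcode into patient id and tumor/normal status.

    The first 10 characters are the anonymized patient identifier and the
    following two characters are the numeric sample-type code: 01-09 are
    tumor samples, 10-19 are normal-tissue samples.
    """
    if not isinstance(barcode, str) or len(barcode) < PATIENT_ID_LEN + 2:
        raise BarcodeError(
            f"barcode {barcode!r} is too short: need at least "
            f"{PATIENT_ID_LEN + 2} characters (patient id + sample-type code)"
        )
    patient_id = barcode[:PATIENT_ID_LEN]
    code = barcode[PATIENT_ID_LEN : PATIENT_ID_LEN + 2]
    if not _SAMPLE_TYPE_RE.match(code):
        raise BarcodeError(f"barcode {barcode!r} has non-numeric sample-type code {code!r}")
    value = int(code)
    if 1 <= value <= 9:
        sample_type = "tumor"
    elif 10 <= value <= 19:
        sample_type = "normal"
    else:
        raise BarcodeError(f"barcode {barcode!r} has out-of-range sample-type code {code!r}")
    return SampleAnnotation(barcode=barcode, patient_id=patient_id, sample_type=sample_type)


def collapse_stage(raw: object) -> str | None:
    """Collapse a raw pathologic-stage string to its parent stage (I..IV).

    Substage letters (A, B, C) are dropped: "Stage IIIA" -> "III".
    Matching is case-insensitive and tolerates a missing "stage " prefix.
    Unrecognized non-empty values yield None with a logged warning.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    text = str(raw).strip().lower()
    if text in ("", "na", "nan", "[not available]", "not available"):
        return None
    m = _STAGE_PATTERN.match(text)
    if m is None:
        logger.warning("unrecognized pathologic stage %r treated as missing", raw)
        return None
    return m.group(1).upper()


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a Firebrowse-style expression TSV into a genes-x-samples frame.

    The header row is "Hybridization REF" followed by barcodes. An optional
    second header row of per-column data-type labels (e.g. every cell
    "normalized_count") is detected and skipped.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if len(df) > 0:
        first = df.iloc[0]
        numeric = pd.to_numeric(first, errors="coerce")
        if numeric.isna().all():  # second header row of type labels
            df = df.iloc[1:]
    return df.astype(float)


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical TSV (lowercase variable names, one row per patient)."""
    return pd.read_csv(path, sep="\t", dtype=str)


def _clinical_stage_by_patient(clinical: pd.DataFrame) -> dict[str, object]:
    if "pathologic stage" not in clinical.columns:
        raise IngestConfigError('clinical table lacks a "pathologic stage" column')
    barcode_col = next(
        (c for c in clinical.columns if "barcode" in c.lower()), clinical.columns[0]
    )
    out: dict[str, object] = {}
    for code, stage in zip(clinical[barcode_col], clinical["pathologic stage"]):
        out[str(code)[:PATIENT_ID_LEN]] = stage
    return out


def merge_clinical(
    expression: pd.DataFrame | str | Path, clinical: pd.DataFrame | str | Path
) -> ExpressionDataset:
    """Annotate every expression column with its sample group.

    Normal-coded samples become controls regardless of the clinical stage
    field; tumor samples take the collapsed stage of their patient's
    clinical row. A tumor sample with no clinical row (or an unusable
    stage value) is kept with a missing group label so the downstream
    missing-stage filter can account for it.
    """
    if not isinstance(expression, pd.DataFrame):
        expression = read_expression(expression)
    if not isinstance(clinical, pd.DataFrame):
        clinical = read_clinical(clinical)
    stage_of_patient = _clinical_stage_by_patient(clinical)

    labels: list[object] = []
    for barcode in expression.columns:
        ann = parse_barcode(str(barcode))
        if ann.sample_type == "normal":
            labels.append(CONTROL)
            continue
        raw = stage_of_patient.get(ann.patient_id)
        if raw is None and ann.patient_id not in stage_of_patient:
            logger.warning("tumor sample %s has no clinical row; stage missing", barcode)
        stage = collapse_stage(raw)
        labels.append(stage if stage in STAGES else np.nan)
    groups = pd.Series(labels, index=expression.columns, dtype=object)
    return ExpressionDataset(expression, groups)


def filter_low_variance(dataset: ExpressionDataset, sigma_min: float = 1.0) -> ExpressionDataset:
    """Drop genes whose standard deviation across ALL samples is < sigma_min.

    The inequality is strict: a gene with sigma exactly equal to sigma_min
    is retained. Sigma is the sample standard deviation (denominator n-1)
    on the log2 scale, computed over every sample present, controls
    included. Gene order is preserved.
    """
    if sigma_min <= 0:
        raise IngestConfigError(f"sigma_min must be positive, got {sigma_min}")
    if dataset.n_samples < 2:
        raise IngestConfigError("need at least 2 samples to estimate sigma")
    sigma = dataset.values.std(axis=1, ddof=1)
    keep = sigma >= sigma_min
    return ExpressionDataset(dataset.values.loc[keep], dataset.groups)


def drop_missing_stage(dataset: ExpressionDataset) -> ExpressionDataset:
    """Remove tumor samples with missing stage annotation; controls stay."""
    keep = [
        s
        for s in dataset.sample_ids
        if dataset.groups[s] == CONTROL or dataset.groups[s] in STAGES
    ]
    return dataset.subset_samples(keep)


def preprocess(
    expression: pd.DataFrame | str | Path,
    clinical: pd.DataFrame | str | Path,
    sigma_min: float = 1.0,
) -> ExpressionDataset:
    """Full preprocessing chain: merge -> variance filter -> drop NA stage."""
    ds = merge_clinical(expression, clinical)
    ds = filter_low_variance(ds, sigma_min=sigma_min)
    return drop_missing_stage(ds)


def write_dataset(dataset: ExpressionDataset, path: str | Path) -> None:
    """Write the merged annotated dataset as TSV.

    Layout mirrors the input style: a "Hybridization REF" header row of
    barcodes, then a "group" row of sample labels, then one row per gene.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("Hybridization REF\t" + "\t".join(map(str, dataset.sample_ids)) + "\n")
        fh.write(
            "group\t"
            + "\t".join("" if pd.isna(g) else str(g) for g in dataset.groups)
            + "\n"
        )
        dataset.values.to_csv(fh, sep="\t", header=False)


def read_dataset(path: str | Path) -> ExpressionDataset:
    """Read a dataset written by :func:`write_dataset`."""
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        group_row = fh.readline().rstrip("\n").split("\t")[1:]
        values = pd.read_csv(fh, sep="\t", header=None, index_col=0)
    values.columns = header
    values.index.name = "gene"
    groups = pd.Series(
        [g if g else np.nan for g in group_row], index=header, dtype=object
    )
    return ExpressionDataset(values, groups)
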