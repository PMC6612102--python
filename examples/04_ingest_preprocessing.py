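"""Ingesting Firebrowse-style expression and clinical files.

Writes a small simulated cohort in the two-file TCGA/Firebrowse layout
(expression TSV with a 'Hybridization REF' barcode header; clinical TSV
with a 'pathologic stage' column, substages included), then runs the
preprocessing chain: barcode parsing, clinical merge with substage
collapsing, the sigma >= 1 gene filter, and missing-stage removal.
"""

import tempfile
from pathlib import Path

import stagedex as sx

cfg = sx.SimConfig(n_genes=400, group_sizes=(10, 20, 15, 15, 5), seed=3)
dataset, _ = sx.generate_dataset(cfg)

with tempfile.TemporaryDirectory() as tmp:
    exp, clin = Path(tmp) / "expression.tsv", Path(tmp) / "clinical.tsv"
    # plant substages to show they collapse to the parent stage
    sx.write_firebrowse_style(dataset, exp, clin,
                              stage_text=lambda s: f"stage {s.lower()}a")

    merged = sx.merge_clinical(exp, clin)
    filtered = sx.filter_low_variance(merged, sigma_min=1.0)
    final = sx.drop_missing_stage(filtered)

print(f"merged: {merged.n_genes} genes x {merged.n_samples} samples")
print(f"after sigma >= 1 filter: {filtered.n_genes} genes "
      f"({merged.n_genes - filtered.n_genes} near-constant genes removed)")
print(f"after missing-stage removal: {final.n_samples} samples")
print("group sizes:", final.group_sizes())

ann = sx.parse_barcode(final.sample_ids[0])
print(f"\nexample barcode {ann.barcode}: patient {ann.patient_id}, {ann.sample_type}")
# Substaged clinical entries like 'stage iiia' were collapsed to III.
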