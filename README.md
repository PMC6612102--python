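# stagedex

Stage-specific differential expression analysis of cancer transcriptomes.

Bulk RNA-Seq studies usually compare tumors against controls as a single
class, which discards the information of *when* along disease progression
a gene's expression changes. `stagedex` implements a stagewise protocol
developed for hepatocellular carcinoma: per-gene linear models over
normal controls and the four AJCC/TNM stages, empirical-Bayes moderated
contrast statistics, a four-bit stage-string classification with an
argmax-|lfc| stage assignment, a four-pronged significance cascade, and a
strict monotonic-trend screen. It is aimed at computational biologists
dissecting stage-resolved expression from TCGA/Firebrowse-style matrices,
and ships a synthetic-cohort generator with planted ground truth so the
whole pipeline is testable without any download.

## The model

For each gene with log2 expression y, three designs are fitted:

* **Baseline** (genome-wide scan): `y = α + β₁x₁ + β₂x₂ + β₃x₃ + β₄x₄`,
  where `xₖ` indicates stage k; α is the control mean and βₖ the stage-k
  log fold-change (lfc) versus control. Optionally precision-weighted by
  a LOWESS mean-variance trend (voom-style).
* **Cell means** (contrasts): `y = β₀x₀ + … + β₄x₄` with one indicator
  per group; contrasts `cᵀβ` give the four stage-vs-control and six
  inter-stage comparisons.
* **Numeric stage** (trend): `y = aX + b` with X = 0…4 for
  control…stage IV.

Residual variances are moderated by empirical Bayes: per-gene s² (df d)
is shrunk toward a prior s₀² (df d₀) estimated across genes by the
method of moments on log variances, giving the posterior
`s̃² = (d₀s₀² + d·s²)/(d₀ + d)` and t statistics on d₀ + d df. P-values
are FDR-adjusted by Benjamini–Hochberg per statistic family.

A gene is called **stage-specific** when (1) some stage has |lfc| > 2
(4-fold) versus control — recorded as a four-bit string over stages
I–IV — with the gene assigned to the stage of maximal |lfc|; (2) the
adjusted p of that stage's control contrast is < 0.001; and (3) the raw
p of each inter-stage contrast involving that stage is < 0.05. A gene is
**monotone** when its five group means are strictly ordered; monotone
genes with adjusted numeric-model slope p < 0.05 form the significant
monotone set. Stage-IV calls can be pruned to the top-N smooth-trend
genes to guard against the small stage-IV group.

## Worked example

```python
import stagedex as sx

cfg = sx.SimConfig(n_genes=2000, seed=7, effect_lfc=3.0)   # default cohort: 50 controls, 170/85/85/6 tumors
result = sx.run_pipeline(sim_config=cfg)
print(result.manifest["n_stage_specific"])
```

prints

```
{'I': 40, 'II': 40, 'III': 40, 'IV': 159}
```

The 2000 simulated genes contain 40 planted stage-specific genes per
stage; the cascade recovers stages I–III exactly. The 159 stage-IV calls
are dominated by the planted monotone genes, whose maximal |lfc| falls
in stage IV by construction — precisely the situation the stage-IV
pruning addresses: `result.stage4_pruned` keeps the 10 most significant
smooth-trend genes. The monotonic screen
(`result.monotonic_table`) reports 167 significant strictly monotone
genes (82 up, 85 down) with slopes close to the planted ±1 log2 per
stage. The `examples/` directory walks through each capability
(`python examples/01_stage_specific_screen.py`, …); a thin CLI does the
same from the shell (`stagedex simulate`, `stagedex run --simulate 7`).

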