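# enhdyn

Enhancer dynamics and MLL3/4-dependency analysis for CUT&RUN/CUT&TAG-style
chromatin data, with a ground-truth synthetic-genome generator.

## The problem

During a cell-state transition — here the naive → formative transition of
pluripotent stem cells — thousands of enhancers gain or lose the histone marks
H3K4me1 (deposited by the MLL3/4 methyltransferases) and H3K27ac (deposited by
P300/CBP).  The textbook model chains these events to transcription:
MLL3/4 → H3K4me1 → P300/CBP → H3K27ac → target-gene activation.  Testing that
model requires classifying every enhancer along several axes and then asking
whether chromatin changes and expression changes at nearby genes actually
move together.  `enhdyn` is that pipeline, for anyone analysing sparse
chromatin profiling tracks across a two-condition × two-genotype design:

- **peakcall** — SEACR-style sparse-enrichment peak calling: signal blocks
  (maximal runs of positive coverage) thresholded on total signal
  AUC > the (1−α) quantile of an IgG control's block AUCs (α = 0.05);
- **diffquant** — union peaks, CPM filtering, TMM normalization, a
  negative-binomial Wald test with trended moderated dispersions (plus a
  label-permutation fallback), Benjamini–Hochberg FDR;
- **classify** — the category logic: dynamics (*naive*/*formative* if
  FDR < 0.05 and |log2FC| > 1, *shared* if FDR > 0.1 and |log2FC| < 0.7),
  MLL3/4 dependency (*dependent* if DKO/WT log2FC < −1 in either state,
  *independent* if > −0.7 in both), Promoter/Distal/Other feature classes,
  75%-of-ATAC-peak accessibility intersection, joint H3K4me1 × H3K27ac
  categories, and gene dependency classes;
- **linkage** — nearest-TSS enhancer→gene assignment, paired Wilcoxon
  category expression tests, a Monte-Carlo Mann–Whitney permutation control
  against random gene sets, enhancer-burden regression and %-loss binning;
- **chromstates** — 16-state segmentation of binarized
  H3K4me1/H3K27ac × WT/DKO tracks (direct combinatorial encoding or a
  Bernoulli-emission HMM trained by Baum–Welch), with per-state expression
  tests;
- **synthetic** — a miniature genome (2 × 5 Mb, 2000 enhancers, 1000 genes)
  with every label planted, negative-binomial counts, Poisson coverage tracks,
  and a coupling dial κ ∈ [0, 1] that sets how much of a gene's DKO/WT fold
  change is explained by the acetylation change at its enhancers.  κ = 0
  plants *decoupling*: chromatin changes with no transcriptional consequence.

`docs/methods.md` documents every rule, default and modelling choice.

## Worked example

Simulate the default genome in the decoupled regime (κ = 0), recover the
planted labels, and test chromatin-vs-expression coupling:

```python
import pandas as pd
from enhdyn.synthetic import (SimConfig, generate_truth, simulate_counts,
                              simulate_expression)
from enhdyn.workflows import mark_category_table, decoupling_analysis

config = SimConfig(seed=1, kappa=0.0)          # decoupled regime
truth, genes = generate_truth(config)
k4 = simulate_counts(truth, config, "H3K4me1")
table = mark_category_table(k4)                # three differential tests + cutoffs

print(pd.crosstab(truth["dynamics"], table["dynamics"]))
print(pd.crosstab(truth["dep_H3K4me1"], table["dependency"]))
```

```
dynamics   formative  naive  shared  unclassified
dynamics
formative        480      0       0             0
naive              0    518       0             0
shared             0      0     946            56

dependency   dependent  independent
dep_H3K4me1
dependent          590            0
independent          0         1410
```

All 480 planted formative and 518 planted naive enhancers are recovered; 56 of
1002 shared enhancers fall into the buffer between the "changing" and
"confidently unchanged" rules and stay unclassified; dependency calls are
error-free at the planted −2 effect.  Now the headline question — do the
chromatin losses couple to transcription?

```python
k27 = simulate_counts(truth, config, "H3K27ac")
expr = simulate_expression(truth, genes, config)
dec = decoupling_analysis(truth, genes, k27, expr)
```

```
H3K27ac loss at dependent formative enhancers: p = 3.87e-17 (median log2FC -1.87, n = 94)
nearby-gene expression change:                 p = 0.73 (median diff -0.015, n = 85 genes)
```

The 94 MLL3/4-dependent formative enhancers lose acetylation massively in the
knockout, yet the 85 genes nearest to them show no expression change — the
pipeline detects the planted decoupling.  Re-running with `kappa=1.0` makes
both p-values significant.

The same flow is available from the shell:

```sh
enhdyn simulate --seed 1 --outdir data/
enhdyn callpeaks --target data/H3K4me1_WT_naive.bedgraph \
                 --control data/IgG_WT_naive.bedgraph -o peaks.bed
enhdyn diff --counts data/counts_H3K4me1.tsv --meta data/samples_H3K4me1.tsv \
            --contrast condition:formative-naive --select genotype=WT -o wt.tsv
enhdyn states --tracks data/H3K4me1_WT_formative.bedgraph \
              data/H3K4me1_DKO_formative.bedgraph \
              data/H3K27ac_WT_formative.bedgraph \
              data/H3K27ac_DKO_formative.bedgraph --bin 1000 -o segments.bed
enhdyn report --seed 1 --outdir report/   # full pipeline + tables + figures
```

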