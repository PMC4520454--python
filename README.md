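# metx

An integrative screen for **poised genes** in a two-platform time course:
genes whose expression is induced at the earliest timepoint of a cellular
state transition while their locus DNA methylation is still (nearly)
unchanged, with demethylation following later.

The motivating system is a germ-cell-cancer reprogramming model: a
seminoma-like cell line transitions in vivo to an embryonal-carcinoma (EC)-
like state over weeks 0/1/2/4/6, assayed in parallel on a 450K-style
methylation array (beta values β ∈ [0, 1]) and an expression intensity
array, alongside an EC-like reference line. `metx` implements the full
analysis stack for that design: methylome profiling, differential
statistics, the methylation–expression correlation funnel, temporal
classification, sample clustering, and a synthetic-data generator with
planted ground truth so every stage is testable without array downloads.

## The screen

For each gene *g* with locus methylation summary m_g (mean β over its
probes) and expression x_g (log2 intensity) across the transition samples:

1. **Inverse-correlation set** — Pearson r(m_g, x_g) with a two-sided p
   from the t distribution (n − 2 df), Benjamini–Hochberg adjusted across
   genes; keep genes with r < 0 and q < 0.05.
2. **5mC/Gex group** — of those, keep genes whose expression actually
   moves: max over timepoints |log2FC vs the week-0 baseline| ≥ log2 1.5.
3. **Temporal classes** — within the group, a gene is *poised_early* iff
   |log2FC(week 1)| ≥ log2 1.5 **and** |Δβ(week 1)| < 0.1 (induced while
   methylation has moved only marginally); all other group members are
   *late_concordant*. The classes partition the group, so
   |group| = |poised| + |late| by construction.

Supporting stages: β→M conversion (M = log2 β/(1 − β)) for probe-level
Welch t-tests with BH correction; quantile normalization for expression;
mean-β profiles over gene-region classes (TSS1500, TSS200, 5′UTR, 1st exon,
body, 3′UTR) split by CpG-island vs open-sea context; per-chromosome
methylation bin censuses (0–40 / 40–80 / >80%); violin-style distribution
summaries; and unsupervised hierarchical clustering of samples with Newick
export.

## Worked example

```python
from metx.simulate import SimConfig, generate_dataset
from metx.pipeline import run_screen

manifest, betas, expr, sheet, truth = generate_dataset(SimConfig(seed=1))
res = run_screen(manifest, betas, expr, sheet)
print("inverse:", len(res["inverse_set"]), "group:", len(res["group_set"]),
      "poised:", len(res["poised_set"]), "late:", len(res["late_set"]))

true_poised = set(truth.index[truth.planted_class == "poised_early"])
called = set(res["poised_set"].members)
tp = len(called & true_poised)
print("sensitivity:", tp / len(true_poised), "precision:", tp / len(called))
```

prints

```
inverse: 509 group: 500 poised: 100 late: 400
sensitivity: 1.0 precision: 1.0
```

The default simulation plants 2000 genes (5% poised, 10% late-concordant,
10% silenced, 75% null) over 5 timepoints × 3 replicates plus an EC-like
reference. Of the 500 planted non-null genes, 509 genes pass the inverse-
correlation screen (500 true plus a handful of null false positives, as
expected at q < 0.05), the fold-change gate trims the set to 500, and the
temporal classifier recovers all 100 planted poised genes with no false
calls at these effect sizes (1.5 log2 units expression, 0.3 β shift).

The same pipeline runs from the shell:

```sh
metx simulate --out data/ --seed 1
metx run-all --betas data/betas.tsv --expr data/expression.tsv \
  --manifest data/manifest.tsv --samples data/samples.tsv --out results/
```

writing per-probe and per-gene statistics (TSV), gene sets (GMT),
dendrograms (Newick) and a JSON run manifest with input/output checksums.

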