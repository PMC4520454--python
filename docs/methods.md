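# Methods

## Data model

Two matched platforms over one sample sheet: a probes × samples methylation
matrix of beta values (β, fraction methylated signal, in [0, 1]) and a
genes × samples expression matrix of log2 intensities. Probes map to genes
through a 450K-style manifest (probe id, chromosome, 1-based position, gene
symbol, gene-region class ∈ {TSS1500, TSS200, 5UTR, 1stExon, Body, 3UTR},
island relation ∈ {Island, Shore, Shelf, OpenSea}). Multi-gene probe
annotations are exploded to one row per (probe, gene, region); Shore/Shelf
probes are accepted on input but excluded from the two-context
(Island vs OpenSea) stratification, which contrasts CpG-island-associated
methylation with the open sea only. Samples carry cell line, environment
(in_vitro/in_vivo), week and a free group label; week 0 is the parental
baseline, so an in vivo sample at week 0 is rejected.

The pipeline accepts already-normalized betas. Array-level methylation
normalization (color-balance and probe-chemistry corrections) operates on
raw channel intensities, which a beta matrix no longer contains, so it is
out of scope here. Expression is quantile normalized; downstream statistics
run on log2 intensities.

## Statistics

**β ↔ M.** M = log2(β′/(1−β′)) with β′ clipped into [ε, 1−ε], ε = 1e-6,
so boundary betas stay finite without materially moving interior values.
Probe-level tests run on M (closer to homoscedastic); effect sizes (Δβ) and
all descriptive profiles are reported on the interpretable β scale.

**Differential methylation.** Welch (unequal-variance) two-sided t-test per
probe with Welch–Satterthwaite degrees of freedom; BH step-up adjustment
across probes. Degenerate convention: both groups constant and equal →
(t, p) = (0, 1); both constant and different → (±∞, 0). Probes missing in
more than half of either group's samples are dropped from the test. The
"differentially methylated" probe universe for the descriptive profiles is
q < 0.05 and |Δβ| ≥ 0.2 (both configurable; no single convention fixes
them). Note triplicates have limited per-probe power at these gates — the
probe universe drives descriptive profiles, not the gene screen.

**Quantile normalization.** Reference distribution = row means of the
column-sorted matrix; each column's values are replaced by the reference at
their within-column rank; ties receive the mean of the reference values at
the tied ranks. Requires a complete matrix; the documented pre-step for
missing values is row-median imputation. Idempotent, and exactly
multiset-identical across columns in the tie-free case.

**Correlation screen.** Gene-level methylation = unweighted mean β over all
mapped probes (region-restricted variants, e.g. promoter-only, are an
option; the all-probe default makes no assumption about which region drives
regulation). Pearson r between the gene's methylation and expression across
the transition-series samples (baseline + all in vivo timepoints of the
transitioning line; the reference line is excluded by default and
includable by flag), p from t = r√((n−2)/(1−r²)), BH across genes. Genes
with zero variance on either side are excluded from the screen rather than
recorded as r = 0 — a flat profile is not evidence. Gates: inverse set
r < 0, q < 0.05; group gate max |log2FC| ≥ log2 1.5 ≈ 0.585 (the
conventional 1.5-fold microarray gate); poised gate |Δβ(week 1)| < 0.1
operationalizes "methylation still essentially unchanged". The funnel
containment (poised ⊆ group ⊆ inverse ⊆ tested) and the exclusive-
exhaustive split of the group are asserted on every run.

**Clustering.** Samples are clustered agglomeratively on the top-5000 most
variable features (configurable to all): expression with 1 − Pearson
distance, methylation with Euclidean distance over betas, average linkage
by default — the common microarray conventions; no published convention is
being matched. Flat partitions are produced by cutting the tree at the
height giving k clusters. Dendrograms serialize to Newick with branch
lengths equal to merge-height differences.

## Synthetic-data generator

The generator emulates the two-platform transition time course: 2000 genes
by default, weeks (0, 1, 2, 4, 6) × 3 replicates on both platforms, plus 3
replicates of an EC-like reference line frozen at the endpoint state.
Replication is explicit (real xenograft series often run single arrays per
timepoint, which cannot support per-probe tests). Planted classes and their
trajectories, with fc_effect = 1.5 log2 units and delta_beta_effect = 0.3:

| class (default fraction) | expression log2FC | methylation Δβ |
|---|---|---|
| poised_early (5%) | +fc at week 1, rising linearly in time to +2·fc at week 6 | 0 at week 1, −Δβ from week 2 |
| late_concordant (10%) | +fc from week 4 | −Δβ from week 4 |
| silenced_down (10%) | −fc from week 2 | +Δβ from week 2 |
| null (75%) | 0 | 0 |

The poised ramp (continued induction after the initial jump) mirrors the
biology the class models — rapid induction, then further increase as the
locus demethylates — and it is what makes the class identifiable: with a
flat expression step at week 1 against a methylation step at week 2, the
population correlation is bounded near |r| ≈ 0.6 regardless of noise, too
weak for a q < 0.05 screen at n = 15.

Non-null class counts are exact rounded fractions (null absorbs the
remainder); class labels are assigned by seeded permutation. Baseline
methylation is drawn high (0.55–0.80) for demethylating classes, low
(0.15–0.40) for the silenced class, and uniform (0.1–0.9) for nulls; probe
means get per-probe N(0, 0.04) offsets, clipped to (0.02, 0.98). Noise:
Beta(μ·φ, (1−μ)·φ) on betas with precision φ = 100 (per-sample sd ≈ 0.05
at mid-methylation, typical of array replicates), Gaussian σ = 0.25 on log2
expression. Expression baselines are N(8, 1.5), the usual log2 intensity
range. Everything is drawn from one seeded generator in fixed order, so a
config reproduces its dataset bit-identically.

Not emulated: probe cross-hybridization, SNP-overlapping probes,
batch/chip effects, copy-number artifacts, and probe-type chemistry
differences. Passing recovery tests therefore demonstrates the screen's
statistical behaviour under the planted model, not robustness to those
real-data pathologies.

## Numerical choices and edge cases

- Bin census boundaries: the percent bins are [0, 40], (40, 80], (80, 100]
  (right-inclusive, lowest bin closed) — exhaustive with no gaps, since the
  colloquial "0–40 / 41–80 / >81" leaves 40–41 and 80–81 undefined on a
  continuous scale.
- Duplicate transcripts collapse to one gene per set, keeping the
  transcript of maximal |log2FC|.
- Empty region strata are reported as missing (NaN), never as 0.
- KDE mode estimates fall back to the constant value when a sample's
  subset is degenerate.
- Agglomeration ties are broken deterministically by scipy's pair-index
  order; permuting input sample order yields an isomorphic tree.
- The analysis itself draws no random numbers: a run manifest (parameter
  echo, versions, input checksums) reproduces outputs byte-identically.

## Problem sizes

Defaults are sized for a laptop-class run: the full screen on the default
study takes under a second; the error-control simulations in the test
suite use 5000 features × 200 all-null datasets (vectorized Welch and
correlation paths) and 20 000 null tests for the realized size of the
Welch test, all within seconds.

## Known limitations

- The temporal classification is threshold-based; it orders events
  (induction before demethylation) but supports no causal claim.
- Per-probe differential methylation with triplicates is underpowered for
  small Δβ; the screen's power comes from pooling probes per gene and
  correlating across the whole series.
- The fold-change gate reads "1.5" as a linear fold change (log2 1.5 ≈
  0.585); the stricter reading (1.5 on the log2 scale, 2.83-fold) is
  available via the threshold parameter.
- With very few non-null genes, BH adaptivity makes the inverse screen's
  realized sensitivity depend on the planted fraction; the recovery
  guarantees quoted in the tests are for the default composition.
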