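"""Per-probe differential methylation and descriptive methylome profiles.

Tests run on M-values (logit2 of beta), the scale on which array
methylation data is closest to Gaussian; effect sizes (delta beta) and all
descriptive summaries are reported on the beta scale, which is the
interpretable one.  Multiple testing is controlled with the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from metx.io import CONTEXTS, REGION_CLASSES
from metx.preprocess import beta_to_m

BIN_EDGES = (0.0, 40.0, 80.0, 100.0)  # percent methylation; right-inclusive
BIN_LABELS = ("low", "mid", "high")


def welch_t_test(group_a, group_b):
    """Two-sided Welch (unequal variance) t-test.

    Returns ``(t, p)``.  Degenerate cases follow a fixed convention: both
    groups with zero variance and equal means give ``(0, 1)``; both with
    zero variance and different means give ``(+/-inf, 0)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 finite values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def welch_t_test_rows(A: np.ndarray, B: np.ndarray):
    """Vectorized Welch test over matrix rows (features x replicates).

    Rows where both groups are constant get the same convention as
    :func:`welch_t_test`.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(A, B, axis=1, equal_var=False)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (A.var(axis=1, ddof=1) == 0) & (B.var(axis=1, ddof=1) == 0)
    if degenerate.any():
        diff = A.mean(axis=1) - B.mean(axis=1)
        equal = degenerate & (diff == 0)
        t[equal], p[equal] = 0.0, 1.0
        uneq = degenerate & (diff != 0)
        t[uneq] = np.where(diff[uneq] > 0, np.inf, -np.inf)
        p[uneq] = 0.0
    return t, p


def bh_adjust(pvalues):
    """Benjamini-Hochberg step-up adjusted p-values, returned in input order
    and capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def diff_methylation(
    betas: pd.DataFrame,
    samples_a,
    samples_b,
    epsilon: float = 1e-6,
    max_missing_fraction: float = 0.5,
) -> pd.DataFrame:
    """Per-probe Welch test of group B vs group A on M-values.

    Probes missing in more than ``max_missing_fraction`` of either group's
    samples are dropped from the test (reported nowhere rather than as a
    shaky statistic).  Returns a DataFrame indexed by probe with columns
    ``mean_a, mean_b, delta_beta, t, p, q``; ``delta_beta`` is
    ``mean(B) - mean(A)`` on the beta scale.
    """
    samples_a, samples_b = list(samples_a), list(samples_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    if set(samples_a) & set(samples_b):
        raise ValueError("contrast groups overlap")
    A_beta = betas[samples_a]
    B_beta = betas[samples_b]
    ok = (
        (A_beta.notna().mean(axis=1) >= 1 - max_missing_fraction)
        & (B_beta.notna().mean(axis=1) >= 1 - max_missing_fraction)
        & (A_beta.notna().sum(axis=1) >= 2)
        & (B_beta.notna().sum(axis=1) >= 2)
    )
    A_beta, B_beta = A_beta[ok], B_beta[ok]
    A = beta_to_m(A_beta, epsilon).to_numpy()
    B = beta_to_m(B_beta, epsilon).to_numpy()
    if np.isnan(A).any() or np.isnan(B).any():
        # fall back to the scalar path for probes with scattered missingness
        t = np.empty(A.shape[0])
        p = np.empty(A.shape[0])
        for i in range(A.shape[0]):
            t[i], p[i] = welch_t_test(A[i][np.isfinite(A[i])], B[i][np.isfinite(B[i])])
    else:
        t, p = welch_t_test_rows(A, B)
    out = pd.DataFrame(
        {
            "mean_a": A_beta.mean(axis=1),
            "mean_b": B_beta.mean(axis=1),
            "t": t,
            "p": p,
        },
        index=A_beta.index,
    )
    out["delta_beta"] = out["mean_b"] - out["mean_a"]
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out[["mean_a", "mean_b", "delta_beta", "t", "p", "q"]]


def dm_probes(results: pd.DataFrame, q_threshold: float = 0.05,
              delta_beta_threshold: float = 0.2) -> pd.Index:
    """Probes passing the differential-methylation gate
    (q below threshold and |delta beta| at or above threshold)."""
    keep = (results["q"] < q_threshold) & (results["delta_beta"].abs() >= delta_beta_threshold)
    return results.index[keep]


# ---------------------------------------------------------------------------
# descriptive methylome profiles

def region_mean_profile(betas: pd.DataFrame, manifest: pd.DataFrame,
                        probe_subset, groups: dict) -> pd.DataFrame:
    """Mean beta per sample group and gene-region class.

    ``groups`` maps group name -> list of sample ids.  The mean is unweighted
    over all (probe, annotation) pairs of the subset falling in each region;
    regions with no subset probes are reported as NaN, not 0.
    """
    probe_subset = pd.Index(probe_subset)
    ann = manifest[manifest["probe_id"].isin(probe_subset)]
    unknown = set(ann["region_class"]) - set(REGION_CLASSES)
    if unknown:
        raise ValueError(f"unknown region class {unknown}")
    rows = {}
    for name, samples in groups.items():
        sample_mean = betas.loc[betas.index.intersection(probe_subset), list(samples)].mean(axis=1)
        per_region = {}
        for region in REGION_CLASSES:
            probes = ann.loc[ann["region_class"] == region, "probe_id"]
            vals = sample_mean.reindex(probes).dropna()
            per_region[region] = vals.mean() if len(vals) else np.nan
        rows[name] = per_region
    return pd.DataFrame.from_dict(rows, orient="index")[list(REGION_CLASSES)]


def context_stratify(betas: pd.DataFrame, manifest: pd.DataFrame,
                     probe_subset, groups: dict) -> pd.DataFrame:
    """Region profile split by CpG context (Island vs OpenSea).

    Shore/Shelf probes are excluded: the two-context analysis contrasts
    CpG-island-associated methylation with the open sea only.  Returns a
    DataFrame indexed by (context, group) with region-class columns.
    """
    frames = {}
    for context in CONTEXTS:
        probes = manifest.loc[manifest["island_relation"] == context, "probe_id"]
        subset = pd.Index(probe_subset).intersection(pd.Index(probes.unique()))
        sub_manifest = manifest[manifest["island_relation"] == context]
        frames[context] = region_mean_profile(betas, sub_manifest, subset, groups)
    return pd.concat(frames, names=["context", "group"])


def bin_census(betas: pd.DataFrame, manifest: pd.DataFrame, samples) -> pd.DataFrame:
    """Per-chromosome census of probes by mean methylation bin.

    Bins on the percent scale: low [0, 40], mid (40, 80], high (80, 100]
    (right-inclusive so every finite beta falls in exactly one bin; the
    printed "0-40 / 41-80 / >81" convention leaves the boundaries open).
    Rows sum to the number of probes with a finite mean beta.
    """
    mean_beta = betas[list(samples)].mean(axis=1) * 100.0
    chrom = manifest.drop_duplicates("probe_id").set_index("probe_id")["chromosome"]
    df = pd.DataFrame({"pct": mean_beta}).join(chrom, how="inner").dropna()
    binned = pd.cut(df["pct"], bins=list(BIN_EDGES), labels=BIN_LABELS, include_lowest=True)
    counts = (
        pd.crosstab(df["chromosome"], binned)
        .reindex(columns=list(BIN_LABELS), fill_value=0)
    )
    counts.columns.name = None
    counts.index.name = "chromosome"
    return counts.astype(int)


def distribution_summary(betas: pd.DataFrame, probe_subset, samples=None,
                         grid_size: int = 512) -> pd.DataFrame:
    """Per-sample distribution summary of a probe subset: quantiles
    (5/25/50/75/95%) and the kernel-density mode on [0, 1].

    Backs the violin-plot style readout of how the genome-wide methylation
    distribution shifts over the time course.
    """
    sub = betas.loc[betas.index.intersection(pd.Index(probe_subset))]
    if sub.empty:
        raise ValueError("probe subset is empty")
    if samples is not None:
        sub = sub[list(samples)]
    grid = np.linspace(0.0, 1.0, grid_size)
    rows = {}
    for sample in sub.columns:
        vals = sub[sample].dropna().to_numpy()
        q = np.quantile(vals, [0.05, 0.25, 0.50, 0.75, 0.95])
        if np.ptp(vals) == 0:
            mode = float(vals[0])
        else:
            kde = stats.gaussian_kde(vals)
            mode = float(grid[int(np.argmax(kde(grid)))])
        rows[sample] = dict(zip(["q05", "q25", "q50", "q75", "q95"], q), mode=mode)
    return pd.DataFrame.from_dict(rows, orient="index")
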