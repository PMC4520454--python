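"""Per-gene expression fold changes against the parental baseline,
deregulated gene sets per timepoint, and averaged group contrasts."""

from __future__ import annotations

import numpy as np
import pandas as pd

from metx.diffmeth import bh_adjust, welch_t_test_rows
from metx.io import GeneSet

DIRECTIONS = ("up", "down", "both")
#: conventional microarray gate: 1.5-fold on the linear scale
DEFAULT_FC_THRESHOLD = float(np.log2(1.5))


def log2_fold_change(expr: pd.DataFrame, baseline_samples, target_samples) -> pd.Series:
    """Per-gene ``mean(target) - mean(baseline)`` on log2 intensities."""
    baseline_samples, target_samples = list(baseline_samples), list(target_samples)
    if not baseline_samples or not target_samples:
        raise ValueError("both sample groups must be non-empty")
    fc = expr[target_samples].mean(axis=1) - expr[baseline_samples].mean(axis=1)
    fc.name = "log2fc"
    return fc


def fold_change_table(expr: pd.DataFrame, sheet: pd.DataFrame,
                      baseline_group: str) -> pd.DataFrame:
    """log2 fold change of every timepoint group vs the baseline group.

    Groups are taken from the sample sheet's ``group`` column; the result is
    genes x groups (baseline column included, identically 0 up to rounding).
    """
    if baseline_group not in set(sheet["group"]):
        raise ValueError(f"baseline group {baseline_group!r} not in sample sheet")
    base = sheet.loc[sheet["group"] == baseline_group, "sample_id"]
    cols = {}
    for group, sub in sheet.groupby("group", sort=False):
        cols[group] = log2_fold_change(expr, base, sub["sample_id"])
    return pd.DataFrame(cols)


def diff_expression(expr: pd.DataFrame, sheet: pd.DataFrame,
                    baseline_group: str) -> pd.DataFrame:
    """Tidy per-gene, per-group differential expression vs baseline.

    Returns columns ``gene, group, log2fc, p, q``; p is a Welch test across
    replicates (NaN when a side has < 2 replicates), q is BH-adjusted within
    each group.
    """
    base = list(sheet.loc[sheet["group"] == baseline_group, "sample_id"])
    if not base:
        raise ValueError(f"baseline group {baseline_group!r} not in sample sheet")
    frames = []
    B = expr[base].to_numpy()
    for group, sub in sheet.groupby("group", sort=False):
        if group == baseline_group:
            continue
        tgt = list(sub["sample_id"])
        fc = log2_fold_change(expr, base, tgt)
        frame = pd.DataFrame({"gene": expr.index, "group": group, "log2fc": fc.to_numpy()})
        if len(base) >= 2 and len(tgt) >= 2:
            _, p = welch_t_test_rows(expr[tgt].to_numpy(), B)
            frame["p"] = p
            frame["q"] = bh_adjust(p)
        else:
            frame["p"] = np.nan
            frame["q"] = np.nan
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def collapse_transcripts(log2fc: pd.Series) -> pd.Series:
    """Collapse duplicate gene symbols keeping the transcript of maximal
    |log2fc| (multi-probe genes are recorded only once)."""
    if not log2fc.index.has_duplicates:
        return log2fc
    out = {}
    for gene, sub in log2fc.groupby(level=0):
        out[gene] = sub.iloc[int(np.argmax(np.abs(sub.to_numpy())))]
    return pd.Series(out, name=log2fc.name)


def deregulated_set(log2fc: pd.Series, fc_threshold: float = DEFAULT_FC_THRESHOLD,
                    direction: str = "both", name: str = "deregulated",
                    description: str = "") -> GeneSet:
    """Genes whose fold change passes the threshold in the given direction.

    ``direction='both'`` selects on |log2fc|; duplicate gene symbols are
    collapsed first (max |log2fc| wins) so a set never lists a gene twice.
    """
    if fc_threshold <= 0:
        raise ValueError("fc_threshold must be > 0")
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    fc = collapse_transcripts(log2fc.dropna())
    if direction == "up":
        keep = fc >= fc_threshold
    elif direction == "down":
        keep = fc <= -fc_threshold
    else:
        keep = fc.abs() >= fc_threshold
    return GeneSet(name, description, tuple(fc.index[keep]))


def group_contrast(expr: pd.DataFrame, group_a_samples, group_b_samples) -> pd.Series:
    """Per-gene ``mean(A) - mean(B)`` of averaged group intensities
    (antisymmetric under swapping the groups)."""
    a, b = list(group_a_samples), list(group_b_samples)
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    if set(a) & set(b):
        raise ValueError(f"groups overlap: {sorted(set(a) & set(b))}")
    diff = expr[a].mean(axis=1) - expr[b].mean(axis=1)
    diff.name = "group_contrast"
    return diff
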