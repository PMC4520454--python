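"""The screen's core: per-gene methylation-expression correlation across the
time course and the three-step candidate funnel.

Step 1 (inverse-correlation set): genes whose locus methylation and
expression are significantly anticorrelated (Pearson r < 0, BH-adjusted
q below the gate) across the transition samples.

Step 2 (fold-change gate, the "5mC/Gex group"): of those, keep genes whose
expression actually moves — max |log2 fold change| over the time course at
or above the threshold.

Step 3 (temporal classification): within the group, a gene is *poised*
when it is already induced at the earliest timepoint while its methylation
has changed only marginally (demethylation follows later); every other
group member changes expression and methylation concordantly late.  The
classification is exclusive and exhaustive over the group, so
|group| = |poised| + |late_concordant| by construction.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from metx.diffmeth import bh_adjust
from metx.io import REGION_CLASSES, GeneSet

TEMPORAL_CLASSES = ("poised_early", "late_concordant", "not_classified")


# ---------------------------------------------------------------------------
# gene-level methylation

def gene_level_methylation(betas: pd.DataFrame, manifest: pd.DataFrame,
                           region_selection=None) -> pd.DataFrame:
    """Summarize probe betas to one methylation value per gene and sample.

    The summary is the mean over all probes mapped to the gene, optionally
    restricted to a subset of gene-region classes (e.g. promoter-only:
    ``("TSS1500", "TSS200")``).  Genes with no (remaining) probes are absent
    from the output rather than reported as NaN rows.
    """
    ann = manifest[manifest["gene"] != ""]
    if region_selection is not None:
        region_selection = tuple(region_selection) if not isinstance(region_selection, str) \
            else (region_selection,)
        bad = set(region_selection) - set(REGION_CLASSES)
        if bad:
            raise ValueError(f"unknown region class {bad}; expected {REGION_CLASSES}")
        ann = ann[ann["region_class"].isin(region_selection)]
    pairs = ann[["probe_id", "gene"]].drop_duplicates()
    pairs = pairs[pairs["probe_id"].isin(betas.index)]
    if pairs.empty:
        return pd.DataFrame(columns=betas.columns)
    merged = betas.loc[pairs["probe_id"]].copy()
    merged.index = pd.Index(pairs["gene"], name="gene")
    return merged.groupby(level=0).mean()


# ---------------------------------------------------------------------------
# correlation

def pearson_correlate(gene_meth, gene_expr):
    """Product-moment correlation of one gene's methylation and expression.

    Returns ``(r, p)`` with a two-sided p from the t distribution with
    n - 2 degrees of freedom.  Requires >= 3 paired finite samples and
    non-zero variance on both sides (a flat profile is not evidence of
    anything; callers exclude such genes from the screen instead of
    recording r = 0).
    """
    x = np.asarray(gene_meth, dtype=float)
    y = np.asarray(gene_expr, dtype=float)
    if x.shape != y.shape:
        raise ValueError("methylation and expression vectors differ in length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired samples")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc**2))
    sy = np.sqrt(np.sum(yc**2))
    if sx == 0 or sy == 0:
        raise ValueError("zero variance: correlation not computable")
    r = float(np.sum(xc * yc) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def correlate_genes(gene_meth: pd.DataFrame, expr: pd.DataFrame, samples,
                    q_gate: float = 0.05) -> pd.DataFrame:
    """Per-gene Pearson r/p/q between methylation and expression.

    Restricted to the given samples (the transition series by default
    upstream) and the genes present on both platforms.  Genes with zero
    variance on either side are excluded before BH adjustment.  Returns a
    DataFrame indexed by gene with columns ``r, p, q, inverse_flag``.
    """
    samples = list(samples)
    genes = gene_meth.index.intersection(expr.index)
    M = gene_meth.loc[genes, samples].to_numpy(dtype=float)
    E = expr.loc[genes, samples].to_numpy(dtype=float)
    n = len(samples)
    if n < 3:
        raise ValueError("need at least 3 samples for correlation")
    Mc = M - M.mean(axis=1, keepdims=True)
    Ec = E - E.mean(axis=1, keepdims=True)
    sm = np.sqrt((Mc**2).sum(axis=1))
    se = np.sqrt((Ec**2).sum(axis=1))
    computable = (sm > 0) & (se > 0) & np.isfinite(M).all(axis=1) & np.isfinite(E).all(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Mc * Ec).sum(axis=1) / (sm * se)
    r = np.clip(r, -1.0, 1.0)
    rr = r[computable]
    with np.errstate(divide="ignore"):
        t = rr * np.sqrt((n - 2) / np.maximum(1.0 - rr * rr, 0.0))
    p = np.where(np.abs(rr) == 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    out = pd.DataFrame({"r": rr, "p": p}, index=genes[computable])
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["inverse_flag"] = (out["r"] < 0) & (out["q"] < q_gate)
    out.index.name = "gene"
    return out


# ---------------------------------------------------------------------------
# the funnel

def inverse_correlation_screen(records: pd.DataFrame, q_gate: float = 0.05,
                               name: str = "inverse_correlation") -> GeneSet:
    """Genes with r < 0 and BH-adjusted q below the gate."""
    keep = records.index[(records["r"] < 0) & (records["q"] < q_gate)]
    return GeneSet(name, f"inverse 5mC-expression correlation, q<{q_gate}", tuple(keep))


def apply_fc_gate(inverse_set: GeneSet, max_abs_log2fc: pd.Series,
                  fc_threshold: float, name: str = "5mC_Gex_group") -> GeneSet:
    """Intersect the inverse-correlation set with the genes whose maximal
    |log2FC| over the time course reaches the threshold."""
    if fc_threshold < 0:
        raise ValueError("fc_threshold must be >= 0")
    passing = set(max_abs_log2fc.index[max_abs_log2fc.abs() >= fc_threshold])
    members = tuple(g for g in inverse_set.members if g in passing)
    return GeneSet(name, f"inverse correlation and max |log2FC| >= {fc_threshold:g}", members)


def classify_temporal(group: GeneSet, log2fc_table: pd.DataFrame,
                      delta_beta_table: pd.DataFrame, early_timepoint,
                      fc_threshold: float, poised_delta_beta: float = 0.1) -> pd.Series:
    """Split the 5mC/Gex group into poised-early vs late-concordant genes.

    ``log2fc_table`` and ``delta_beta_table`` are genes x timepoint-groups
    (fold change and methylation change vs baseline).  A gene is
    ``poised_early`` iff it is induced at the early timepoint
    (|log2FC| >= fc_threshold) while its methylation there has moved less
    than ``poised_delta_beta``; every other group member is
    ``late_concordant``.  Exclusive and exhaustive over the group.
    """
    if early_timepoint not in log2fc_table.columns:
        raise ValueError(f"early timepoint {early_timepoint!r} has no samples")
    missing = [g for g in group.members if g not in log2fc_table.index
               or g not in delta_beta_table.index]
    if missing:
        raise ValueError(f"group genes missing from tables: {missing[:5]}")
    out = {}
    for gene in group.members:
        fc_early = log2fc_table.loc[gene, early_timepoint]
        db_early = delta_beta_table.loc[gene, early_timepoint]
        if abs(fc_early) >= fc_threshold and abs(db_early) < poised_delta_beta:
            out[gene] = "poised_early"
        else:
            out[gene] = "late_concordant"
    return pd.Series(out, name="temporal_class", dtype=object)


def integration_table(records: pd.DataFrame, max_abs_log2fc: pd.Series,
                      delta_beta_table: pd.DataFrame, temporal: pd.Series,
                      group: GeneSet, early_timepoint) -> pd.DataFrame:
    """Assemble the per-gene integration record table (one row per tested
    gene: correlation statistics, gates passed, temporal class)."""
    out = records.copy()
    out["max_abs_log2fc"] = max_abs_log2fc.reindex(out.index).abs()
    out["in_group_flag"] = out.index.isin(set(group.members))
    out["delta_beta_early"] = delta_beta_table.reindex(out.index)[early_timepoint]
    out["temporal_class"] = temporal.reindex(out.index).fillna("not_classified")
    return out


def check_funnel(tested, inverse_set: GeneSet, group: GeneSet, temporal: pd.Series) -> None:
    """Assert the screen's containment invariants; raise on violation.

    poised subset of group subset of inverse set subset of tested genes, and
    |group| = |poised| + |late_concordant|.
    """
    tested = set(tested)
    inv = set(inverse_set.members)
    grp = set(group.members)
    poised = set(temporal.index[temporal == "poised_early"])
    late = set(temporal.index[temporal == "late_concordant"])
    if not inv <= tested:
        raise AssertionError("inverse-correlation set not contained in tested genes")
    if not grp <= inv:
        raise AssertionError("5mC/Gex group not contained in inverse-correlation set")
    if not poised <= grp:
        raise AssertionError("poised set not contained in 5mC/Gex group")
    if len(grp) != len(poised) + len(late) or (poised | late) != grp:
        raise AssertionError("temporal classification not exclusive-exhaustive over group")


# ---------------------------------------------------------------------------
# set algebra

def set_report(sets: dict) -> pd.DataFrame:
    """All Venn-partition region cardinalities for 2+ named gene sets.

    Each region is a membership pattern (in/out per set); counts over all
    regions sum to |union|.  Returns one row per non-empty pattern plus the
    empty patterns, with the member list joined by commas.
    """
    if len(sets) < 2:
        raise ValueError("set_report requires at least 2 sets")
    names = list(sets)
    member_sets = {n: set(sets[n].members) for n in names}
    union = set().union(*member_sets.values())
    rows = []
    for pattern in product([True, False], repeat=len(names)):
        if not any(pattern):
            continue
        region = set(union)
        for name, inside in zip(names, pattern):
            region &= member_sets[name] if inside else (union - member_sets[name])
        rows.append({
            **{name: inside for name, inside in zip(names, pattern)},
            "count": len(region),
            "members": ",".join(sorted(region)),
        })
    report = pd.DataFrame(rows)
    assert report["count"].sum() == len(union)
    return report
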