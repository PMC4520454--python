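"""End-to-end orchestration: run every stage on one input set with one
parameter block, write all artifacts, and record a reproducibility manifest.

``run_screen`` is the in-memory pipeline (used directly by tests and the
recovery analyses); ``run_all`` wraps it with file IO, per-stage error
reporting and a JSON run manifest (parameter echo, package versions, input
and output checksums).
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from metx import diffexpr, diffmeth, integrate
from metx.cluster import hierarchical_cluster, clusters_at_k
from metx.io import (
    check_samples_match,
    read_manifest,
    read_matrix,
    read_sample_sheet,
    write_gene_sets,
    write_matrix,
    write_newick,
)


@dataclass
class ScreenParams:
    """All stage thresholds in one place (documented defaults; none of these
    are stated by any single convention, so each is configurable)."""

    q_correlation: float = 0.05      # gate on BH-adjusted correlation p
    fc_threshold: float = diffexpr.DEFAULT_FC_THRESHOLD  # log2(1.5)
    poised_delta_beta: float = 0.1   # "only marginal" methylation change
    early_week: int = 1
    q_methylation: float = 0.05      # probe-level DM gate
    delta_beta_threshold: float = 0.2
    region_selection: tuple | None = None  # None = all mapped probes
    include_reference: bool = False  # EC line in the correlation series
    reference_group: str = "EC"
    cluster_metric_expr: str = "correlation"
    cluster_metric_meth: str = "euclidean"
    cluster_linkage: str = "average"
    cluster_top_n: int = 5000

    def __post_init__(self):
        for name in ("q_correlation", "q_methylation"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.fc_threshold <= 0:
            raise ValueError("fc_threshold must be > 0")
        if not 0 < self.poised_delta_beta <= 1:
            raise ValueError("poised_delta_beta must lie in (0, 1]")


def transition_samples(sheet: pd.DataFrame, reference_group: str = "EC") -> pd.DataFrame:
    """The transition series: every sample outside the reference group,
    ordered by week."""
    sub = sheet[sheet["group"] != reference_group]
    return sub.sort_values(["week", "sample_id"], kind="mergesort")


def run_screen(manifest, betas, expr, sheet, params: ScreenParams | None = None) -> dict:
    """Run the full screen in memory; returns a dict of stage results.

    Keys: ``records`` (per-gene integration table), ``inverse_set``,
    ``group_set``, ``poised_set``, ``late_set``, ``temporal``,
    ``log2fc_table``, ``delta_beta_table``, ``diffmeth``, ``dm_probes``,
    ``region_profile``, ``context_profile``, ``bin_census``,
    ``distribution``, ``deregulated`` (per-week GeneSets), ``venn``,
    ``tree_expr``, ``tree_meth``, ``clusters_expr``, ``clusters_meth``.
    """
    params = params or ScreenParams()
    check_samples_match(betas, sheet)
    check_samples_match(expr, sheet)

    trans = transition_samples(sheet, params.reference_group)
    weeks = sorted(trans["week"].unique())
    baseline_group = f"week{weeks[0]}"
    endpoint_group = f"week{weeks[-1]}"
    early_group = f"week{params.early_week}"
    if early_group not in set(trans["group"]):
        raise ValueError(f"early timepoint week {params.early_week} has no samples")
    group_samples = {g: list(s["sample_id"]) for g, s in trans.groupby("group", sort=False)}

    # --- expression stage
    fc_table = diffexpr.fold_change_table(expr, trans, baseline_group)
    nonbase = [c for c in fc_table.columns if c != baseline_group]
    max_abs_fc = fc_table[nonbase].abs().max(axis=1)
    deregulated = {
        g: diffexpr.deregulated_set(fc_table[g], params.fc_threshold, "both",
                                    name=f"deregulated_{g}")
        for g in nonbase
    }

    # --- methylation stage
    dm = diffmeth.diff_methylation(betas, group_samples[baseline_group],
                                   group_samples[endpoint_group])
    dm_idx = diffmeth.dm_probes(dm, params.q_methylation, params.delta_beta_threshold)
    groups_for_profiles = dict(group_samples)
    ref_samples = list(sheet.loc[sheet["group"] == params.reference_group, "sample_id"])
    if ref_samples:
        groups_for_profiles[params.reference_group] = ref_samples
    profile_probes = dm_idx if len(dm_idx) else betas.index
    region_profile = diffmeth.region_mean_profile(betas, manifest, profile_probes,
                                                 groups_for_profiles)
    context_profile = diffmeth.context_stratify(betas, manifest, profile_probes,
                                                groups_for_profiles)
    census = diffmeth.bin_census(betas, manifest, group_samples[endpoint_group])
    distribution = diffmeth.distribution_summary(betas, profile_probes)

    # --- integration stage
    gene_meth = integrate.gene_level_methylation(betas, manifest, params.region_selection)
    corr_samples = list(trans["sample_id"])
    if params.include_reference:
        corr_samples += ref_samples
    records = integrate.correlate_genes(gene_meth, expr, corr_samples,
                                        params.q_correlation)
    inverse_set = integrate.inverse_correlation_screen(records, params.q_correlation)
    group_set = integrate.apply_fc_gate(inverse_set, max_abs_fc, params.fc_threshold)
    gm_groups = pd.DataFrame({
        g: gene_meth[s].mean(axis=1) for g, s in group_samples.items()
    })
    delta_beta_table = gm_groups.sub(gm_groups[baseline_group], axis=0)
    temporal = integrate.classify_temporal(group_set, fc_table, delta_beta_table,
                                           early_group, params.fc_threshold,
                                           params.poised_delta_beta)
    integrate.check_funnel(records.index, inverse_set, group_set, temporal)
    poised = integrate.GeneSet("poised_early", "induced early, demethylated later",
                               tuple(temporal.index[temporal == "poised_early"]))
    late = integrate.GeneSet("late_concordant", "late concordant change",
                             tuple(temporal.index[temporal == "late_concordant"]))
    table = integrate.integration_table(records, max_abs_fc, delta_beta_table,
                                        temporal, group_set, early_group)
    venn = integrate.set_report({
        "inverse_correlation": inverse_set,
        f"deregulated_{early_group}": deregulated[early_group],
        f"deregulated_{endpoint_group}": deregulated[endpoint_group],
    })

    # --- clustering stage (all samples, reference included)
    tree_expr = hierarchical_cluster(expr, params.cluster_metric_expr,
                                     params.cluster_linkage, params.cluster_top_n)
    tree_meth = hierarchical_cluster(betas, params.cluster_metric_meth,
                                     params.cluster_linkage, params.cluster_top_n)

    return {
        "params": params,
        "baseline_group": baseline_group,
        "endpoint_group": endpoint_group,
        "records": table,
        "inverse_set": inverse_set,
        "group_set": group_set,
        "poised_set": poised,
        "late_set": late,
        "temporal": temporal,
        "log2fc_table": fc_table,
        "max_abs_log2fc": max_abs_fc,
        "delta_beta_table": delta_beta_table,
        "deregulated": deregulated,
        "diffmeth": dm,
        "dm_probes": dm_idx,
        "region_profile": region_profile,
        "context_profile": context_profile,
        "bin_census": census,
        "distribution": distribution,
        "venn": venn,
        "tree_expr": tree_expr,
        "tree_meth": tree_meth,
        "clusters_expr": clusters_at_k(tree_expr, 2),
        "clusters_meth": clusters_at_k(tree_meth, 2),
    }


# ---------------------------------------------------------------------------
# file-level orchestration

@dataclass
class RunConfig:
    betas: str
    expression: str
    manifest: str
    samples: str
    outdir: str
    params: ScreenParams = field(default_factory=ScreenParams)
    seed: int = 0


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _log(stage: str, t0: float) -> None:
    print(f"[metx] {stage}: {time.perf_counter() - t0:.2f}s", file=sys.stderr)


def run_all(config: RunConfig) -> Path:
    """Execute the pipeline on disk inputs; returns the output directory.

    Fails fast with the offending path if an input is missing; any stage
    error is re-raised annotated with the stage name.  The run manifest
    (``run_manifest.json``) plus the input files reproduce every output
    byte-identically: the analysis itself draws no random numbers.
    """
    for name in ("betas", "expression", "manifest", "samples"):
        p = Path(getattr(config, name))
        if not p.exists():
            raise FileNotFoundError(f"input {name!r} not found: {p}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    try:
        manifest = read_manifest(config.manifest)
        betas = read_matrix(config.betas, kind="beta")
        expr = read_matrix(config.expression, kind="log2")
        sheet = read_sample_sheet(config.samples)
    except Exception as exc:
        raise RuntimeError(f"stage 'load' failed: {exc}") from exc
    _log("load", t0)

    t0 = time.perf_counter()
    try:
        res = run_screen(manifest, betas, expr, sheet, config.params)
    except Exception as exc:
        raise RuntimeError(f"stage 'screen' failed: {exc}") from exc
    _log("screen", t0)

    t0 = time.perf_counter()
    res["records"].to_csv(outdir / "integration_records.tsv", sep="\t",
                          float_format="%.6g")
    res["diffmeth"].to_csv(outdir / "diffmeth.tsv", sep="\t", float_format="%.6g")
    write_matrix(res["log2fc_table"], outdir / "log2fc.tsv")
    write_matrix(res["delta_beta_table"], outdir / "delta_beta.tsv")
    res["region_profile"].to_csv(outdir / "region_profile.tsv", sep="\t",
                                 float_format="%.6g")
    res["context_profile"].to_csv(outdir / "context_profile.tsv", sep="\t",
                                  float_format="%.6g")
    res["bin_census"].to_csv(outdir / "bin_census.tsv", sep="\t")
    res["distribution"].to_csv(outdir / "distribution_summary.tsv", sep="\t",
                               float_format="%.6g")
    res["venn"].to_csv(outdir / "venn_report.tsv", sep="\t", index=False)
    sets = [res["inverse_set"], res["group_set"], res["poised_set"], res["late_set"],
            *res["deregulated"].values()]
    write_gene_sets(sets, outdir / "gene_sets.gmt")
    write_newick(res["tree_expr"], outdir / "dendrogram_expression.nwk")
    write_newick(res["tree_meth"], outdir / "dendrogram_methylation.nwk")
    _log("write", t0)

    versions = {"metx": __import__("metx").__version__,
                "numpy": np.__version__, "pandas": pd.__version__}
    run_manifest = {
        "config": {**{k: getattr(config, k) for k in
                      ("betas", "expression", "manifest", "samples", "outdir", "seed")},
                   "params": asdict(config.params)},
        "versions": versions,
        "input_checksums": {name: _sha256(getattr(config, name))
                            for name in ("betas", "expression", "manifest", "samples")},
        "output_checksums": {p.name: _sha256(p) for p in sorted(outdir.iterdir())
                             if p.name != "run_manifest.json"},
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=2, default=str)
    return outdir
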