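"""Synthetic two-platform time course with planted gene classes.

Emulates a seminoma-like cell line transitioning to an embryonal-carcinoma-
like state over a 0/1/2/4/6-week in vivo series, assayed on a 450K-style
methylation array (beta values) and an intensity expression array, plus an
EC-like reference line.  Four planted gene classes drive the dynamics:

``poised_early``
    expression induced by ``fc_effect`` log2 units already at week 1 (rising
    further to 2x by week 6), while locus methylation is unchanged at week 1
    and drops by ``delta_beta_effect`` from week 2 on — the "poised for
    expression" pattern of rapid induction followed by demethylation.
``late_concordant``
    expression and methylation move together late (from week 4).
``silenced_down``
    expression down and methylation up from week 2 (de novo silencing).
``null``
    no planted change.

Methylation noise is Beta-distributed with a mean/precision
parameterization (``shape1 = mean * precision``), the standard model for
bounded array betas; expression noise is Gaussian on the log2 scale.  The
generator also returns a ground-truth table (gene, class, per-timepoint
log2FC and mean-beta profiles) used by the recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from metx.io import REGION_CLASSES, validate_sample_sheet

GENE_CLASSES = ("poised_early", "late_concordant", "silenced_down", "null")

DEFAULT_FRACTIONS = {
    "poised_early": 0.05,
    "late_concordant": 0.10,
    "silenced_down": 0.10,
    "null": 0.75,
}


@dataclass
class SimConfig:
    """Parameters of the synthetic transition time course.

    Defaults are the desk-scale study conditions used throughout the test
    suite: 2000 genes, 5 timepoints x 3 replicates, 1.5 log2-unit induction
    and a 0.3 methylation shift for remodelled loci.
    """

    n_genes: int = 2000
    probes_per_gene: tuple = (3, 8)  # inclusive min/max
    timepoints: tuple = (0, 1, 2, 4, 6)  # weeks
    replicates_per_timepoint: int = 3
    class_fractions: dict = field(default_factory=lambda: dict(DEFAULT_FRACTIONS))
    beta_precision: float = 100.0
    expr_sigma: float = 0.25
    fc_effect: float = 1.5
    delta_beta_effect: float = 0.3
    ec_replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {total}")
        unknown = set(self.class_fractions) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene classes {unknown}")
        if self.n_genes < 1 or self.replicates_per_timepoint < 1 or self.ec_replicates < 1:
            raise ValueError("all counts must be >= 1")
        lo, hi = self.probes_per_gene
        if lo < 1 or hi < lo:
            raise ValueError("probes_per_gene must be (min >= 1, max >= min)")
        tp = tuple(self.timepoints)
        if len(tp) < 2 or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if tp[0] != 0:
            raise ValueError("the first timepoint is the week-0 baseline")
        if self.fc_effect <= 0 or self.delta_beta_effect <= 0:
            raise ValueError("effect sizes must be > 0")
        if self.beta_precision <= 0 or self.expr_sigma <= 0:
            raise ValueError("noise parameters must be > 0")


def beta_noise(mean_beta: float, precision: float, draws: int, seed: int) -> np.ndarray:
    """Beta-distributed draws with the mean/precision parameterization
    ``shape1 = mean * precision, shape2 = (1 - mean) * precision``."""
    if not 0 < mean_beta < 1:
        raise ValueError("mean_beta must lie strictly inside (0, 1)")
    if precision <= 0:
        raise ValueError("precision must be > 0")
    rng = np.random.default_rng(seed)
    return rng.beta(mean_beta * precision, (1.0 - mean_beta) * precision, size=draws)


def _class_counts(config: SimConfig) -> dict:
    """Deterministic class counts: every non-null class gets
    round(fraction * n); null absorbs the remainder."""
    counts = {}
    for cls in ("poised_early", "late_concordant", "silenced_down"):
        counts[cls] = int(round(config.class_fractions.get(cls, 0.0) * config.n_genes))
    counts["null"] = config.n_genes - sum(counts.values())
    if counts["null"] < 0:
        raise ValueError("non-null class fractions exceed 1 for this n_genes")
    return counts


def _profiles(config: SimConfig):
    """Per-class planted (log2FC, delta-beta) trajectories over timepoints."""
    tp = np.asarray(config.timepoints, dtype=float)
    fc, db = config.fc_effect, config.delta_beta_effect
    zero = np.zeros_like(tp)

    def step(onset):
        return (tp >= onset).astype(float)

    # poised genes are induced at week 1 and keep rising to 2x by the end,
    # with demethylation following one timepoint later
    ramp = np.clip((tp - tp[1]) / (tp[-1] - tp[1]), 0.0, 1.0)
    poised_fc = fc * step(tp[1]) * (1.0 + ramp)
    poised_db = -db * step(tp[2])
    late_fc = fc * step(tp[3])
    late_db = -db * step(tp[3])
    sil_fc = -fc * step(tp[2])
    sil_db = db * step(tp[2])
    return {
        "poised_early": (poised_fc, poised_db),
        "late_concordant": (late_fc, late_db),
        "silenced_down": (sil_fc, sil_db),
        "null": (zero, zero),
    }


def generate_dataset(config: SimConfig):
    """Generate the full synthetic study.

    Returns ``(manifest, betas, expr, sample_sheet, truth)``:

    - manifest: exploded probe annotation table (one gene/region per row)
    - betas: probes x samples methylation matrix in [0, 1]
    - expr: genes x samples log2 expression intensity matrix
    - sample_sheet: sample_id / cell_line / environment / week / group
    - truth: per-gene planted class and true per-timepoint profiles

    Identical configs (including seed) produce bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    counts = _class_counts(config)
    profiles = _profiles(config)
    tp = list(config.timepoints)

    genes = [f"SIM{i + 1:05d}" for i in range(config.n_genes)]
    classes = np.array(
        sum(([cls] * counts[cls] for cls in GENE_CLASSES), []), dtype=object
    )
    classes = classes[rng.permutation(config.n_genes)]

    # sample sheet: transition series + EC reference line
    records = []
    for w in tp:
        env = "in_vitro" if w == 0 else "in_vivo"
        for r in range(config.replicates_per_timepoint):
            records.append((f"T_w{w}_r{r + 1}", "TCam2like", env, w, f"week{w}"))
    for r in range(config.ec_replicates):
        records.append((f"EC_r{r + 1}", "EClike", "in_vitro", 0, "EC"))
    sheet = pd.DataFrame(
        records, columns=["sample_id", "cell_line", "environment", "week", "group"]
    )
    validate_sample_sheet(sheet)
    sample_week_idx = []  # timepoint index per sample; EC samples use the endpoint
    for _, row in sheet.iterrows():
        if row["group"] == "EC":
            sample_week_idx.append(len(tp) - 1)
        else:
            sample_week_idx.append(tp.index(row["week"]))
    sample_week_idx = np.array(sample_week_idx)
    n_samples = len(sheet)

    # gene-level baselines
    expr_base = rng.normal(8.0, 1.5, size=config.n_genes)
    beta_base = np.empty(config.n_genes)
    for i, cls in enumerate(classes):
        if cls in ("poised_early", "late_concordant"):
            beta_base[i] = rng.uniform(0.55, 0.80)  # methylated, demethylates
        elif cls == "silenced_down":
            beta_base[i] = rng.uniform(0.15, 0.40)  # open, gains methylation
        else:
            beta_base[i] = rng.uniform(0.10, 0.90)

    # probe layout: genes round-robin over chromosomes, running coordinates
    chroms = [str(c) for c in range(1, 23)]
    n_probes_per_gene = rng.integers(config.probes_per_gene[0],
                                     config.probes_per_gene[1] + 1,
                                     size=config.n_genes)
    manifest_rows = []
    probe_gene_idx = []
    position = {c: 0 for c in chroms}
    probe_counter = 0
    for i, gene in enumerate(genes):
        chrom = chroms[i % len(chroms)]
        for _ in range(n_probes_per_gene[i]):
            probe_counter += 1
            position[chrom] += int(rng.integers(100, 5000))
            region = REGION_CLASSES[int(rng.integers(len(REGION_CLASSES)))]
            island = "Island" if rng.random() < 0.5 else "OpenSea"
            manifest_rows.append(
                (f"cg{probe_counter:08d}", chrom, position[chrom], gene, region, island)
            )
            probe_gene_idx.append(i)
    manifest = pd.DataFrame(
        manifest_rows,
        columns=["probe_id", "chromosome", "position", "gene", "region_class",
                 "island_relation"],
    )
    probe_gene_idx = np.array(probe_gene_idx)
    n_probes = len(manifest)

    # planted per-gene trajectories
    fc_profile = np.stack([profiles[c][0] for c in classes])      # genes x timepoints
    db_profile = np.stack([profiles[c][1] for c in classes])

    # expression matrix: baseline + planted shift + Gaussian noise
    expr_true = expr_base[:, None] + fc_profile[:, sample_week_idx]
    expr = expr_true + rng.normal(0.0, config.expr_sigma, size=(config.n_genes, n_samples))

    # methylation matrix: probe-level mean = gene trajectory + probe offset
    probe_offset = rng.normal(0.0, 0.04, size=n_probes)
    probe_mean = (
        beta_base[probe_gene_idx, None]
        + probe_offset[:, None]
        + db_profile[probe_gene_idx][:, sample_week_idx]
    )
    probe_mean = np.clip(probe_mean, 0.02, 0.98)
    betas = rng.beta(probe_mean * config.beta_precision,
                     (1.0 - probe_mean) * config.beta_precision)

    betas = pd.DataFrame(betas, index=manifest["probe_id"].unique(),
                         columns=sheet["sample_id"])
    betas.index.name = "probe_id"
    expr = pd.DataFrame(expr, index=pd.Index(genes, name="gene"),
                        columns=sheet["sample_id"])

    truth = pd.DataFrame({"gene": genes, "planted_class": classes})
    for j, w in enumerate(tp):
        truth[f"true_log2fc_w{w}"] = fc_profile[:, j]
    for j, w in enumerate(tp):
        truth[f"true_beta_w{w}"] = np.clip(beta_base + db_profile[:, j], 0.02, 0.98)
    truth = truth.set_index("gene")

    return manifest, betas, expr, sheet, truth


def write_dataset(outdir, manifest, betas, expr, sheet, truth) -> dict:
    """Write all five artifacts as TSV into ``outdir``; returns the paths."""
    from pathlib import Path

    from metx.io import write_manifest, write_matrix, write_sample_sheet

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "manifest": outdir / "manifest.tsv",
        "betas": outdir / "betas.tsv",
        "expression": outdir / "expression.tsv",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_manifest(manifest, paths["manifest"])
    write_matrix(betas, paths["betas"], float_format="%.6f")
    write_matrix(expr, paths["expression"], float_format="%.6f")
    write_sample_sheet(sheet, paths["samples"])
    truth.to_csv(paths["truth"], sep="\t", float_format="%.6f")
    return {k: str(v) for k, v in paths.items()}
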