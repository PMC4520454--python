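"""On-disk formats: probe manifest, numeric matrices, sample sheet, GMT gene
sets and Newick dendrograms.

All tabular formats are tab-separated text with a header row.  The probe
manifest follows the Infinium 450K manifest column names (``IlmnID``,
``CHR``, ``MAPINFO``, ``UCSC_RefGene_Name``, ``UCSC_RefGene_Group``,
``Relation_to_UCSC_CpG_Island``) so a real manifest can be column-mapped
directly; multi-gene / multi-region annotations (semicolon separated on the
array) are exploded into one row per (probe, gene, region) pair.

Readers validate rather than coerce: out-of-range beta values, unknown
region labels and id mismatches raise ``ValueError`` naming the offending
entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REGION_CLASSES = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR")
ISLAND_RELATIONS = ("Island", "Shore", "Shelf", "OpenSea")
#: island relations entering the two-context analysis; Shore/Shelf are
#: accepted on input but excluded from Island-vs-OpenSea stratification
CONTEXTS = ("Island", "OpenSea")

VALID_CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "Y")

MANIFEST_COLUMNS = {
    "IlmnID": "probe_id",
    "CHR": "chromosome",
    "MAPINFO": "position",
    "UCSC_RefGene_Name": "gene",
    "UCSC_RefGene_Group": "region_class",
    "Relation_to_UCSC_CpG_Island": "island_relation",
}


# ---------------------------------------------------------------------------
# probe manifest

def read_manifest(path) -> pd.DataFrame:
    """Read a 450K-style probe manifest into a first-normal-form table.

    Returns a DataFrame with columns ``probe_id, chromosome, position,
    gene, region_class, island_relation``; rows with semicolon-separated
    gene/region annotations are exploded so each row carries exactly one
    (gene, region) pair.  Coordinates are 1-based (MAPINFO convention) and
    used only for reporting.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"manifest {path}: missing columns {missing}")
    rows = []
    for i, rec in enumerate(raw.itertuples(index=False), start=2):  # line no. incl. header
        probe = getattr(rec, "IlmnID")
        chrom = getattr(rec, "CHR")
        if chrom not in VALID_CHROMOSOMES:
            raise ValueError(f"manifest line {i}: invalid chromosome {chrom!r}")
        try:
            pos = int(getattr(rec, "MAPINFO"))
        except ValueError:
            raise ValueError(f"manifest line {i}: non-integer position") from None
        if pos < 1:
            raise ValueError(f"manifest line {i}: position must be >= 1, got {pos}")
        island = getattr(rec, "Relation_to_UCSC_CpG_Island")
        if island not in ISLAND_RELATIONS:
            raise ValueError(
                f"manifest line {i}: unknown island relation {island!r} "
                f"(expected one of {ISLAND_RELATIONS})"
            )
        genes = getattr(rec, "UCSC_RefGene_Name").split(";")
        regions = getattr(rec, "UCSC_RefGene_Group").split(";")
        if len(genes) == 1 and len(regions) > 1:
            genes = genes * len(regions)
        if len(genes) != len(regions):
            raise ValueError(f"manifest line {i}: gene/region annotation length mismatch")
        for gene, region in zip(genes, regions):
            if region not in REGION_CLASSES:
                raise ValueError(
                    f"manifest line {i}: unknown region class {region!r} "
                    f"(expected one of {REGION_CLASSES})"
                )
            rows.append((probe, chrom, pos, gene, region, island))
    out = pd.DataFrame(
        rows,
        columns=["probe_id", "chromosome", "position", "gene", "region_class", "island_relation"],
    )
    dup = out.duplicated(["probe_id", "gene", "region_class"])
    if dup.any():
        first = out.loc[dup.idxmax(), "probe_id"]
        raise ValueError(f"manifest: duplicate (probe, gene, region) annotation for {first}")
    return out


def write_manifest(manifest: pd.DataFrame, path) -> None:
    """Write an exploded manifest back to 450K column names (one annotation
    per row; no re-joining of multi-gene probes)."""
    out = manifest.rename(columns={v: k for k, v in MANIFEST_COLUMNS.items()})
    out[list(MANIFEST_COLUMNS)].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# numeric matrices

def read_matrix(path, kind: str = "beta") -> pd.DataFrame:
    """Read a features x samples matrix (first column = feature id).

    ``kind='beta'`` enforces values in [0, 1] (NaN allowed); ``kind='linear'``
    enforces strictly positive intensities; ``kind='log2'`` applies no range
    check.  Violations raise with the offending feature and sample named.
    """
    mat = pd.read_csv(path, sep="\t", index_col=0)
    if mat.index.has_duplicates:
        dup = mat.index[mat.index.duplicated()][0]
        raise ValueError(f"matrix {path}: duplicate feature id {dup!r}")
    mat = mat.astype(float)
    if kind == "beta":
        bad = (mat < 0) | (mat > 1)
    elif kind == "linear":
        bad = mat <= 0
    elif kind == "log2":
        bad = pd.DataFrame(False, index=mat.index, columns=mat.columns)
    else:
        raise ValueError(f"unknown matrix kind {kind!r}")
    if bad.any().any():
        col = bad.any(axis=0).idxmax()
        row = bad[col].idxmax()
        raise ValueError(
            f"matrix {path}: value {mat.loc[row, col]} out of range for kind "
            f"{kind!r} at feature {row!r}, sample {col!r}"
        )
    return mat


def write_matrix(matrix: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    matrix.to_csv(path, sep="\t", float_format=float_format)


# ---------------------------------------------------------------------------
# sample sheet

ENVIRONMENTS = ("in_vitro", "in_vivo")
SAMPLE_SHEET_COLUMNS = ("sample_id", "cell_line", "environment", "week", "group")


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cell_line": str,
                                               "environment": str, "group": str})
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet {path}: missing columns {missing}")
    validate_sample_sheet(sheet)
    return sheet


def validate_sample_sheet(sheet: pd.DataFrame) -> None:
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"sample sheet: duplicate sample_id {dup!r}")
    bad_env = ~sheet["environment"].isin(ENVIRONMENTS)
    if bad_env.any():
        raise ValueError(
            f"sample sheet: unknown environment {sheet.loc[bad_env, 'environment'].iloc[0]!r}"
        )
    if (sheet["week"] < 0).any():
        raise ValueError("sample sheet: negative week")
    # week 0 is the parental in vitro state; an in vivo sample must have grown
    zero_in_vivo = (sheet["week"] == 0) & (sheet["environment"] == "in_vivo")
    if zero_in_vivo.any():
        sid = sheet.loc[zero_in_vivo, "sample_id"].iloc[0]
        raise ValueError(f"sample sheet: sample {sid!r} is in_vivo at week 0")


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet[list(SAMPLE_SHEET_COLUMNS)].to_csv(path, sep="\t", index=False)


def check_samples_match(matrix: pd.DataFrame, sheet: pd.DataFrame) -> None:
    """Raise if the matrix carries a sample absent from the sheet."""
    known = set(sheet["sample_id"])
    unknown = [c for c in matrix.columns if c not in known]
    if unknown:
        raise ValueError(f"samples {unknown} present in matrix but not in sample sheet")


# ---------------------------------------------------------------------------
# gene sets (GMT dialect)

@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (duplicates collapsed, order preserved)."""

    name: str
    description: str = ""
    members: tuple = field(default_factory=tuple)

    def __post_init__(self):
        seen, uniq = set(), []
        for m in self.members:
            if m not in seen:
                seen.add(m)
                uniq.append(m)
        object.__setattr__(self, "members", tuple(uniq))

    def __contains__(self, gene):
        return gene in set(self.members)

    def __len__(self):
        return len(self.members)


def write_gene_sets(sets, path) -> None:
    """Write gene sets as GMT: one set per line, tab-separated
    ``name<TAB>description<TAB>member...``."""
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


def read_gene_sets(path):
    sets = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"GMT {path} line {i}: expected >= 2 tab-separated fields")
            sets.append(GeneSet(fields[0], fields[1], tuple(fields[2:])))
    return sets


# ---------------------------------------------------------------------------
# Newick

def write_newick(tree, path) -> None:
    """Serialize a :class:`~metx.cluster.ClusterTree` dendrogram to Newick.

    Branch lengths are merge-height differences; leaves sit at height 0 so a
    pair merged at height h is written ``(A:h,B:h);``.
    """
    from metx.cluster import to_newick  # local import avoids cycle at import time

    if len(tree.labels) < 2:
        raise ValueError("Newick export requires a tree with >= 2 leaves")
    if len(set(tree.labels)) != len(tree.labels):
        raise ValueError("Newick export: duplicate leaf labels")
    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")
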