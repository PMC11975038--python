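"""Readers and writers for the on-disk formats.

Conventions
-----------
* matrices (beta values, counts, FPKM) are UTF-8 tab-separated files with a
  header row of sample ids and feature ids in the first column;
* sample sheets are comma-separated with one row per sample/assay;
* gene sets use the standard GMT layout (name, description, genes...);
* single-cell counts use the MatrixMarket triplet convention
  (matrix.mtx + features.tsv + barcodes.tsv, genes x cells);
* gene identifiers are uppercased symbols — the join key across expression
  matrices, probe annotation, and gene sets;
* time in culture is stored in months (the sampling unit) and converted to
  years only inside velocity computations.
"""

from __future__ import annotations

import io as _io
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import FormatError

CONDITIONS = ("in_vivo", "in_vitro_control", "metformin", "rapamycin")
CELL_TYPES = ("fibroblast", "iN")
SHEET_ASSAYS = ("dnam", "rna_bulk", "rna_sc")
PROMOTER_REGIONS = ("TSS200", "TSS1500", "UTR5", "FirstExon")
REGIONS = PROMOTER_REGIONS + ("Body", "Other")

SHEET_COLUMNS = [
    "sample_id", "donor_id", "chronological_age_at_baseline",
    "time_in_culture", "condition", "cell_type", "assay",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with an explicit unit flag."""

    values: pd.DataFrame
    unit: str  # "counts" | "fpkm"

    def __post_init__(self):
        if self.unit not in ("counts", "fpkm"):
            raise FormatError(f"unknown expression unit {self.unit!r}")
        vals = self.values.to_numpy()
        if vals.size and np.nanmin(vals) < 0:
            raise FormatError(f"negative value in {self.unit} matrix")
        if self.unit == "counts" and vals.size:
            if not np.allclose(vals, np.round(vals), atol=1e-8, equal_nan=True):
                raise FormatError("counts matrix contains non-integer values")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def log2_plus1(self) -> pd.DataFrame:
        """log2(value + 1); the scale used for correlation screens and clocks."""
        return np.log2(self.values.astype(float) + 1.0)

    def to_fpkm(self, gene_length_kb: float | pd.Series = 1.0) -> "ExpressionMatrix":
        """Convert counts to FPKM given transcript lengths in kilobases."""
        if self.unit == "fpkm":
            return self
        total = self.values.sum(axis=0).astype(float)
        if (total == 0).any():
            raise FormatError("cannot FPKM-normalize a sample with zero total counts")
        per_million = self.values.astype(float).div(total / 1e6, axis=1)
        fpkm = per_million.div(gene_length_kb, axis=0) if isinstance(
            gene_length_kb, pd.Series) else per_million / float(gene_length_kb)
        return ExpressionMatrix(fpkm, "fpkm")


@dataclass
class SparseCountMatrix:
    """Genes x cells sparse nonnegative-integer count matrix."""

    matrix: scipy.sparse.csr_matrix
    gene_ids: pd.Index
    cell_ids: pd.Index

    def __post_init__(self):
        self.matrix = scipy.sparse.csr_matrix(self.matrix)
        self.gene_ids = pd.Index(self.gene_ids)
        self.cell_ids = pd.Index(self.cell_ids)
        if self.matrix.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise FormatError("negative entry in count matrix")

    def to_dense(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix.toarray(), index=self.gene_ids, columns=self.cell_ids
        )


# ---------------------------------------------------------------------------
# beta matrices
# ---------------------------------------------------------------------------

def _read_tsv_matrix(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    if path.stat().st_size == 0:
        raise FormatError(f"{path}: empty file")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate feature id {dup!r}")
    return df


def read_beta_matrix(path) -> pd.DataFrame:
    """Read a probes x samples beta-value TSV, rejecting out-of-range values."""
    df = _read_tsv_matrix(path)
    vals = df.to_numpy(dtype=float)
    bad = np.where((vals < 0) | (vals > 1))
    if bad[0].size:
        i, j = bad[0][0], bad[1][0]
        raise FormatError(
            f"{path}: beta value {vals[i, j]} outside [0, 1] at "
            f"probe {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    return df.astype(float)


def write_beta_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="probe_id")


def read_expression_matrix(path, unit: str) -> ExpressionMatrix:
    return ExpressionMatrix(_read_tsv_matrix(path).astype(float), unit)


def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# sample sheets
# ---------------------------------------------------------------------------

def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise FormatError(f"sample sheet missing columns: {missing}")
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicate sample_id {dup!r} in sample sheet")
    if (sheet["time_in_culture"] < 0).any():
        raise FormatError("time_in_culture must be >= 0")
    bad_cond = set(sheet["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise FormatError(f"unknown condition values: {sorted(bad_cond)}")
    bad_assay = set(sheet["assay"]) - set(SHEET_ASSAYS)
    if bad_assay:
        raise FormatError(f"unknown assay values: {sorted(bad_assay)}")
    bad_ct = set(sheet["cell_type"]) - set(CELL_TYPES)
    if bad_ct:
        raise FormatError(f"unknown cell_type values: {sorted(bad_ct)}")
    return sheet


def read_sample_sheet(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise FormatError(f"{path}: missing or empty sample sheet")
    return validate_sample_sheet(pd.read_csv(path))


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    validate_sample_sheet(sheet).to_csv(path, index=False)


def check_sheet_matches_matrix(sheet: pd.DataFrame, columns, assay: str) -> None:
    """Every matrix column must have a sheet row of the given assay and vice versa."""
    sheet_ids = set(sheet.loc[sheet["assay"] == assay, "sample_id"])
    mat_ids = set(columns)
    only_mat = mat_ids - sheet_ids
    only_sheet = sheet_ids - mat_ids
    if only_mat or only_sheet:
        raise FormatError(
            f"sample sheet / matrix mismatch for assay {assay!r}: "
            f"matrix-only={sorted(only_mat)[:5]}, sheet-only={sorted(only_sheet)[:5]}"
        )


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict:
    """Read a GMT file into {set_name: [SYMBOL, ...]}; symbols are uppercased."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise FormatError(f"{path}: missing or empty GMT file")
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: gene set with no genes")
            name, genes = parts[0], [g.strip().upper() for g in parts[2:] if g.strip()]
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no genes")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = genes
    return sets


def write_gmt(sets: dict, path, descriptions: dict | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# probe annotation
# ---------------------------------------------------------------------------

def read_probe_annotation(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise FormatError(f"{path}: missing or empty probe annotation")
    annot = pd.read_csv(path, sep="\t")
    required = ["probe_id", "gene", "region"]
    missing = [c for c in required if c not in annot.columns]
    if missing:
        raise FormatError(f"{path}: probe annotation missing columns {missing}")
    bad = set(annot["region"]) - set(REGIONS)
    if bad:
        raise FormatError(f"{path}: unknown regions {sorted(bad)}")
    annot["gene"] = annot["gene"].str.upper()
    if annot.duplicated(["probe_id", "gene", "region"]).any():
        raise FormatError(f"{path}: duplicate probe-gene-region row")
    return annot


def write_probe_annotation(annot: pd.DataFrame, path) -> None:
    annot.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MatrixMarket triplets
# ---------------------------------------------------------------------------

def read_mtx_triplet(directory) -> SparseCountMatrix:
    """Read matrix.mtx + features.tsv + barcodes.tsv from a directory."""
    directory = Path(directory)
    paths = {name: directory / name
             for name in ("matrix.mtx", "features.tsv", "barcodes.tsv")}
    for name, p in paths.items():
        if not p.exists():
            raise FormatError(f"{directory}: missing {name}")
    mat = scipy.sparse.csr_matrix(scipy.io.mmread(paths["matrix.mtx"]))
    features = pd.Index(
        pd.read_csv(paths["features.tsv"], sep="\t", header=None)[0].to_numpy())
    barcodes = pd.Index(
        pd.read_csv(paths["barcodes.tsv"], sep="\t", header=None)[0].to_numpy())
    if mat.shape != (len(features), len(barcodes)):
        raise FormatError(
            f"{directory}: matrix.mtx is {mat.shape} but sidecars give "
            f"{len(features)} features x {len(barcodes)} barcodes"
        )
    if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
        raise FormatError(f"{directory}: non-integer entries in matrix.mtx")
    return SparseCountMatrix(mat, pd.Index(features), pd.Index(barcodes))


def write_mtx_triplet(counts: SparseCountMatrix, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(directory / "matrix.mtx"),
                     scipy.sparse.coo_matrix(counts.matrix), field="integer")
    # mmwrite appends .mtx if absent; normalize the name
    written = directory / "matrix.mtx.mtx"
    if written.exists():
        written.rename(directory / "matrix.mtx")
    pd.Series(counts.gene_ids).to_csv(
        directory / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(counts.cell_ids).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# JSON helpers (truth files, reports)
# ---------------------------------------------------------------------------

def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=default)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
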