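"""On-disk formats, expression normalisation and the sparse-gene prefilter.

All tabular files are TSV: UTF-8, tab separated, '.' decimal, no quoting,
case-sensitive gene identifiers.  Expression matrices are genes x samples
with a header row of sample ids and the first column holding gene ids.
Mutations are MAF-like (sample, gene, variant_class), copy number comes
either per-gene (sample, gene, log2_ratio) or as SEG-like segments
(sample, chrom, start, end, log2_ratio; 1-based inclusive), and signatures
are JSON ``{"genes": [{"id", "direction", ...}], "meta": {...}}``.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import Signature

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "write_expression",
    "filter_sparse_genes",
    "zscore_by_gene",
    "normalize_variant_class",
    "read_mutations",
    "write_mutations",
    "read_cna_genes",
    "write_cna_genes",
    "read_seg",
    "write_seg",
    "read_signature",
    "write_signature",
]

VALUE_KINDS = ("zscore", "log2")

# Closed alias table for MAF-style variant classes.  The status caller only
# distinguishes truncating / splice / missense; common none-equivalent tokens
# collapse to "other" and are ignored downstream.
_TRUNCATING = {"truncating", "nonsense", "frameshift", "stop-gain", "stop_gain",
               "nonsense_mutation", "frame_shift_del", "frame_shift_ins"}
_SPLICE = {"splice", "splice_site"}
_MISSENSE = {"missense", "missense_mutation"}
_OTHER = {"other", "none", "wt", "silent", "intron", "utr", "in_frame_del",
          "in_frame_ins", "nonstop_mutation"}
VARIANT_CLASSES = ("truncating", "splice", "missense", "other")


def normalize_variant_class(token: str) -> str:
    t = str(token).strip().lower()
    if t in _TRUNCATING:
        return "truncating"
    if t in _SPLICE:
        return "splice"
    if t in _MISSENSE:
        return "missense"
    if t in _OTHER:
        return "other"
    allowed = sorted(_TRUNCATING | _SPLICE | _MISSENSE | _OTHER)
    raise ValueError(f"unknown variant_class {token!r}; allowed tokens: {allowed}")


@dataclass
class ExpressionMatrix:
    """Gene x sample numeric matrix with a declared value kind.

    ``value_kind`` is "zscore" or "log2".  Identifiers are unique and order
    preserving; values are finite after loading.
    """

    data: pd.DataFrame
    value_kind: str

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"value_kind must be one of {VALUE_KINDS}, got {self.value_kind!r}")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")

    @property
    def genes(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise KeyError(f"unknown samples: {missing}")
        return ExpressionMatrix(self.data.loc[:, list(samples)], self.value_kind)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"unknown genes: {missing}")
        return ExpressionMatrix(self.data.loc[list(genes)], self.value_kind)


def read_expression(path, value_kind: str, impute_zero: bool = False) -> ExpressionMatrix:
    """Read a genes x samples TSV.  Duplicate ids, ragged rows and
    non-numeric cells raise with the offending line; missing cells are
    rejected unless ``impute_zero`` is set on a log2 matrix.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False,
                      na_values=[""])
    raw.index = raw.index.astype(str)
    if raw.index.duplicated().any():
        gene = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated gene row {gene!r}")
    if raw.columns.duplicated().any():
        col = raw.columns[raw.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicated sample column {col!r}")
    data = raw.apply(pd.to_numeric, errors="coerce")
    bad = data.isna() & raw.notna()
    if bad.to_numpy().any():
        g = bad.index[bad.any(axis=1)][0]
        s = bad.columns[bad.loc[g]][0]
        line = data.index.get_loc(g) + 2  # header is line 1
        raise ValueError(
            f"{path}: non-numeric cell {raw.loc[g, s]!r} for gene {g!r}, sample {s!r} (line {line})"
        )
    if data.isna().to_numpy().any():
        if impute_zero and value_kind == "log2":
            data = data.fillna(0.0)
        else:
            g = data.index[data.isna().any(axis=1)][0]
            line = data.index.get_loc(g) + 2
            raise ValueError(f"{path}: missing cell in gene row {g!r} (line {line})")
    data = data.astype(float)
    data.index.name = None
    data.columns.name = None
    return ExpressionMatrix(data, value_kind)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene")


def filter_sparse_genes(matrix: ExpressionMatrix, max_zero_frac: float = 0.75) -> ExpressionMatrix:
    """Drop genes whose fraction of zero values is strictly greater than
    ``max_zero_frac`` (default: >75% zeros).  Zeros are only meaningful on
    the log2 scale; z-score input is returned unchanged with a warning.
    """
    if matrix.value_kind != "log2":
        warnings.warn("sparse-gene filter skipped: zeros are not meaningful on z-score input")
        return matrix
    zero_frac = (matrix.data == 0).mean(axis=1)
    keep = zero_frac <= max_zero_frac
    return ExpressionMatrix(matrix.data.loc[keep], matrix.value_kind)


def zscore_by_gene(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each gene row to mean 0 / SD 1 (population SD, n in the
    denominator).  Constant genes have no z-score and raise; drop them first
    (e.g. with :func:`filter_sparse_genes`) if they are expected.
    """
    if len(matrix.samples) < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    x = matrix.values
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)  # population SD
    constant = np.flatnonzero(sd.ravel() == 0)
    if constant.size:
        names = [matrix.genes[i] for i in constant]
        raise ValueError(f"constant genes cannot be z-scored: {names}")
    z = (x - mu) / sd
    return ExpressionMatrix(
        pd.DataFrame(z, index=matrix.data.index, columns=matrix.data.columns), "zscore"
    )


def read_mutations(path) -> pd.DataFrame:
    """MAF-like table (sample, gene, variant_class); classes are normalized
    through the alias table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["sample", "gene", "variant_class"], path)
    df["variant_class"] = df["variant_class"].map(normalize_variant_class)
    return df[["sample", "gene", "variant_class"]]


def write_mutations(df: pd.DataFrame, path) -> None:
    df[["sample", "gene", "variant_class"]].to_csv(path, sep="\t", index=False)


def read_cna_genes(path) -> pd.DataFrame:
    """Per-gene copy-number table (sample, gene, log2_ratio)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["sample", "gene", "log2_ratio"], path)
    df["log2_ratio"] = pd.to_numeric(df["log2_ratio"])
    if not np.isfinite(df["log2_ratio"]).all():
        raise ValueError(f"{path}: non-finite log2_ratio values")
    return df[["sample", "gene", "log2_ratio"]]


def write_cna_genes(df: pd.DataFrame, path) -> None:
    df[["sample", "gene", "log2_ratio"]].to_csv(path, sep="\t", index=False)


def read_seg(path) -> pd.DataFrame:
    """SEG-like segments (sample, chrom, start, end, log2_ratio), 1-based
    inclusive coordinates with start <= end."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["sample", "chrom", "start", "end", "log2_ratio"], path)
    df["start"] = pd.to_numeric(df["start"], downcast="integer")
    df["end"] = pd.to_numeric(df["end"], downcast="integer")
    df["log2_ratio"] = pd.to_numeric(df["log2_ratio"])
    bad = df["end"] < df["start"]
    if bad.any():
        row = df.index[bad][0] + 2
        raise ValueError(f"{path}: segment end < start at line {row}")
    return df[["sample", "chrom", "start", "end", "log2_ratio"]]


def write_seg(df: pd.DataFrame, path) -> None:
    df[["sample", "chrom", "start", "end", "log2_ratio"]].to_csv(path, sep="\t", index=False)


def read_signature(path) -> Signature:
    with open(path) as fh:
        payload = json.load(fh)
    genes = [entry["id"] for entry in payload["genes"]]
    directions = {entry["id"]: int(entry["direction"]) for entry in payload["genes"]}
    mean_z = {
        entry["id"]: float(entry["mean_z"])
        for entry in payload["genes"]
        if "mean_z" in entry
    }
    return Signature(
        genes=genes,
        directions=directions,
        mean_z=mean_z,
        meta=payload.get("meta", {}),
        valid=payload.get("valid", True),
    )


def write_signature(signature: Signature, path) -> None:
    entries = []
    for g in signature.genes:
        entry = {"id": g, "direction": int(signature.directions[g])}
        if g in signature.mean_z:
            entry["mean_z"] = signature.mean_z[g]
        entries.append(entry)
    payload = {"genes": entries, "meta": signature.meta, "valid": signature.valid}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
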