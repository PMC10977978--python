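"""Tabular readers, writers, and schema validation.

Fixed dialect throughout: UTF-8, tab-separated values with a header row,
``NA`` for missing, decimal point only, ``#``-prefixed comment lines for
provenance (seed, config hash).  Floats are written with 10+ significant
digits so every writer/reader pair round-trips losslessly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scipy_io

__all__ = [
    "ValidationError",
    "ValidationReport",
    "read_fish_cells",
    "read_counts_tsv",
    "read_counts_mtx",
    "read_sample_metadata",
    "read_if_cells",
    "read_allele_counts",
    "write_table",
    "write_json",
    "config_hash",
]

FLOAT_FORMAT = "%.10g"
TIMEPOINTS = {"pre", "post"}
BIOPSY_INDICES = {"1", "2", "surgical"}


class ValidationError(ValueError):
    """Hard schema failure; the message names the file, column, and row."""


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_if_failed(self) -> None:
        if self.errors:
            raise ValidationError("; ".join(self.errors))


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, comment="#", dtype=str, keep_default_na=False,
                       na_values=["NA"])


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")


def _to_int(df: pd.DataFrame, col: str, path, minimum: int = 0) -> pd.Series:
    try:
        values = pd.to_numeric(df[col], errors="raise")
    except (ValueError, TypeError):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
        raise ValidationError(f"{path}: column {col!r} non-numeric at row {bad + 2}")
    if (values % 1 != 0).any():
        bad = df.index[values % 1 != 0][0]
        raise ValidationError(f"{path}: column {col!r} non-integer at row {bad + 2}")
    if (values < minimum).any():
        bad = df.index[values < minimum][0]
        raise ValidationError(
            f"{path}: column {col!r} below {minimum} at row {bad + 2}"
        )
    return values.astype(int)


def read_fish_cells(path) -> pd.DataFrame:
    """Read and validate a per-cell FISH count table (TSV/CSV)."""
    df = _read_tsv(path)
    _require_columns(df, ["patient_id", "timepoint", "area_id", "erbb2", "cep17"], path)
    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"].astype(str),
            "timepoint": df["timepoint"].astype(str).str.strip().str.lower(),
            "area_id": df["area_id"].astype(str),
            "erbb2": _to_int(df, "erbb2", path),
            "cep17": _to_int(df, "cep17", path),
        }
    )
    bad_tp = ~out["timepoint"].isin(TIMEPOINTS)
    if bad_tp.any():
        row = out.index[bad_tp][0]
        raise ValidationError(
            f"{path}: timepoint must be pre/post at row {row + 2}, "
            f"got {out.loc[row, 'timepoint']!r}"
        )
    if (out["patient_id"].str.len() == 0).any() or (out["area_id"].str.len() == 0).any():
        raise ValidationError(f"{path}: empty patient_id or area_id")
    return out


def read_counts_tsv(path) -> pd.DataFrame:
    """Genes x samples raw count matrix from TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.index.duplicated().any():
        raise ValidationError(f"{path}: duplicate gene identifiers")
    if df.columns.duplicated().any():
        raise ValidationError(f"{path}: duplicate sample identifiers")
    values = df.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        raise ValidationError(f"{path}: non-numeric count values")
    if (values < 0).any().any():
        raise ValidationError(f"{path}: negative count values")
    return values.astype(np.int64)


def read_counts_mtx(mtx_path, genes_path, samples_path) -> pd.DataFrame:
    """Genes x samples counts from MatrixMarket triplet + sidecar name files."""
    matrix = scipy_io.mmread(mtx_path).toarray()
    genes = [l.strip() for l in Path(genes_path).read_text().splitlines() if l.strip()]
    samples = [l.strip() for l in Path(samples_path).read_text().splitlines() if l.strip()]
    if matrix.shape != (len(genes), len(samples)):
        raise ValidationError(
            f"{mtx_path}: shape {matrix.shape} does not match sidecar files "
            f"({len(genes)} genes, {len(samples)} samples)"
        )
    if (matrix < 0).any():
        raise ValidationError(f"{mtx_path}: negative count values")
    return pd.DataFrame(matrix.astype(np.int64), index=genes, columns=samples)


def read_sample_metadata(path) -> pd.DataFrame:
    """Sample metadata keyed by sample_id; validates enums where present."""
    df = _read_tsv(path)
    _require_columns(df, ["sample_id", "patient_id", "timepoint"], path)
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample_id")
    df["timepoint"] = df["timepoint"].astype(str).str.strip().str.lower()
    if (~df["timepoint"].isin(TIMEPOINTS)).any():
        raise ValidationError(f"{path}: timepoint values must be pre/post")
    if "biopsy_index" in df.columns:
        present = df["biopsy_index"].dropna().astype(str)
        if (~present.isin(BIOPSY_INDICES)).any():
            raise ValidationError(f"{path}: biopsy_index must be 1/2/surgical")
    for col in ("pcr", "het"):
        if col in df.columns:
            df[col] = df[col].astype(str).str.lower().isin({"true", "1", "yes"})
    for col in ("rcb_score", "age"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df.set_index("sample_id")


def read_if_cells(path) -> pd.DataFrame:
    """Per-cell immunofluorescence intensity table (CSV/TSV)."""
    df = _read_tsv(path)
    _require_columns(df, ["cell_id", "tumor_id", "her2_intensity", "ck5_intensity"], path)
    out = df.copy()
    for col in ("her2_intensity", "ck5_intensity"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = df.index[vals.isna()][0]
            raise ValidationError(f"{path}: column {col!r} non-numeric at row {row + 2}")
        if (vals < 0).any() or ~np.isfinite(vals).all():
            raise ValidationError(f"{path}: column {col!r} must be finite and >= 0")
        out[col] = vals.astype(float)
    return out


def read_allele_counts(path) -> pd.DataFrame:
    """Per-site allele counts (sample_id, gene, codon_label, depth, alt_count)."""
    df = _read_tsv(path)
    _require_columns(df, ["sample_id", "gene", "codon_label", "depth", "alt_count"], path)
    out = df.copy()
    out["depth"] = _to_int(df, "depth", path)
    out["alt_count"] = _to_int(df, "alt_count", path)
    over = out["alt_count"] > out["depth"]
    if over.any():
        row = out.index[over][0]
        raise ValidationError(f"{path}: alt_count exceeds depth at row {row + 2}")
    return out


def write_table(df: pd.DataFrame, path, header_comments: "list[str] | None" = None,
                index: bool = False) -> None:
    """Write a TSV with 10-significant-digit floats and provenance comments."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", float_format=FLOAT_FORMAT, na_rep="NA", index=index)


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n",
                    encoding="utf-8")


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping, for output provenance."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
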