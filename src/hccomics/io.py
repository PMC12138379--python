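"""Readers and writers for the tabular formats the pipeline touches.

All matrices are oriented features x samples. Missing values are
serialized as ``NA`` in TSV. Gene sets use the standard GMT layout
(name, description, then one gene per tab-separated field).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GeneSet",
    "GmtParseError",
    "read_gmt",
    "write_gmt",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_probe_manifest",
    "write_probe_manifest",
    "read_gistic_lesions",
    "read_maf_lite",
]

VALID_CHROMOSOMES = {str(i) for i in range(1, 23)} | {"X", "Y"}


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene symbols (GMT line)."""

    name: str
    description: str = ""
    genes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r}: duplicate genes")
        if not self.genes:
            raise ValueError(f"gene set {self.name!r}: empty gene list")


class GmtParseError(ValueError):
    pass


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file into a list of :class:`GeneSet`.

    Duplicate gene entries within a line are collapsed (first occurrence
    kept). Lines with fewer than 3 tab-separated fields raise
    :class:`GmtParseError` naming the offending line.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(f"line {lineno}: fewer than 3 fields")
            name, desc = fields[0], fields[1]
            seen: dict[str, None] = {}
            for g in fields[2:]:
                if g and g not in seen:
                    seen[g] = None
            sets.append(GeneSet(name=name, description=desc, genes=tuple(seen)))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def read_matrix_tsv(path: str | Path, index_name: str | None = None) -> pd.DataFrame:
    """Read a features x samples TSV (first column = row ids, ``NA`` = missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"],
                     keep_default_na=False, float_precision="round_trip")
    if index_name is not None:
        df.index.name = index_name
    return df


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a features x samples TSV, ``NA`` for missing entries.

    Floats are serialized with Python's shortest round-trip repr so a
    write/read cycle reproduces values bit-exactly.
    """
    df.to_csv(path, sep="\t", na_rep="NA")


MANIFEST_COLUMNS = ["chromosome", "tss_distance", "gene", "snp_associated"]


def read_probe_manifest(path: str | Path) -> pd.DataFrame:
    """Read a probe manifest: probe_id, chromosome, tss_distance, gene, snp_associated.

    ``tss_distance`` is signed bp relative to the nearest transcription
    start site; downstream promoter tests use its absolute value.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={"chromosome": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate probe ids: {dups[:5]}")
    bad = set(df["chromosome"].astype(str)) - VALID_CHROMOSOMES
    if bad:
        raise ValueError(f"invalid chromosomes in manifest: {sorted(bad)[:5]}")
    df["snp_associated"] = df["snp_associated"].astype(bool)
    df["tss_distance"] = df["tss_distance"].astype(int)
    return df


def write_probe_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, sep="\t")


# Descriptor columns recognized in GISTIC-style lesion tables; anything
# else (besides the descriptor itself) is treated as a sample column.
_GISTIC_META_COLS = (
    "Descriptor",
    "Wide Peak Limits",
    "Peak Limits",
    "Region Limits",
    "q values",
    "Residual q values after removing segments shared with higher peaks",
    "Broad or Focal",
    "Amplitude Threshold",
    "n Genes",
)


def read_gistic_lesions(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a GISTIC ``new_all_lesions``-style table.

    Returns ``(values, meta)``: ``values`` is the lesion x sample numeric
    matrix (continuous CN or discrete calls, retained verbatim — the
    caller chooses which file dialect it feeds in), ``meta`` has per-lesion
    ``type`` (amp|del, parsed from the "Amplification"/"Deletion" prefix of
    the lesion name), ``level`` (focal|arm, from the "Broad or Focal"
    column when present, else focal) and ``gene_count`` (from "n Genes"
    when present, else missing).
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    meta_cols = [c for c in raw.columns if c in _GISTIC_META_COLS]
    sample_cols = [c for c in raw.columns if c not in _GISTIC_META_COLS]
    if not sample_cols:
        raise ValueError("lesion table has no sample columns")

    types = []
    for name in raw.index:
        low = str(name).lower()
        if low.startswith("amplification"):
            types.append("amp")
        elif low.startswith("deletion"):
            types.append("del")
        else:
            raise ValueError(f"unknown lesion type in descriptor {name!r}")

    values = raw[sample_cols].copy()
    for col in sample_cols:
        converted = pd.to_numeric(values[col], errors="coerce")
        bad = converted.isna() & values[col].notna()
        if bad.any():
            row = values.index[bad.argmax()]
            raise ValueError(f"non-numeric value at lesion {row!r}, sample {col!r}")
        values[col] = converted
    values = values.astype(float)

    meta = pd.DataFrame(index=raw.index)
    meta["type"] = types
    if "Broad or Focal" in meta_cols:
        meta["level"] = raw["Broad or Focal"].map(
            lambda v: "arm" if str(v).strip().lower() in ("broad", "arm") else "focal"
        )
    else:
        meta["level"] = "focal"
    if "n Genes" in meta_cols:
        meta["gene_count"] = pd.to_numeric(raw["n Genes"], errors="coerce")
    else:
        meta["gene_count"] = np.nan
    return values, meta


def read_maf_lite(
    path: str | Path, classifications: set[str] | None = None
) -> pd.DataFrame:
    """Read a MAF-lite TSV (gene, sample, classification) into a binary matrix.

    Entry is 1 iff at least one retained record exists for the
    (gene, sample) pair. ``classifications`` optionally restricts which
    record classes are retained (default: all records in the file).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene", "sample"):
        if col not in df.columns:
            raise ValueError(f"MAF-lite file missing column {col!r}")
    if classifications is not None:
        if "classification" not in df.columns:
            raise ValueError("classification filter given but column absent")
        df = df[df["classification"].isin(classifications)]
    if df.empty:
        warnings.warn("MAF-lite file has no retained records; empty matrix")
        return pd.DataFrame(dtype=int)
    if df[["gene", "sample"]].isna().any().any():
        raise ValueError("MAF-lite record with empty gene or sample")
    mat = pd.crosstab(df["gene"], df["sample"])
    mat = (mat > 0).astype(int)
    mat.index.name = "gene"
    mat.columns.name = None
    return mat
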