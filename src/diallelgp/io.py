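"""Readers and writers for the package's plain-text interchange formats.

* Pedigree CSV: ``clone_id, sire_id, dam_id, cytoplasm_type`` ("0" = unknown
  parent).
* Phenotype CSV (long format): ``clone_id, trait, value, year, block,
  replicate``; empty field = missing value.
* Dosage TSV: first column ``clone_id``, remaining columns marker dosages on
  the 0-4 scale, ``NA`` for missing.
* Relationship-matrix TSV: square table with clone ids as header row and
  first column.
* Raw dry-matter CSV: ``clone_id, year, replicate, weight_air_kg,
  weight_water_kg``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .kinship import RelationshipMatrix

__all__ = [
    "read_pedigree", "write_pedigree",
    "read_phenotypes", "write_phenotypes",
    "read_dosages", "write_dosages",
    "read_matrix", "write_matrix",
    "read_dry_matter_raw", "read_dosage_vcf",
]


def read_pedigree(path) -> pd.DataFrame:
    ped = pd.read_csv(path, dtype=str).fillna("0")
    required = {"clone_id", "sire_id", "dam_id"}
    missing = required - set(ped.columns)
    if missing:
        raise ValueError(f"pedigree file lacks columns: {sorted(missing)}")
    return ped


def write_pedigree(ped: pd.DataFrame, path) -> None:
    ped.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"clone_id", "trait", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype file lacks columns: {sorted(missing)}")
    df["clone_id"] = df["clone_id"].astype(str)
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    for col, default in (("year", 0), ("block", "B1"), ("replicate", 1)):
        if col not in df:
            df[col] = default
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_dosages(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    df.index.name = "clone_id"
    return df.astype(float)


def write_dosages(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.insert(0, "clone_id", out.index.astype(str))
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_matrix(path, kind: str = "A") -> RelationshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValueError("matrix file row/column ids disagree")
    return RelationshipMatrix(df.to_numpy(float), list(df.index), kind)


def write_matrix(M: RelationshipMatrix, path) -> None:
    M.to_frame().to_csv(path, sep="\t")


def read_dry_matter_raw(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"clone_id", "weight_air_kg", "weight_water_kg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"raw dry-matter file lacks columns: {sorted(missing)}")
    df["clone_id"] = df["clone_id"].astype(str)
    return df


def read_dosage_vcf(path, dosage_field: str = "DS") -> pd.DataFrame:
    """Dosage matrix from a VCF carrying a per-sample dosage FORMAT field.

    The field is interpreted on the 0-4 (tetraploid alternate-allele dosage)
    scale; missing values become NaN.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    markers, columns = [], []
    for var in vcf:
        vals = var.format(dosage_field)
        if vals is None:
            continue
        v = np.asarray(vals, dtype=float).reshape(len(samples), -1)[:, 0]
        v = np.where((v < 0) | (v > 4), np.nan, v)
        markers.append(v)
        columns.append(var.ID or f"{var.CHROM}:{var.POS}")
    if not markers:
        raise ValueError(f"no variants with FORMAT field {dosage_field!r}")
    return pd.DataFrame(np.column_stack(markers), index=samples,
                        columns=columns)
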