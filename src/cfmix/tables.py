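"""Plain-text tables: allele-depth, sex-region depth and genotype TSVs.

All files are tab-separated with a declared header line; lines starting with
``#`` are metadata (config hash, seed) and are ignored on read. Genotypes are
coded 0/1/2 alt-allele copies with ``NA`` for missing.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .panel import Panel

__all__ = [
    "write_depth_table",
    "read_depth_table",
    "write_sex_depth_table",
    "read_sex_depth_table",
    "write_genotype_table",
    "read_genotype_table",
    "sample_depths",
]

DEPTH_COLUMNS = ["sample_id", "region_id", "ref_count", "alt_count"]
SEX_DEPTH_COLUMNS = ["sample_id", "region_id", "depth"]
GENOTYPE_COLUMNS = ["sample_id", "region_id", "genotype"]


def _write_header(fh, columns: list[str], metadata: Mapping[str, str] | None) -> None:
    if metadata:
        meta = " ".join(f"{k}={v}" for k, v in metadata.items())
        fh.write(f"# cfmix {meta}\n")
    fh.write("\t".join(columns) + "\n")


def _read_tsv(path: Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    if list(df.columns) != columns:
        raise ValueError(f"{path}: expected columns {columns}, got {list(df.columns)}")
    return df


def _check_regions(df: pd.DataFrame, panel: Panel | None, path: Path) -> None:
    if panel is None:
        return
    known = {r.region_id for r in panel.regions}
    unknown = sorted(set(df["region_id"]) - known)
    if unknown:
        raise ValueError(f"{path}: unknown region_id(s) not in panel: {unknown[:5]}")


def write_depth_table(
    depths: pd.DataFrame, path: str | Path, metadata: Mapping[str, str] | None = None
) -> None:
    """Write a long allele-depth table (`sample_id region_id ref_count alt_count`)."""
    df = depths.reset_index() if depths.index.name else depths
    with open(path, "w") as fh:
        _write_header(fh, DEPTH_COLUMNS, metadata)
        df[DEPTH_COLUMNS].to_csv(fh, sep="\t", header=False, index=False)


def read_depth_table(path: str | Path, panel: Panel | None = None) -> pd.DataFrame:
    """Read an allele-depth table; validates counts and (optionally) region ids."""
    path = Path(path)
    df = _read_tsv(path, DEPTH_COLUMNS)
    for col in ("ref_count", "alt_count"):
        try:
            df[col] = df[col].astype(np.int64)
        except ValueError as exc:
            raise ValueError(f"{path}: non-integer {col}: {exc}") from exc
        neg = df.index[df[col] < 0]
        if len(neg):
            raise ValueError(f"{path}: negative {col} at data row {neg[0] + 1}")
    _check_regions(df, panel, path)
    return df


def write_sex_depth_table(
    depths: pd.DataFrame, path: str | Path, metadata: Mapping[str, str] | None = None
) -> None:
    df = depths.reset_index() if depths.index.name else depths
    with open(path, "w") as fh:
        _write_header(fh, SEX_DEPTH_COLUMNS, metadata)
        df[SEX_DEPTH_COLUMNS].to_csv(fh, sep="\t", header=False, index=False)


def read_sex_depth_table(path: str | Path, panel: Panel | None = None) -> pd.DataFrame:
    path = Path(path)
    df = _read_tsv(path, SEX_DEPTH_COLUMNS)
    try:
        df["depth"] = df["depth"].astype(np.int64)
    except ValueError as exc:
        raise ValueError(f"{path}: non-integer depth: {exc}") from exc
    if (df["depth"] < 0).any():
        row = df.index[df["depth"] < 0][0]
        raise ValueError(f"{path}: negative depth at data row {row + 1}")
    _check_regions(df, panel, path)
    return df


def write_genotype_table(
    genotypes: pd.DataFrame, path: str | Path, metadata: Mapping[str, str] | None = None
) -> None:
    """Write a samples x loci genotype matrix as a long TSV with NA for missing."""
    long = genotypes.stack(future_stack=True).reset_index()
    long.columns = GENOTYPE_COLUMNS
    long["genotype"] = long["genotype"].map(
        lambda g: "NA" if pd.isna(g) else str(int(g))
    )
    with open(path, "w") as fh:
        _write_header(fh, GENOTYPE_COLUMNS, metadata)
        long.to_csv(fh, sep="\t", header=False, index=False)


def read_genotype_table(path: str | Path, panel: Panel | None = None) -> pd.DataFrame:
    """Read a genotype TSV back into a samples x loci Int8 matrix."""
    path = Path(path)
    df = _read_tsv(path, GENOTYPE_COLUMNS)
    bad = ~df["genotype"].isin(["0", "1", "2", "NA"])
    if bad.any():
        row = df.index[bad][0]
        raise ValueError(
            f"{path}: data row {row + 1}: genotype {df['genotype'][row]!r} "
            "not one of 0/1/2/NA"
        )
    _check_regions(df, panel, path)
    df["genotype"] = df["genotype"].map(lambda v: pd.NA if v == "NA" else int(v))
    wide = df.pivot(index="sample_id", columns="region_id", values="genotype")
    wide = wide.astype("Int8")
    wide.index.name = None
    wide.columns.name = None
    # preserve first-appearance order of samples and loci
    wide = wide.loc[
        list(dict.fromkeys(df["sample_id"])), list(dict.fromkeys(df["region_id"]))
    ]
    return wide


def sample_depths(depths: pd.DataFrame, sample_id: str) -> pd.DataFrame:
    """Single-sample view of a long depth table, indexed by region_id."""
    sub = depths[depths["sample_id"] == sample_id]
    if sub.empty:
        raise ValueError(f"no rows for sample {sample_id!r}")
    return sub.set_index("region_id")[["ref_count", "alt_count"]]
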