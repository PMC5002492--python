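"""CSV interchange for compositions, SBP designs and generated datasets.

Conventions
-----------
* All tables are plain CSV with a header row.
* Composition tables are tidy: one specimen per row; metadata columns
  (``id, tissue, year, treatment, block, ...``) precede part concentration
  columns.  Macronutrients are in g kg⁻¹ dry mass; boron (and other trace
  parts) in mg kg⁻¹ on disk, converted to g kg⁻¹ on load and back on write.
  A missing filling value column is computed on load as scale − Σ parts.
* SBP tables have part-name columns with entries in {−1, 0, 1} and an
  optional leading label column.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .composition import DEFAULT_SCALE, FILLING_PART, SbpTable
from .reference import MICRO_ELEMENTS

__all__ = [
    "META_COLUMNS",
    "read_sbp",
    "write_sbp",
    "read_compositions",
    "write_compositions",
    "write_dataset",
]

#: columns never interpreted as composition parts
META_COLUMNS = (
    "id", "tissue", "year", "treatment", "block", "source",
    "dose_mg_ha", "yield_mg_ha", "latent_class", "category",
)


def read_sbp(path: str | Path) -> SbpTable:
    """Read an SBP contrast table from CSV (optional first label column)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"SBP file not found: {path}")
    return SbpTable.from_frame(pd.read_csv(path))


def write_sbp(sbp: SbpTable, path: str | Path) -> Path:
    path = Path(path)
    sbp.to_frame().to_csv(path, index=False)
    return path


def part_columns(df: pd.DataFrame) -> list[str]:
    """Columns of ``df`` holding part concentrations (non-metadata)."""
    return [c for c in df.columns if c not in META_COLUMNS]


def read_compositions(
    path: str | Path,
    scale: float = DEFAULT_SCALE,
    mg_parts: Iterable[str] = MICRO_ELEMENTS,
) -> pd.DataFrame:
    """Load a tidy composition table; returns metadata + parts in g kg⁻¹.

    Parts listed in ``mg_parts`` are converted from mg kg⁻¹.  When the
    filling value column is absent it is computed per specimen; a specimen
    whose analyzed parts already exceed the scale raises (unit error).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"composition file not found: {path}")
    df = pd.read_csv(path)
    parts = part_columns(df)
    if not parts:
        raise ValueError(f"{path} has no part concentration columns")
    mg_parts = set(mg_parts)
    for col in parts:
        df[col] = pd.to_numeric(df[col])
        if col in mg_parts:
            df[col] = df[col] / 1000.0
        if (df[col] <= 0).any():
            bad = df.index[df[col] <= 0][0]
            raise ValueError(f"nonpositive {col} in row {bad} of {path}")
    if FILLING_PART not in parts:
        total = df[parts].sum(axis=1)
        if (total >= scale).any():
            bad = df.index[total >= scale][0]
            raise ValueError(
                f"row {bad} of {path}: analyzed parts sum to {total[bad]:.4g} "
                f"≥ scale {scale}; check units (is B in mg kg⁻¹?)"
            )
        df[FILLING_PART] = scale - total
    return df


def write_compositions(
    df: pd.DataFrame,
    path: str | Path,
    mg_parts: Iterable[str] = MICRO_ELEMENTS,
) -> Path:
    """Write a composition table, re-reporting trace parts in mg kg⁻¹."""
    path = Path(path)
    out = df.copy()
    for col in part_columns(out):
        if col in set(mg_parts):
            out[col] = out[col] * 1000.0
    out.to_csv(path, index=False)
    return path


def write_dataset(dataset, outdir: str | Path) -> dict[str, Path]:
    """Write a generated orchard dataset as the CSVs the pipeline consumes.

    Emits ``compositions.csv`` (leaf and fruit rows), ``yields.csv``,
    ``treatments.csv`` (per-year application schedule) and
    ``amendments.csv`` (per-year waste analyses, lab units).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = dataset.specimens

    def _tissue_frame(comp: pd.DataFrame, tissue: str) -> pd.DataFrame:
        meta = spec[["id", "year", "treatment", "block"]].copy()
        meta.insert(1, "tissue", tissue)
        return pd.concat([meta.reset_index(drop=True),
                          comp.reset_index(drop=True)], axis=1)

    comps = pd.concat(
        [_tissue_frame(dataset.foliar, "leaf"),
         _tissue_frame(dataset.fruit, "fruit")],
        ignore_index=True,
    )
    paths = {
        "compositions": write_compositions(comps, outdir / "compositions.csv",
                                           mg_parts=("B",)),
    }

    yields = spec[["id", "year", "block", "treatment", "yield_mg_ha"]]
    yields.to_csv(outdir / "yields.csv", index=False)
    paths["yields"] = outdir / "yields.csv"

    trt = dataset.config.treatments()
    schedule = []
    for year in range(1, dataset.config.years + 1):
        for _, row in trt.iterrows():
            schedule.append((row["treatment"], year, row["source"],
                             row["dose_mg_ha"]))
    pd.DataFrame(schedule,
                 columns=["treatment", "year", "source", "dose_mg_ha"]
                 ).to_csv(outdir / "treatments.csv", index=False)
    paths["treatments"] = outdir / "treatments.csv"

    dataset.amendments.to_csv(outdir / "amendments.csv", index=False)
    paths["amendments"] = outdir / "amendments.csv"
    return paths


def read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    """Read a CSV and check the required columns are present."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path} is missing columns {missing}")
    return df
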