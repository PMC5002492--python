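"""End-to-end pipeline driver: ilr → diagnosis → ranges → budget.

The driver reads the CSV inputs (or a directory written by the synthetic
generator), runs each stage, and writes tabular outputs plus a manifest
echoing the configuration, so identical configurations yield byte-identical
outputs.  Any stage failure is re-raised with the stage name attached.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .budget import cumulate_budget, fruit_removal, mineral_input, waste_input, AmendmentBatch
from .composition import DEFAULT_SCALE, compositional_mean, ilr_transform, sbp_to_basis
from .io import part_columns, read_compositions, read_sbp, read_table
from .model import NutrientDiagnosis
from .ranges import critical_values, redfield_ratio_range
from .reference import BUDGET_ELEMENTS, default_sbp

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths and parameters driving one pipeline run."""

    compositions: str | Path
    yields: str | Path
    treatments: str | Path
    amendments: str | Path
    outdir: str | Path
    sbp: str | Path | None = None        # None = packaged default design
    cutoff: float | str = "median"       # Mg ha⁻¹, or "median"
    scale: float = DEFAULT_SCALE
    alpha: float = 0.05
    n_draws: int = 100_000
    folds: int = 10
    seed: int = 42
    knn_grid: Mapping[str, Sequence] = field(default_factory=lambda: {
        "k": [5, 10], "minkowski_p": [2.0, 4.0], "kernel": ["optimal"]})
    dm_fraction: float = 0.11

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = Path(path).parent
        for key in ("compositions", "yields", "treatments", "amendments",
                    "sbp", "outdir"):
            if raw.get(key) is not None:
                raw[key] = str((base / raw[key]).resolve()
                               if not Path(raw[key]).is_absolute()
                               else raw[key])
        return cls(**raw)

    def validate(self) -> None:
        for key in ("compositions", "yields", "treatments", "amendments"):
            p = Path(getattr(self, key))
            if not p.exists():
                raise FileNotFoundError(f"{key} file not found: {p}")
        if self.sbp is not None and not Path(self.sbp).exists():
            raise FileNotFoundError(f"sbp file not found: {self.sbp}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_draws < 1 or self.folds < 2:
            raise ValueError("n_draws ≥ 1 and folds ≥ 2 required")


def _log(message: str, verbose: bool) -> None:
    if verbose:
        print(f"[nutribalance] {message}", file=sys.stderr)


def run_pipeline(config: PipelineConfig, verbose: bool = False) -> dict:
    """Execute all stages and write outputs; returns paths and key objects."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    stage = "ilr"
    try:
        _log("computing balances", verbose)
        sbp = read_sbp(config.sbp) if config.sbp is not None else default_sbp()
        basis = sbp_to_basis(sbp)
        comps = read_compositions(config.compositions, config.scale)
        leaf = comps[comps["tissue"] == "leaf"].reset_index(drop=True)
        if leaf.empty:
            raise ValueError("no leaf specimens in the composition table")
        balances = ilr_transform(leaf, basis)
        balances.insert(0, "id", leaf["id"].to_numpy())
        balances.to_csv(outdir / "balances.csv", index=False)
        outputs["balances"] = outdir / "balances.csv"
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        raise PipelineError(stage, exc) from exc

    stage = "diagnose"
    try:
        _log("knn diagnosis", verbose)
        yields_df = read_table(config.yields, ["id", "yield_mg_ha"])
        merged = leaf[["id"]].merge(yields_df, on="id", how="left")
        if merged["yield_mg_ha"].isna().any():
            missing = merged.loc[merged["yield_mg_ha"].isna(), "id"].iloc[0]
            raise ValueError(f"no yield recorded for specimen {missing!r}")
        y = merged["yield_mg_ha"].to_numpy(dtype=float)
        cutoff = (float(np.median(y)) if config.cutoff == "median"
                  else float(config.cutoff))
        model = NutrientDiagnosis(balances.drop(columns="id"), y, cutoff, basis)
        results = model.fit(grid=config.knn_grid, folds=config.folds,
                            seed=config.seed)
        table = results.specimen_table()
        table.insert(0, "id", leaf["id"].to_numpy())
        table.to_csv(outdir / "diagnosis.csv", index=False)
        metrics = pd.Series({**results.metrics,
                             "cv_accuracy": results.cv_accuracy,
                             "cutoff_mg_ha": cutoff,
                             **{f"n_{k.lower()}": v for k, v in
                                results.partition.to_series().items()}})
        metrics.rename_axis("metric").rename("value").to_csv(
            outdir / "metrics.csv")
        outputs["diagnosis"] = outdir / "diagnosis.csv"
        outputs["metrics"] = outdir / "metrics.csv"
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "ranges"
    try:
        _log("Monte-Carlo concentration ranges", verbose)
        frames = []
        crit = None
        groups = [g for g in ("TN", "TP")
                  if results.group_members(g).size >= 2]
        group_ranges = {
            g: results.concentration_ranges(g, config.alpha,
                                            scale=config.scale,
                                            n_draws=config.n_draws,
                                            seed=config.seed)
            for g in groups
        }
        if {"TN", "TP"} <= set(group_ranges):
            crit = critical_values(group_ranges["TN"], group_ranges["TP"])
        for g, rg in group_ranges.items():
            frame = rg.to_frame().reset_index()
            frame["critical_value"] = [
                (crit or {}).get(p) for p in frame["nutrient"]
            ]
            frames.append(frame)
        ranges_df = pd.concat(frames, ignore_index=True)
        ranges_df.to_csv(outdir / "ranges.csv", index=False)
        outputs["ranges"] = outdir / "ranges.csv"
        np_ratio = {
            g: redfield_ratio_range(
                leaf.iloc[results.group_members(g)][["N", "P"]])
            for g in groups
        }
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "budget"
    try:
        _log("budget balance sheets", verbose)
        treatments = read_table(config.treatments,
                                ["treatment", "year", "source", "dose_mg_ha"])
        amendments = read_table(config.amendments, ["year", "source"])
        fruit = comps[comps["tissue"] == "fruit"].reset_index(drop=True)
        spec_meta = leaf[["id", "treatment", "year"]].merge(
            yields_df[["id", "yield_mg_ha"]], on="id", how="left")
        sheets = []
        for treatment, schedule in treatments.groupby("treatment", sort=True):
            cycles = []
            for _, row in schedule.sort_values("year").iterrows():
                year, source = row["year"], row["source"]
                if source == "mineral":
                    inputs = mineral_input()
                else:
                    batch_rows = amendments[(amendments["year"] == year)
                                            & (amendments["source"] == source)]
                    if batch_rows.empty:
                        raise ValueError(
                            f"no amendment analysis for {source} in year {year}")
                    contents = batch_rows.iloc[0].drop(
                        ["year", "source"]).to_dict()
                    batch = AmendmentBatch(source, contents, int(year))
                    inputs = waste_input(float(row["dose_mg_ha"]), batch)
                mask = ((spec_meta["treatment"] == treatment)
                        & (spec_meta["year"] == year))
                mean_yield = float(spec_meta.loc[mask, "yield_mg_ha"].mean())
                fr = fruit[(fruit["treatment"] == treatment)
                           & (fruit["year"] == year)]
                fruit_mean = compositional_mean(
                    fr[part_columns(fr)], basis, config.scale)
                removal = fruit_removal(mean_yield, fruit_mean,
                                        config.dm_fraction,
                                        elements=BUDGET_ELEMENTS)
                cycles.append((inputs, removal))
            sheets.append(cumulate_budget(cycles, treatment).to_frame())
        budget_df = pd.concat(sheets).reset_index()
        budget_df.to_csv(outdir / "budget.csv", index=False)
        outputs["budget"] = outdir / "budget.csv"
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    manifest = {
        "package": "nutribalance",
        "version": __version__,
        "seed": config.seed,
        "scale": config.scale,
        "alpha": config.alpha,
        "n_draws": config.n_draws,
        "folds": config.folds,
        "cutoff": config.cutoff,
        "knn_grid": {k: list(v) for k, v in config.knn_grid.items()},
        "selected_knn": {"k": results.config.k,
                         "minkowski_p": results.config.minkowski_p,
                         "kernel": results.config.kernel},
        "cv_accuracy": round(float(results.cv_accuracy), 6),
        "redfield_np_range": {g: [round(v, 4) for v in r]
                              for g, r in np_ratio.items()},
        "outputs": sorted(p.name for p in outputs.values()),
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    outputs["manifest"] = outdir / "manifest.yaml"

    return {"outputs": outputs, "results": results, "manifest": manifest,
            "basis": basis}
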