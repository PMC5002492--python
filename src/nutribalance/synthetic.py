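"""Synthetic orchard generator with the structure the diagnosis assumes.

The generator emulates a long-term fertilization trial: a factorial of
blocks × treatments (graded doses of dried organic waste, one fresh-waste
dose expressed as dry-matter equivalent, and a mineral standard) observed
over several harvest years.  Fruit yield follows a plateau dose–response
plus Gaussian noise; specimens are latently high or low yielders relative
to a cutoff.  Foliar compositions are logistic-normal: multivariate normal
in ilr space around a class centroid — the high class at the literature
sufficiency midpoints, the low class shifted by a configurable δ on
designated balances — and back-transformed to closed concentrations.
Waste batch analyses vary year to year around their packaged means.

Every draw flows from one integer seed, and the latent truth (class
centroids, shifts, cutoff) is kept on the dataset for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .composition import OrthonormalBasis, filling_value, ilr, inverse_ilr_transform
from .diagnosis import HIGH, LOW, discretize_yield
from .model import NutrientDiagnosis
from .reference import (
    DRY_WASTE_MEAN,
    DRY_WASTE_SD,
    FOLIAR_SUFFICIENCY,
    FRESH_WASTE_MEAN,
    FRESH_WASTE_SD,
    default_basis,
)

__all__ = ["GeneratorConfig", "OrchardDataset", "generate_orchard",
           "recover_parameters"]


def _sufficiency_midpoints() -> dict[str, float]:
    return {part: (lo + hi) / 2.0 for part, (lo, hi) in FOLIAR_SUFFICIENCY.items()}


#: fruit dry-mass concentration centroid (g kg⁻¹; B in mg kg⁻¹): fruits are
#: K-rich and Ca-poor relative to leaves, which drives the harvest K export
DEFAULT_FRUIT_CENTROID = {
    "N": 8.0, "P": 1.1, "K": 14.0, "Ca": 0.8, "Mg": 0.9, "S": 0.8, "B": 10.0,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design and distributional parameters of the synthetic orchard.

    Defaults reproduce the emulated trial: 4 blocks × 7 treatments
    (dry-waste doses 0/9/18/27/36 Mg ha⁻¹, fresh waste at 18 Mg dry-matter
    equivalent, mineral standard) over 5 years.  Yield follows a
    Mitscherlich-type plateau (response essentially saturated at the 9 Mg
    ha⁻¹ dose, maximum near 60 Mg ha⁻¹) with 8 Mg ha⁻¹ noise.  The low-yield
    class is shifted on the [P | N] and [S | N,P,K,Mg] balances by an amount
    comparable to twice the per-balance spread, which places the knn
    diagnosis in a realistic (neither trivial nor hopeless) accuracy regime.
    """

    seed: int = 0
    n_blocks: int = 4
    years: int = 5
    dry_doses: tuple[float, ...] = (0.0, 9.0, 18.0, 27.0, 36.0)
    fresh_dose: float = 18.0
    include_mineral: bool = True
    #: foliar centroid of the high-yield class, g kg⁻¹ (B in mg kg⁻¹)
    high_centroid: Mapping[str, float] = field(
        default_factory=_sufficiency_midpoints)
    #: per-balance standard deviation of the logistic-normal noise
    balance_sd: float = 0.15
    #: low-class shift per balance label (unitless, in ilr coordinates)
    delta: Mapping[str, float] = field(default_factory=lambda: {
        "[P | N]": -0.30, "[S | N,P,K,Mg]": 0.30})
    #: optional full ilr covariance; overrides ``balance_sd`` when given
    ilr_cov: np.ndarray | None = None
    #: plateau yield model: base (unfertilized), maximum, Mitscherlich rate
    yield_base: float = 40.0
    yield_max: float = 60.0
    yield_rate: float = 3.0
    #: dry-matter-equivalent dose assigned to the mineral standard
    mineral_dose_equivalent: float = 9.0
    yield_sd: float = 8.0
    #: yield cutoff; None = dataset median
    cutoff: float | None = None
    fruit_centroid: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FRUIT_CENTROID))
    fruit_balance_sd: float = 0.10
    scale: float = 1000.0

    def covariance(self, n_balances: int) -> np.ndarray:
        if self.ilr_cov is not None:
            cov = np.asarray(self.ilr_cov, dtype=float)
            if cov.shape != (n_balances, n_balances):
                raise ValueError("ilr covariance shape mismatch")
            if not np.allclose(cov, cov.T):
                raise ValueError("ilr covariance must be symmetric")
            if np.linalg.eigvalsh(cov).min() <= 0:
                raise ValueError("ilr covariance must be positive definite")
            return cov
        if self.balance_sd <= 0:
            raise ValueError("balance_sd must be positive")
        return np.eye(n_balances) * self.balance_sd**2

    def treatments(self) -> pd.DataFrame:
        rows = []
        for dose in self.dry_doses:
            name = "control" if dose == 0 else f"dry-{dose:g}"
            rows.append((name, "dry_waste", float(dose), float(dose)))
        rows.append((f"fresh-{self.fresh_dose:g}", "fresh_waste",
                     float(self.fresh_dose), float(self.fresh_dose)))
        if self.include_mineral:
            rows.append(("mineral", "mineral", 0.0,
                         float(self.mineral_dose_equivalent)))
        return pd.DataFrame(
            rows, columns=["treatment", "source", "dose_mg_ha", "dose_equivalent"]
        )

    def yield_response(self, dose_equivalent: float) -> float:
        return self.yield_max - (self.yield_max - self.yield_base) * float(
            np.exp(-dose_equivalent / self.yield_rate)
        )


@dataclass
class OrchardDataset:
    """Generated specimens, compositions, amendments and latent truth."""

    specimens: pd.DataFrame       # id, year, block, treatment, source, dose, yield, class
    foliar: pd.DataFrame          # closed foliar compositions, g kg⁻¹
    fruit: pd.DataFrame           # closed fruit compositions, g kg⁻¹
    amendments: pd.DataFrame      # year × source element contents (lab units)
    truth: dict
    config: GeneratorConfig
    basis: OrthonormalBasis

    @property
    def yields(self) -> np.ndarray:
        return self.specimens["yield_mg_ha"].to_numpy(dtype=float)

    @property
    def classes(self) -> np.ndarray:
        return self.specimens["latent_class"].to_numpy()


def _centroid_profile(centroid: Mapping[str, float], scale: float):
    return filling_value(dict(centroid), scale, meta={"id": "centroid"})


def generate_orchard(config: GeneratorConfig | None = None,
                     seed: int | None = None) -> OrchardDataset:
    """Draw one synthetic orchard dataset; deterministic per seed."""
    config = config or GeneratorConfig()
    if seed is not None:
        config = GeneratorConfig(**{**config.__dict__, "seed": int(seed)})
    rng = np.random.default_rng(config.seed)
    basis = default_basis()
    cov = config.covariance(basis.n_balances)

    high_profile = _centroid_profile(config.high_centroid, config.scale)
    mu_high = ilr(high_profile, basis).coordinates
    delta_vec = np.zeros(basis.n_balances)
    for label, shift in config.delta.items():
        if label not in basis.labels:
            raise ValueError(f"delta names unknown balance {label!r}")
        delta_vec[basis.labels.index(label)] = float(shift)
    mu_low = mu_high + delta_vec

    fruit_profile = _centroid_profile(config.fruit_centroid, config.scale)
    mu_fruit = ilr(fruit_profile, basis).coordinates

    treatments = config.treatments()
    rows = []
    for year in range(1, config.years + 1):
        for _, trt in treatments.iterrows():
            mean_yield = config.yield_response(trt["dose_equivalent"])
            for block in range(1, config.n_blocks + 1):
                y = max(0.0, mean_yield + rng.normal(0.0, config.yield_sd))
                rows.append((f"{trt['treatment']}-b{block}-y{year}", year, block,
                             trt["treatment"], trt["source"],
                             trt["dose_mg_ha"], y))
    specimens = pd.DataFrame(
        rows, columns=["id", "year", "block", "treatment", "source",
                       "dose_mg_ha", "yield_mg_ha"],
    )

    cutoff = (float(np.median(specimens["yield_mg_ha"]))
              if config.cutoff is None else float(config.cutoff))
    classes = discretize_yield(specimens["yield_mg_ha"], cutoff)
    specimens["latent_class"] = classes

    n = len(specimens)
    chol = np.linalg.cholesky(cov)
    noise = rng.standard_normal((n, basis.n_balances)) @ chol.T
    mu = np.where((classes == LOW)[:, None], mu_low, mu_high)
    foliar = inverse_ilr_transform(mu + noise, basis, config.scale)
    foliar.index = specimens.index

    fruit_noise = rng.standard_normal((n, basis.n_balances)) * config.fruit_balance_sd
    fruit = inverse_ilr_transform(mu_fruit + fruit_noise, basis, config.scale)
    fruit.index = specimens.index

    amendment_rows = []
    for year in range(1, config.years + 1):
        for source, means, sds in (("dry_waste", DRY_WASTE_MEAN, DRY_WASTE_SD),
                                   ("fresh_waste", FRESH_WASTE_MEAN,
                                    FRESH_WASTE_SD)):
            contents = {
                e: max(1e-6, rng.normal(means[e], sds[e])) for e in means
            }
            amendment_rows.append({"year": year, "source": source, **contents})
    amendments = pd.DataFrame(amendment_rows)

    truth = {
        "mu_high": mu_high,
        "mu_low": mu_low,
        "delta": delta_vec,
        "cutoff": cutoff,
        "centroid_high": dict(zip(basis.parts,
                                  inverse_ilr_transform(mu_high[None, :], basis,
                                                        config.scale).iloc[0])),
        "centroid_low": dict(zip(basis.parts,
                                 inverse_ilr_transform(mu_low[None, :], basis,
                                                       config.scale).iloc[0])),
        "balance_labels": basis.labels,
    }
    return OrchardDataset(specimens, foliar, fruit, amendments, truth,
                          config, basis)


def recover_parameters(
    dataset: OrchardDataset,
    grid: Mapping | None = None,
    folds: int = 10,
    seed: int | None = None,
    alpha: float = 0.05,
    n_draws: int = 100_000,
) -> dict:
    """Run the full pipeline on a generated dataset and score it against truth.

    Reports the cross-validated class-recovery accuracy (the honest
    estimate), the resubstitution accuracy, estimated vs true high-class
    centroids, and whether the TN concentration ranges contain the true
    high-class centroid nutrient by nutrient.
    """
    seed = dataset.config.seed if seed is None else seed
    model = NutrientDiagnosis.from_compositions(
        dataset.foliar, dataset.yields, dataset.truth["cutoff"], dataset.basis
    )
    results = model.fit(grid=grid, folds=folds, seed=seed)

    tn_idx = results.group_members("TN")
    report: dict = {
        "config": results.config,
        "cv_accuracy": results.cv_accuracy,
        "resubstitution_accuracy": results.metrics["accuracy"],
        "metrics": results.metrics,
        "confusion": results.partition.to_series().to_dict(),
    }
    true_centroid = {p: v for p, v in dataset.truth["centroid_high"].items()}
    if tn_idx.size >= 2:
        tn_ranges = results.concentration_ranges("TN", alpha, n_draws=n_draws,
                                                 seed=seed)
        per_part = {p: tn_ranges.bounds(p)[0] <= true_centroid[p]
                    <= tn_ranges.bounds(p)[1] for p in tn_ranges.parts}
        report["tn_ranges"] = tn_ranges
        report["tn_covers_centroid_by_part"] = per_part
        report["tn_covers_centroid"] = all(per_part.values())
        report["estimated_centroid_high"] = dict(
            zip(tn_ranges.parts, tn_ranges.mean))
    report["true_centroid_high"] = true_centroid
    return report
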