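"""Nutrient budget balance sheets for fertilized orchards.

Inputs are what fertilization adds to a hectare (organic waste at a dry-mass
dose times its analyzed content, or a mineral recipe); removals are what the
harvest exports (fresh fruit yield times fruit dry-matter fraction times the
fruit nutrient concentration on a dry basis).  The budget of an element over
a period is the cumulated input minus the cumulated removal, in kg ha⁻¹;
negative budgets flag soil mining (the classic orchard potassium deficit).

Also provided: charge-based soil unit conversion (kg ha⁻¹ → mmol of charge
per dm³ of soil) and base-saturation arithmetic on soil cation summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .reference import (
    BUDGET_ELEMENTS,
    CATION_CHARGE,
    MICRO_ELEMENTS,
    MINERAL_RECIPE,
    MOLAR_MASS,
)

__all__ = [
    "AmendmentBatch",
    "BalanceSheet",
    "SoilCationSummary",
    "waste_input",
    "mineral_input",
    "fruit_removal",
    "cumulate_budget",
    "kg_ha_to_mmolc_dm3",
    "mmolc_dm3_to_kg_ha",
    "base_saturation",
]

#: conventional soil volume of one hectare mixed to 0.1 m depth, dm³ ha⁻¹
DEFAULT_SOIL_VOLUME_DM3 = 1.0e6


@dataclass(frozen=True)
class AmendmentBatch:
    """One year's analyzed amendment: element contents on a dry-mass basis.

    Macronutrient contents in g kg⁻¹, micronutrients (``B, Cu, Fe, Mn, Zn``)
    in mg kg⁻¹, as laboratories report them.
    """

    source: str  # dry_waste | fresh_waste | mineral
    contents: Mapping[str, float]
    year: int | None = None
    dry_basis: bool = True

    def __post_init__(self) -> None:
        for element, value in self.contents.items():
            if value < 0:
                raise ValueError(f"negative content for {element!r}: {value}")

    def content_g_kg(self, element: str) -> float:
        """Content in g kg⁻¹ dry mass (micros converted from mg kg⁻¹)."""
        value = float(self.contents.get(element, 0.0))
        return value / 1000.0 if element in MICRO_ELEMENTS else value


def waste_input(dose_mg_ha: float, batch: AmendmentBatch,
                elements: Sequence[str] = BUDGET_ELEMENTS) -> dict[str, float]:
    """Nutrient input from an organic amendment, kg element ha⁻¹.

    ``dose_mg_ha`` is the dose in Mg *dry matter* ha⁻¹ (fresh waste doses are
    expressed as dry-matter equivalents).  kg ha⁻¹ = dose × content(g kg⁻¹):
    1 Mg × 1 g kg⁻¹ = 1 kg.
    """
    if dose_mg_ha < 0:
        raise ValueError("waste dose cannot be negative")
    return {e: dose_mg_ha * batch.content_g_kg(e) for e in elements}


def mineral_input(recipe: Mapping[str, float] | None = None,
                  elements: Sequence[str] = BUDGET_ELEMENTS) -> dict[str, float]:
    """Per-element mineral fertilizer input, kg ha⁻¹.

    With no recipe, returns the packaged locally recommended standard
    (urea / superphosphate / KCl); elements absent from the recipe are 0.
    """
    if recipe is None:
        recipe = MINERAL_RECIPE
    for element, value in recipe.items():
        if value < 0:
            raise ValueError(f"negative amount for {element!r}: {value}")
    return {e: float(recipe.get(e, 0.0)) for e in elements}


def fruit_removal(yield_mg_ha: float, fruit_conc,
                  dm_fraction: float = 0.11,
                  elements: Sequence[str] | None = None) -> dict[str, float]:
    """Nutrient removal through harvested fruit, kg element ha⁻¹.

    ``yield_mg_ha`` is fresh fruit yield (Mg ha⁻¹); ``dm_fraction`` the fruit
    dry-matter fraction at harvest (default 11 %); ``fruit_conc`` maps
    elements to concentrations in g kg⁻¹ dry mass (a ``NutrientProfile``
    works — use the compositional mean when several analyses exist).
    """
    if yield_mg_ha < 0:
        raise ValueError("yield cannot be negative")
    if not 0.0 < dm_fraction < 1.0:
        raise ValueError(f"dry-matter fraction {dm_fraction} outside (0, 1)")
    if hasattr(fruit_conc, "parts"):  # NutrientProfile
        conc = dict(zip(fruit_conc.parts, fruit_conc.values))
    else:
        conc = dict(fruit_conc)
    if elements is None:
        elements = [e for e in conc if e != "Fv"]
    return {e: yield_mg_ha * dm_fraction * float(conc.get(e, 0.0))
            for e in elements}


@dataclass(frozen=True)
class BalanceSheet:
    """Per-element cumulated inputs, removals and budget, kg ha⁻¹."""

    inputs: Mapping[str, float]
    removals: Mapping[str, float]
    treatment: str | None = None
    period: tuple[object, object] | None = None
    budget: Mapping[str, float] = field(init=False)

    def __post_init__(self) -> None:
        if set(self.inputs) != set(self.removals):
            raise ValueError("inputs and removals track different element sets")
        for element, value in self.removals.items():
            if value < 0:
                raise ValueError(f"negative removal for {element!r}: {value}")
        object.__setattr__(
            self,
            "budget",
            {e: self.inputs[e] - self.removals[e] for e in self.inputs},
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "input_kg_ha": pd.Series(dict(self.inputs)),
                "removal_kg_ha": pd.Series(dict(self.removals)),
                "budget_kg_ha": pd.Series(dict(self.budget)),
            }
        )
        df.index.name = "element"
        if self.treatment is not None:
            df.insert(0, "treatment", self.treatment)
        return df


def cumulate_budget(
    cycles: Iterable[tuple[Mapping[str, float], Mapping[str, float]]],
    treatment: str | None = None,
    period: tuple[object, object] | None = None,
) -> BalanceSheet:
    """Sum per-cycle (inputs, removals) pairs into one balance sheet.

    The sign convention is input − removal: a negative budget is a deficit.
    All cycles must track the same element set.
    """
    cycles = list(cycles)
    if not cycles:
        raise ValueError("at least one cropping cycle is required")
    elements = set(cycles[0][0])
    inputs = {e: 0.0 for e in elements}
    removals = {e: 0.0 for e in elements}
    for i, (cycle_in, cycle_out) in enumerate(cycles):
        if set(cycle_in) != elements or set(cycle_out) != elements:
            raise ValueError(f"cycle {i + 1} tracks a different element set")
        for e in elements:
            inputs[e] += float(cycle_in[e])
            removals[e] += float(cycle_out[e])
    return BalanceSheet(inputs, removals, treatment, period)


def kg_ha_to_mmolc_dm3(
    mass_kg_ha: float,
    molar_mass: float,
    charge: int = 1,
    soil_volume_dm3: float = DEFAULT_SOIL_VOLUME_DM3,
) -> float:
    """Convert an areal element mass to a soil charge concentration.

    kg ha⁻¹ × 10³ (g) ÷ molar mass (g mol⁻¹) × charge × 10³ (mmol_c)
    ÷ soil volume (dm³ ha⁻¹, default 10⁶ = one hectare mixed 0.1 m deep).
    """
    if mass_kg_ha < 0:
        raise ValueError("mass cannot be negative")
    if molar_mass <= 0:
        raise ValueError("molar mass must be positive")
    if charge < 1:
        raise ValueError("ionic charge must be at least 1")
    if soil_volume_dm3 <= 0:
        raise ValueError("soil volume must be positive")
    return mass_kg_ha * 1e3 / molar_mass * charge * 1e3 / soil_volume_dm3


def mmolc_dm3_to_kg_ha(
    conc_mmolc_dm3: float,
    molar_mass: float,
    charge: int = 1,
    soil_volume_dm3: float = DEFAULT_SOIL_VOLUME_DM3,
) -> float:
    """Inverse of :func:`kg_ha_to_mmolc_dm3`."""
    if molar_mass <= 0 or soil_volume_dm3 <= 0:
        raise ValueError("molar mass and soil volume must be positive")
    if charge < 1:
        raise ValueError("ionic charge must be at least 1")
    return conc_mmolc_dm3 * soil_volume_dm3 / 1e3 / charge * molar_mass / 1e3


def cation_kg_ha_to_mmolc_dm3(element: str, mass_kg_ha: float,
                              soil_volume_dm3: float = DEFAULT_SOIL_VOLUME_DM3
                              ) -> float:
    """Convenience wrapper using packaged molar masses and charges."""
    return kg_ha_to_mmolc_dm3(
        mass_kg_ha, MOLAR_MASS[element], CATION_CHARGE[element], soil_volume_dm3
    )


@dataclass(frozen=True)
class SoilCationSummary:
    """Exchangeable cations and potential acidity, mmol_c dm⁻³."""

    K: float
    Ca: float
    Mg: float
    H_Al: float

    def __post_init__(self) -> None:
        for name in ("K", "Ca", "Mg", "H_Al"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative {name}")

    @property
    def cec(self) -> float:
        """Cation exchange capacity: sum of cationic species, mmol_c dm⁻³."""
        return self.K + self.Ca + self.Mg + self.H_Al


def base_saturation(soil: SoilCationSummary) -> float:
    """Base saturation %: 100 · (K + Ca + Mg) / CEC."""
    if soil.cec == 0:
        raise ValueError("CEC is zero; base saturation undefined")
    return 100.0 * (soil.K + soil.Ca + soil.Mg) / soil.cec
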