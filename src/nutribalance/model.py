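"""Statsmodels-style front end: a diagnosis model and its results object.

:class:`NutrientDiagnosis` holds the data (balance coordinates and observed
yields) and the design choices (yield cutoff, balance basis); ``fit()``
tunes or applies a weighted knn classifier and returns a
:class:`NutrientDiagnosisResults` carrying the confusion partition,
diagnostic metrics, per-group balance confidence intervals, Monte-Carlo
concentration ranges, critical values and a printable summary.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import diagnosis as _dx
from . import ranges as _rg
from .composition import DEFAULT_SCALE, OrthonormalBasis, ilr_transform
from .reference import default_basis

__all__ = ["NutrientDiagnosis", "NutrientDiagnosisResults"]


class NutrientDiagnosis:
    """Compositional nutrient diagnosis of yield classes in balance space.

    Parameters
    ----------
    balances : DataFrame or array, one specimen per row
        ilr coordinates of the foliar compositions.
    yields : sequence of float
        Observed fresh fruit yields, Mg ha⁻¹.
    cutoff : float
        Yield discretization threshold (Mg ha⁻¹); a specimen at or above it
        is a high yielder. No universal default exists — it is a local,
        crop- and market-specific choice.
    basis : OrthonormalBasis, optional
        Needed for concentration ranges; defaults to the packaged 7-balance
        diagnostic basis when the coordinate count matches.
    """

    def __init__(self, balances, yields, cutoff: float,
                 basis: OrthonormalBasis | None = None):
        if isinstance(balances, pd.DataFrame):
            self.balance_labels = tuple(map(str, balances.columns))
            self.exog = balances.to_numpy(dtype=float)
        else:
            self.exog = np.atleast_2d(np.asarray(balances, dtype=float))
            self.balance_labels = tuple(
                f"b{j + 1}" for j in range(self.exog.shape[1])
            )
        self.yields = np.asarray(yields, dtype=float)
        if self.yields.shape[0] != self.exog.shape[0]:
            raise ValueError("one yield per specimen required")
        self.cutoff = float(cutoff)
        self.classes = _dx.discretize_yield(self.yields, self.cutoff)
        if basis is None:
            packaged = default_basis()
            basis = packaged if packaged.n_balances == self.exog.shape[1] else None
        self.basis = basis

    @classmethod
    def from_compositions(cls, compositions: pd.DataFrame, yields,
                          cutoff: float,
                          basis: OrthonormalBasis | None = None,
                          ) -> "NutrientDiagnosis":
        """Build from a closed composition table, transforming to balances."""
        basis = basis or default_basis()
        return cls(ilr_transform(compositions, basis), yields, cutoff, basis)

    def fit(
        self,
        config: _dx.KnnConfig | None = None,
        grid: Mapping[str, Sequence] | None = None,
        folds: int = 10,
        seed: int | None = None,
    ) -> "NutrientDiagnosisResults":
        """Tune (if ``config`` is None) and apply the knn diagnosis.

        Whole-set predictions include each specimen among its own potential
        neighbours, mirroring resubstitution accuracy reporting; the
        cross-validated accuracy is the honest generalization estimate.
        """
        cv_accuracy = float("nan")
        if config is None:
            config, cv_accuracy = _dx.tune_knn(
                self.exog, self.classes, grid=grid, folds=folds, seed=seed
            )
        elif config.seed is None and seed is not None:
            config = _dx.KnnConfig(config.k, config.minkowski_p, config.kernel,
                                   folds, seed)
        predicted = _dx.knn_predict(self.exog, self.classes, self.exog, config)
        partition = _dx.partition_confusion(self.classes, predicted)
        return NutrientDiagnosisResults(self, config, predicted, partition,
                                        cv_accuracy)


class NutrientDiagnosisResults:
    """Fitted diagnosis: confusion partition, metrics and derived ranges."""

    def __init__(self, model: NutrientDiagnosis, config: _dx.KnnConfig,
                 predicted: np.ndarray, partition: _dx.ConfusionPartition,
                 cv_accuracy: float):
        self.model = model
        self.config = config
        self.predicted = predicted
        self.partition = partition
        self.cv_accuracy = cv_accuracy
        self.metrics = _dx.diagnostic_metrics(partition)

    def group_members(self, group: str) -> np.ndarray:
        members = {
            "TN": self.partition.tn_members, "FN": self.partition.fn_members,
            "TP": self.partition.tp_members, "FP": self.partition.fp_members,
        }[group.upper()]
        return np.asarray(members, dtype=int)

    def balance_ci(self, group: str = "TN", alpha: float = 0.05) -> _rg.BalanceCI:
        """Student-t confidence intervals on the group's balance means."""
        idx = self.group_members(group)
        if idx.size < 2:
            raise ValueError(f"group {group} has fewer than 2 specimens")
        return _rg.group_balance_ci(self.model.exog[idx], alpha,
                                    self.model.balance_labels, group.upper())

    def concentration_ranges(
        self, group: str = "TN", alpha: float = 0.05,
        scale: float = DEFAULT_SCALE, n_draws: int = 100_000,
        seed: int | None = None,
        quantiles: tuple[float, float] | None = None,
    ) -> _rg.ConcentrationRange:
        """Monte-Carlo concentration ranges for one diagnostic group."""
        if self.model.basis is None:
            raise ValueError("a complete basis is required for ranges")
        ci = self.balance_ci(group, alpha)
        return _rg.mc_concentration_ranges(ci, self.model.basis, scale,
                                           n_draws, seed, quantiles)

    def critical_values(self, alpha: float = 0.05, n_draws: int = 100_000,
                        seed: int | None = None, rule: str = "midpoint",
                        ) -> dict[str, float | None]:
        """Critical concentrations from non-overlapping TN vs TP ranges."""
        tn = self.concentration_ranges("TN", alpha, n_draws=n_draws, seed=seed)
        tp = self.concentration_ranges("TP", alpha, n_draws=n_draws, seed=seed)
        return _rg.critical_values(tn, tp, rule)

    def specimen_table(self) -> pd.DataFrame:
        """Per-specimen yields, classes, predictions and categories."""
        category = self.partition.category_of()
        return pd.DataFrame({
            "yield_mg_ha": self.model.yields,
            "observed": self.model.classes,
            "predicted": self.predicted,
            "category": [category[i] for i in range(len(self.predicted))],
        })

    def summary(self) -> str:
        cp, m = self.partition, self.metrics
        lines = [
            "Compositional nutrient diagnosis (weighted knn in ilr space)",
            "=" * 60,
            f"specimens: {cp.total}    yield cutoff: {self.model.cutoff:g} Mg/ha",
            (f"knn: k={self.config.k}, Minkowski p={self.config.minkowski_p:g}, "
             f"kernel={self.config.kernel}"),
            (f"confusion: TN={cp.tn}  TP={cp.tp}  FN={cp.fn}  FP={cp.fp}"),
            (f"accuracy={m['accuracy']:.3f}  npv={m['npv']:.3f}  "
             f"ppv={m['ppv']:.3f}"),
            (f"sensitivity={m['sensitivity']:.3f}  "
             f"specificity={m['specificity']:.3f}"),
        ]
        if np.isfinite(self.cv_accuracy):
            lines.insert(4, f"cross-validated accuracy: {self.cv_accuracy:.3f}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<NutrientDiagnosisResults accuracy={self.metrics['accuracy']:.3f}>"
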