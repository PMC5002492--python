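"""Balance confidence intervals and Monte-Carlo concentration ranges.

Group statistics live in balance (ilr) space, where Euclidean inference is
valid: each balance of a diagnostic group (typically the TN norm group) gets
a Student-t confidence interval for its mean.  The per-balance intervals
form an axis-aligned box in ilr space — the "fulcrum" statistics of the
mobile design.  Concentration ranges are obtained by drawing a large number
of vectors uniformly inside that box, back-transforming each draw to closed
concentrations, and recording each nutrient's extremes over the draws (the
"buckets").  Sampling the box with independent uniform coordinates is a
deliberate methodological simplification: the box, not the joint confidence
ellipsoid, is what the interval-by-interval summary defines.

Where the TN and TP ranges of a nutrient do not overlap, a critical
concentration separating balanced from misbalanced specimens can be read
off the gap between the facing bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .composition import (
    DEFAULT_SCALE,
    OrthonormalBasis,
    inverse_ilr,
    inverse_ilr_transform,
)

__all__ = [
    "BalanceCI",
    "ConcentrationRange",
    "group_balance_ci",
    "mc_concentration_ranges",
    "critical_values",
    "redfield_ratio_range",
]


@dataclass(frozen=True)
class BalanceCI:
    """Two-sided Student-t confidence intervals on group balance means."""

    labels: tuple[str, ...]
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n: int
    alpha: float = 0.05
    group: str | None = None

    def __post_init__(self) -> None:
        for name in ("mean", "lower", "upper"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        if not (self.mean.shape == self.lower.shape == self.upper.shape
                == (len(self.labels),)):
            raise ValueError("mean/lower/upper must align with balance labels")
        if self.n < 2:
            raise ValueError("a confidence interval needs n ≥ 2")
        if ((self.lower > self.mean + 1e-12) | (self.mean > self.upper + 1e-12)).any():
            raise ValueError("interval bounds must bracket the mean")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"mean": self.mean, "lower": self.lower,
                           "upper": self.upper},
                          index=pd.Index(self.labels, name="balance"))
        df["n"] = self.n
        if self.group is not None:
            df.insert(0, "group", self.group)
        return df


def group_balance_ci(
    balances,
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
    group: str | None = None,
) -> BalanceCI:
    """Per-balance t-interval ``mean ± t_{1−α/2, n−1} · s/√n`` for one group."""
    if isinstance(balances, pd.DataFrame):
        if labels is None:
            labels = tuple(map(str, balances.columns))
        balances = balances.to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(balances, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise ValueError("confidence intervals need at least 2 specimens")
    if labels is None:
        labels = tuple(f"b{j + 1}" for j in range(X.shape[1]))
    mean = X.mean(axis=0)
    sem = X.std(axis=0, ddof=1) / np.sqrt(n)
    half = stats.t.ppf(1.0 - alpha / 2.0, df=n - 1) * sem
    return BalanceCI(tuple(labels), mean, mean - half, mean + half,
                     n, alpha, group)


@dataclass(frozen=True)
class ConcentrationRange:
    """Per-nutrient minimum / centroid / maximum concentrations, g kg⁻¹."""

    parts: tuple[str, ...]
    minimum: np.ndarray
    mean: np.ndarray
    maximum: np.ndarray
    group: str | None = None
    scale: float = DEFAULT_SCALE

    def __post_init__(self) -> None:
        for name in ("minimum", "mean", "maximum"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        if not (self.minimum.shape == self.mean.shape == self.maximum.shape
                == (len(self.parts),)):
            raise ValueError("min/mean/max must align with part names")
        if (self.minimum <= 0).any():
            raise ValueError("concentrations must stay positive")
        if ((self.minimum > self.mean + 1e-9)
                | (self.mean > self.maximum + 1e-9)).any():
            raise ValueError("range must satisfy min ≤ mean ≤ max")

    def bounds(self, part: str) -> tuple[float, float]:
        i = self.parts.index(part)
        return float(self.minimum[i]), float(self.maximum[i])

    def contains(self, concentrations: Mapping[str, float]) -> bool:
        """Whether every supplied nutrient lies inside its [min, max]."""
        for part, value in concentrations.items():
            if part not in self.parts:
                continue
            lo, hi = self.bounds(part)
            if not lo <= value <= hi:
                return False
        return True

    def to_frame(self, mg_parts: Sequence[str] = ("B",)) -> pd.DataFrame:
        """Tabulate; parts in ``mg_parts`` are re-reported in mg kg⁻¹."""
        factor = np.array([1000.0 if p in mg_parts else 1.0 for p in self.parts])
        df = pd.DataFrame(
            {
                "minimum": self.minimum * factor,
                "mean": self.mean * factor,
                "maximum": self.maximum * factor,
                "unit": ["mg/kg" if p in mg_parts else "g/kg" for p in self.parts],
            },
            index=pd.Index(self.parts, name="nutrient"),
        )
        if self.group is not None:
            df.insert(0, "group", self.group)
        return df


def mc_concentration_ranges(
    ci: BalanceCI,
    basis: OrthonormalBasis,
    scale: float = DEFAULT_SCALE,
    n_draws: int = 100_000,
    seed: int | None = None,
    quantiles: tuple[float, float] | None = None,
) -> ConcentrationRange:
    """Back-transform a balance confidence box to concentration ranges.

    Draws ``n_draws`` ilr vectors with each coordinate independent uniform
    on its interval, closes each back-transformed draw to ``scale``, and
    reports per-nutrient extremes over the draws; the centroid is the
    back-transform of the interval means.  ``quantiles`` (e.g. ``(0.005,
    0.995)``) replaces the draw extremes with empirical quantiles, which do
    not creep outward as ``n_draws`` grows.  Reproducible from ``seed``, and
    monotone: widening any interval (same seed) never narrows any range.
    """
    basis.require_complete("Monte-Carlo back-transformation")
    if len(ci.labels) != basis.n_balances:
        raise ValueError("confidence intervals must cover every balance of the basis")
    if (ci.lower > ci.upper).any():
        raise ValueError("lower bound exceeds upper bound for some balance")
    if n_draws < 1:
        raise ValueError("need at least one draw")
    rng = np.random.default_rng(seed)
    # common uniforms, affinely mapped: nested boxes yield nested draws
    u = rng.random((n_draws, basis.n_balances))
    draws = ci.lower + u * (ci.upper - ci.lower)
    comps = inverse_ilr_transform(draws, basis, scale).to_numpy()
    if quantiles is None:
        lo, hi = comps.min(axis=0), comps.max(axis=0)
    else:
        q_lo, q_hi = quantiles
        if not 0.0 <= q_lo < q_hi <= 1.0:
            raise ValueError("quantiles must satisfy 0 ≤ lo < hi ≤ 1")
        lo = np.quantile(comps, q_lo, axis=0)
        hi = np.quantile(comps, q_hi, axis=0)
    centroid = inverse_ilr(ci.mean, basis, scale).values
    # the centroid belongs to the box, so clip away quantile-induced inversions
    lo = np.minimum(lo, centroid)
    hi = np.maximum(hi, centroid)
    return ConcentrationRange(basis.parts, lo, centroid, hi, ci.group, scale)


def critical_values(
    tn: ConcentrationRange,
    tp: ConcentrationRange,
    rule: str = "midpoint",
) -> dict[str, float | None]:
    """Critical concentration per nutrient where TN and TP ranges are disjoint.

    ``rule='midpoint'`` places the critical value at the middle of the gap
    between the facing bounds; ``rule='facing'`` uses the TN-side bound
    itself.  Overlapping nutrients map to ``None`` (no critical value can be
    computed — a valid outcome, not an error).
    """
    if set(tn.parts) != set(tp.parts):
        raise ValueError("TN and TP ranges must cover the same nutrients")
    if rule not in ("midpoint", "facing"):
        raise ValueError("rule must be 'midpoint' or 'facing'")
    out: dict[str, float | None] = {}
    for part in tn.parts:
        tn_lo, tn_hi = tn.bounds(part)
        tp_lo, tp_hi = tp.bounds(part)
        if tn_lo > tp_hi:       # TN above TP: deficiency-type critical value
            out[part] = (tn_lo + tp_hi) / 2.0 if rule == "midpoint" else tn_lo
        elif tp_lo > tn_hi:     # TN below TP: excess-type critical value
            out[part] = (tp_lo + tn_hi) / 2.0 if rule == "midpoint" else tn_hi
        else:
            out[part] = None
    return out


def redfield_ratio_range(
    profiles,
    n_part: str = "N",
    p_part: str = "P",
) -> tuple[float, float]:
    """Min–max of the N/P (Redfield) ratio across specimens or MC draws.

    Accepts a composition table (DataFrame with ``N`` and ``P`` columns), an
    iterable of profiles/mappings, or a :class:`ConcentrationRange` — for the
    latter the extreme ratios of the box corners are returned.  The ratio is
    invariant to the closure scale.
    """
    if isinstance(profiles, ConcentrationRange):
        n_lo, n_hi = profiles.bounds(n_part)
        p_lo, p_hi = profiles.bounds(p_part)
        return n_lo / p_hi, n_hi / p_lo
    if isinstance(profiles, pd.DataFrame):
        ratios = (profiles[n_part] / profiles[p_part]).to_numpy(dtype=float)
    else:
        ratios = []
        for prof in profiles:
            if hasattr(prof, "parts"):
                values = dict(zip(prof.parts, prof.values))
            else:
                values = dict(prof)
            ratios.append(float(values[n_part]) / float(values[p_part]))
        ratios = np.asarray(ratios)
    if ratios.size == 0:
        raise ValueError("no specimens supplied")
    return float(ratios.min()), float(ratios.max())
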