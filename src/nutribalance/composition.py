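"""Compositional geometry for tissue nutrient data.

Tissue nutrient concentrations are *compositional*: they carry only relative
information because they are closed to a measurement scale (e.g. 1000 g kg⁻¹
dry mass).  The unanalyzed remainder of the dry mass is carried explicitly as
a *filling value* (``Fv``) so that the closed vector sums exactly to the
scale.  Balances between groups of nutrients are expressed as isometric
log-ratio (ilr) coordinates built from a sequential binary partition (SBP):
an ordered scheme of ±1/0 contrast codes that splits the parts into nested
numerator/denominator groups.  Each SBP row ``j`` defines one balance

    ilr_j = sqrt(n⁺ n⁻ / (n⁺ + n⁻)) · ln( g(c⁺) / g(c⁻) )

where ``n⁺``/``n⁻`` count the parts coded +1/−1 and ``g`` is the geometric
mean over each group.  The sign convention is "[denominator | numerator]"
with the numerator positive: the coordinate grows when the numerator group's
geometric mean grows.  A complete SBP over D parts has D−1 rows and yields an
orthonormal basis of the simplex, so Euclidean statistics (means, distances,
confidence boxes, nearest neighbours) are legitimate on ilr coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NutrientProfile",
    "SbpTable",
    "OrthonormalBasis",
    "BalanceVector",
    "close",
    "filling_value",
    "sbp_to_basis",
    "ilr",
    "ilr_transform",
    "inverse_ilr",
    "inverse_ilr_transform",
    "compositional_mean",
    "aitchison_distance",
    "count_sbps",
]

#: default closure scale: grams per kilogram of dry mass
DEFAULT_SCALE = 1000.0

#: parts conventionally reported in mg kg⁻¹ and converted to g kg⁻¹ on ingestion
MG_PER_KG_PARTS = ("B", "Cu", "Fe", "Mn", "Zn")

#: conventional name of the filling value part
FILLING_PART = "Fv"


@dataclass(frozen=True)
class NutrientProfile:
    """One specimen's closed composition on a fixed scale.

    ``values`` are strictly positive concentrations in g kg⁻¹ dry mass
    (boron and other trace elements are converted from mg kg⁻¹ at ingestion)
    summing to ``scale``.  ``filling_part`` names the part holding the
    unanalyzed remainder, if any.
    """

    parts: tuple[str, ...]
    values: np.ndarray
    scale: float = DEFAULT_SCALE
    filling_part: str | None = None
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if len(self.parts) != values.size:
            raise ValueError("part names and values differ in length")
        if values.size == 0:
            raise ValueError("empty composition")
        for name, v in zip(self.parts, values):
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"part {name!r} has nonpositive value {v!r}")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        total = values.sum()
        if abs(total - self.scale) > 1e-9 * self.scale:
            raise ValueError(
                f"composition sums to {total}, not the scale {self.scale}"
            )
        if self.filling_part is not None and self.filling_part not in self.parts:
            raise ValueError(f"filling part {self.filling_part!r} not among parts")

    def __getitem__(self, part: str) -> float:
        try:
            return float(self.values[self.parts.index(part)])
        except ValueError:
            raise KeyError(part) from None

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.parts), name=self.meta.get("id"))

    def reclose(self, scale: float) -> "NutrientProfile":
        """Return the same composition closed to another scale."""
        return close(self.values, self.parts, scale,
                     filling_part=self.filling_part, meta=self.meta)


def close(
    values: Sequence[float] | np.ndarray,
    parts: Sequence[str] | None = None,
    scale: float = DEFAULT_SCALE,
    *,
    filling_part: str | None = None,
    meta: Mapping[str, object] | None = None,
) -> NutrientProfile:
    """Close a positive vector to the scale ``κ`` (proportional rescaling)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot close an empty vector")
    if parts is None:
        parts = tuple(f"x{i + 1}" for i in range(values.size))
    else:
        parts = tuple(parts)
    for name, v in zip(parts, values):
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"part {name!r} has nonpositive value {v!r}")
    if scale <= 0:
        raise ValueError("scale must be positive")
    closed = values * (scale / values.sum())
    # guard the strict sum invariant against rounding of the last ulp
    closed[-1] += scale - closed.sum()
    return NutrientProfile(parts, closed, scale, filling_part, dict(meta or {}))


def filling_value(
    measured: Mapping[str, float],
    scale: float = DEFAULT_SCALE,
    *,
    mg_parts: Iterable[str] = MG_PER_KG_PARTS,
    filling_part: str = FILLING_PART,
    meta: Mapping[str, object] | None = None,
) -> NutrientProfile:
    """Append the filling value ``Fv = κ − Σ measured`` to analyzed nutrients.

    Measured concentrations are taken in g kg⁻¹ except the parts listed in
    ``mg_parts`` (boron by default), which are supplied in mg kg⁻¹ and
    divided by 1000 before summation.  Measured values are not rescaled; the
    filling value absorbs the unanalyzed remainder of the dry mass.
    """
    if not measured:
        raise ValueError("no measured parts supplied")
    mg_parts = set(mg_parts)
    parts: list[str] = []
    values: list[float] = []
    for name, v in measured.items():
        v = float(v)
        if v <= 0 or not np.isfinite(v):
            raise ValueError(f"part {name!r} has nonpositive value {v!r}")
        parts.append(name)
        values.append(v / 1000.0 if name in mg_parts else v)
    total = float(np.sum(values))
    if total >= scale:
        raise ValueError(
            f"measured parts sum to {total} g kg⁻¹, at or above the scale "
            f"{scale}; check units (is B in mg kg⁻¹?)"
        )
    parts.append(filling_part)
    values.append(scale - total)
    return NutrientProfile(tuple(parts), np.array(values), scale,
                           filling_part, dict(meta or {}))


def _balance_label(parts: Sequence[str], codes: np.ndarray) -> str:
    den = ",".join(p for p, c in zip(parts, codes) if c == -1)
    num = ",".join(p for p, c in zip(parts, codes) if c == +1)
    return f"[{den} | {num}]"


@dataclass(frozen=True)
class SbpTable:
    """A sequential binary partition: one ±1/0 contrast code row per balance.

    Rows must form a nested hierarchy: the nonzero parts of any two rows are
    either disjoint, or one row's nonzero set lies wholly inside the other's
    +1 group or wholly inside its −1 group.  Rows may appear in any order
    (published tables are often printed fine-to-coarse).  A *complete* SBP
    over D parts has exactly D−1 rows and isolates every part.
    """

    parts: tuple[str, ...]
    codes: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=int)
        if codes.ndim != 2 or codes.shape[1] != len(self.parts):
            raise ValueError("codes must be a (rows × parts) matrix")
        object.__setattr__(self, "codes", codes)
        if not self.labels:
            object.__setattr__(
                self,
                "labels",
                tuple(_balance_label(self.parts, row) for row in codes),
            )
        elif len(self.labels) != codes.shape[0]:
            raise ValueError("one label per SBP row required")
        self.validate()

    @property
    def n_rows(self) -> int:
        return int(self.codes.shape[0])

    @property
    def n_parts(self) -> int:
        return len(self.parts)

    @property
    def is_complete(self) -> bool:
        return self.n_rows == self.n_parts - 1

    def validate(self) -> None:
        """Check SBP structure; raise ``ValueError`` naming the first bad row."""
        if not np.isin(self.codes, (-1, 0, 1)).all():
            raise ValueError("SBP codes must be in {-1, 0, +1}")
        groups = []
        for i, row in enumerate(self.codes):
            plus = frozenset(np.flatnonzero(row == +1))
            minus = frozenset(np.flatnonzero(row == -1))
            if not plus or not minus:
                raise ValueError(
                    f"SBP row {i + 1} ({self.labels[i]}) needs at least one "
                    "+1 and one -1 code"
                )
            groups.append((plus, minus, plus | minus))
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                si, sj = groups[i][2], groups[j][2]
                if si.isdisjoint(sj):
                    continue
                if si <= sj:
                    inner, outer = groups[i][2], groups[j]
                    bad = i
                elif sj <= si:
                    inner, outer = groups[j][2], groups[i]
                    bad = j
                else:
                    raise ValueError(
                        f"SBP rows {i + 1} and {j + 1} overlap without nesting"
                    )
                if not (inner <= outer[0] or inner <= outer[1]):
                    raise ValueError(
                        f"SBP row {bad + 1} ({self.labels[bad]}) straddles the "
                        "+/− split of a coarser row (not a sequential refinement)"
                    )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.codes, columns=list(self.parts))
        df.insert(0, "balance", list(self.labels))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SbpTable":
        """Build from a data frame whose first column may hold balance labels."""
        cols = list(df.columns)
        if cols and df[cols[0]].dtype == object:
            labels = tuple(df[cols[0]].astype(str))
            parts = tuple(cols[1:])
            codes = df[cols[1:]].to_numpy(dtype=int)
            return cls(parts, codes, labels)
        return cls(tuple(cols), df.to_numpy(dtype=int))


@dataclass(frozen=True)
class OrthonormalBasis:
    """Orthonormal contrast matrix Ψ (rows × parts) derived from an SBP.

    Row ``j`` carries ``+a_j/n⁺`` on numerator parts and ``−a_j/n⁻`` on
    denominator parts, where ``a_j = sqrt(n⁺ n⁻ / (n⁺ + n⁻))`` is the
    normalization coefficient; for a complete SBP, Ψ Ψᵀ = I.
    """

    parts: tuple[str, ...]
    matrix: np.ndarray
    coefficients: np.ndarray
    labels: tuple[str, ...]
    sbp: SbpTable | None = None

    @property
    def n_balances(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def is_complete(self) -> bool:
        return self.n_balances == len(self.parts) - 1

    def require_complete(self, what: str) -> None:
        if not self.is_complete:
            raise ValueError(
                f"{what} requires a complete basis "
                f"({len(self.parts) - 1} balances, got {self.n_balances}): "
                "the back-transform is underdetermined otherwise"
            )


def sbp_to_basis(sbp: SbpTable) -> OrthonormalBasis:
    """Derive the orthonormal balance basis from a (validated) SBP."""
    sbp.validate()
    psi = np.zeros(sbp.codes.shape, dtype=float)
    coeff = np.zeros(sbp.n_rows)
    for j, row in enumerate(sbp.codes):
        n_pos = int((row == +1).sum())
        n_neg = int((row == -1).sum())
        a = math.sqrt(n_pos * n_neg / (n_pos + n_neg))
        coeff[j] = a
        psi[j, row == +1] = a / n_pos
        psi[j, row == -1] = -a / n_neg
    return OrthonormalBasis(sbp.parts, psi, coeff, sbp.labels, sbp)


@dataclass(frozen=True)
class BalanceVector:
    """ilr coordinates of one specimen under a basis (unitless)."""

    coordinates: np.ndarray
    labels: tuple[str, ...]
    specimen: object | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        object.__setattr__(self, "coordinates", coords)
        if coords.size != len(self.labels):
            raise ValueError("one label per coordinate required")
        if not np.isfinite(coords).all():
            raise ValueError("balance coordinates must be finite")

    def to_series(self) -> pd.Series:
        return pd.Series(self.coordinates, index=list(self.labels),
                         name=self.specimen)


def _aligned_values(profile, basis: OrthonormalBasis) -> np.ndarray:
    """Profile values in basis part order; accepts NutrientProfile or mapping."""
    if isinstance(profile, NutrientProfile):
        getter = dict(zip(profile.parts, profile.values))
    else:
        getter = dict(profile)
    out = np.empty(len(basis.parts))
    for i, part in enumerate(basis.parts):
        if part not in getter:
            raise ValueError(f"profile is missing part {part!r} required by the basis")
        out[i] = getter[part]
        if out[i] <= 0 or not np.isfinite(out[i]):
            raise ValueError(f"part {part!r} has nonpositive value {out[i]!r}")
    return out


def ilr(profile, basis: OrthonormalBasis) -> BalanceVector:
    """ilr coordinates of one composition; invariant to the closure scale."""
    x = _aligned_values(profile, basis)
    coords = basis.matrix @ np.log(x)
    specimen = profile.meta.get("id") if isinstance(profile, NutrientProfile) else None
    return BalanceVector(coords, basis.labels, specimen)


def ilr_transform(table: pd.DataFrame | np.ndarray,
                  basis: OrthonormalBasis) -> pd.DataFrame:
    """ilr coordinates for a table of compositions (rows = specimens).

    A data frame is aligned to the basis parts by column name; a bare array
    is assumed already in basis part order.
    """
    if isinstance(table, pd.DataFrame):
        missing = [p for p in basis.parts if p not in table.columns]
        if missing:
            raise ValueError(f"composition table is missing parts {missing}")
        x = table[list(basis.parts)].to_numpy(dtype=float)
        index = table.index
    else:
        x = np.asarray(table, dtype=float)
        index = pd.RangeIndex(x.shape[0])
    if (x <= 0).any() or not np.isfinite(x).all():
        raise ValueError("compositions must be strictly positive and finite")
    coords = np.log(x) @ basis.matrix.T
    return pd.DataFrame(coords, index=index, columns=list(basis.labels))


def inverse_ilr(
    coordinates: BalanceVector | Sequence[float] | np.ndarray,
    basis: OrthonormalBasis,
    scale: float = DEFAULT_SCALE,
) -> NutrientProfile:
    """Back-transform balance coordinates to a closed composition."""
    basis.require_complete("inverse ilr")
    if isinstance(coordinates, BalanceVector):
        coords = coordinates.coordinates
    else:
        coords = np.asarray(coordinates, dtype=float)
    if coords.shape != (basis.n_balances,):
        raise ValueError(
            f"expected {basis.n_balances} coordinates, got shape {coords.shape}"
        )
    x = np.exp(basis.matrix.T @ coords)
    return close(x, basis.parts, scale)


def inverse_ilr_transform(
    coordinates: pd.DataFrame | np.ndarray,
    basis: OrthonormalBasis,
    scale: float = DEFAULT_SCALE,
) -> pd.DataFrame:
    """Back-transform rows of balance coordinates to closed compositions."""
    basis.require_complete("inverse ilr")
    if isinstance(coordinates, pd.DataFrame):
        coords = coordinates.to_numpy(dtype=float)
        index = coordinates.index
    else:
        coords = np.atleast_2d(np.asarray(coordinates, dtype=float))
        index = pd.RangeIndex(coords.shape[0])
    x = np.exp(coords @ basis.matrix)
    x *= scale / x.sum(axis=1, keepdims=True)
    return pd.DataFrame(x, index=index, columns=list(basis.parts))


def compositional_mean(
    profiles: Iterable[NutrientProfile] | pd.DataFrame,
    basis: OrthonormalBasis,
    scale: float = DEFAULT_SCALE,
) -> NutrientProfile:
    """Centroid of compositions: mean in ilr space, back-transformed.

    Equals the closed per-part geometric mean and does not depend on which
    complete SBP supplies the basis.
    """
    basis.require_complete("the compositional mean")
    if isinstance(profiles, pd.DataFrame):
        coords = ilr_transform(profiles, basis).to_numpy()
    else:
        rows = [ilr(p, basis).coordinates for p in profiles]
        if not rows:
            raise ValueError("cannot average an empty set of profiles")
        coords = np.vstack(rows)
    if coords.shape[0] == 0:
        raise ValueError("cannot average an empty set of profiles")
    return inverse_ilr(coords.mean(axis=0), basis, scale)


def aitchison_distance(p, q, basis: OrthonormalBasis) -> float:
    """Euclidean distance between ilr images; identical under any complete SBP."""
    basis.require_complete("the Aitchison distance")
    bp = ilr(p, basis).coordinates
    bq = ilr(q, basis).coordinates
    return float(np.linalg.norm(bp - bq))


def count_sbps(n_parts: int) -> int:
    """Number of sequential binary partitions of ``n_parts`` parts.

    Closed form D!·(D−1)!/2^(D−1), equivalently the number of ordered
    pairwise-merge sequences of D groups.
    """
    if n_parts < 2:
        raise ValueError("an SBP needs at least two parts")
    return (
        math.factorial(n_parts) * math.factorial(n_parts - 1) // 2 ** (n_parts - 1)
    )
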