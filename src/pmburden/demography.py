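"""Age-structure interpolation and age slicing of population grids.

Age-share tables are anchored at a few years; shares for intervening years
come from componentwise linear interpolation between the bracketing anchors,
renormalized so each year's shares sum to one.  No extrapolation is allowed
beyond the anchor range.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core_grid import AGE_GROUPS, PopulationGrid


class AgeRangeError(ValueError):
    """Requested year lies outside the anchor range."""


@dataclass
class AgeStructure:
    """Population age shares at anchor years.

    ``shares`` has shape ``(n_anchor_years, n_age_groups)``; each row sums
    to one (checked to 1e-9).
    """

    anchor_years: tuple[int, ...]
    shares: np.ndarray
    age_groups: tuple[str, ...] = AGE_GROUPS

    def __post_init__(self) -> None:
        self.anchor_years = tuple(int(y) for y in self.anchor_years)
        self.shares = np.asarray(self.shares, dtype=float)
        if list(self.anchor_years) != sorted(set(self.anchor_years)):
            raise ValueError("anchor_years must be strictly increasing")
        expected = (len(self.anchor_years), len(self.age_groups))
        if self.shares.shape != expected:
            raise ValueError(f"shares shape {self.shares.shape} != {expected}")
        if np.any(self.shares < 0):
            raise ValueError("shares must be >= 0")
        sums = self.shares.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("each anchor year's shares must sum to 1")

    @classmethod
    def from_csv(cls, path: str | Path) -> "AgeStructure":
        """Read a share table: rows = age groups, columns = anchor years."""
        df = pd.read_csv(path, index_col=0)
        groups = tuple(df.index)
        years = tuple(int(c) for c in df.columns)
        return cls(anchor_years=years, shares=df.to_numpy(float).T,
                   age_groups=groups)

    @classmethod
    def bundled_default(cls) -> "AgeStructure":
        """The packaged ageing pyramid (65+ share 8% in 2010 → 23% in 2049)."""
        ref = resources.files("pmburden").joinpath("data/age_structure.csv")
        with resources.as_file(ref) as p:
            return cls.from_csv(p)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.shares.T,
            index=list(self.age_groups),
            columns=[str(y) for y in self.anchor_years],
        ).to_csv(path)


def interpolate_age_shares(s: AgeStructure, year: int) -> np.ndarray:
    """Age shares for ``year`` by linear interpolation between anchors.

    The interpolated vector is renormalized to sum exactly to one.  Years
    outside the anchor range raise :class:`AgeRangeError` (no extrapolation).
    """
    years = s.anchor_years
    if not (years[0] <= year <= years[-1]):
        raise AgeRangeError(
            f"year {year} outside anchor range [{years[0]}, {years[-1]}]"
        )
    yr = np.asarray(years, dtype=float)
    out = np.array([
        np.interp(year, yr, s.shares[:, j]) for j in range(s.shares.shape[1])
    ])
    return out / out.sum()


def share_over_age(pop: PopulationGrid, threshold_group: str) -> float:
    """Fraction of total population in ``threshold_group`` and older groups."""
    if threshold_group not in pop.age_groups:
        raise ValueError(f"unknown age group {threshold_group!r}")
    total = pop.total()
    if total <= 0:
        raise ValueError("population total must be > 0")
    k = pop.age_index(threshold_group)
    return float(pop.counts[..., k:].sum() / total)


def slice_population(
    total_by_cell: np.ndarray, shares: np.ndarray
) -> np.ndarray:
    """Disaggregate per-cell totals into age groups (outer product).

    Conserves the total exactly up to floating point: the shares vector is
    normalized before application.
    """
    shares = np.asarray(shares, dtype=float)
    shares = shares / shares.sum()
    return np.asarray(total_by_cell, dtype=float)[..., None] * shares
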