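"""Domain types and gridded-field I/O shared by every pipeline stage.

The analysis runs on an abstract regular raster: burden arithmetic only ever
pairs a cell's concentration with the same cell's population, so no map
projection or coordinate metadata is carried.  Each cell belongs to exactly
one named region (e.g. ``"central-eastern"`` vs ``"other"``), which is how
regional burden sums are formed.

Gridded fields are stored as NetCDF (one 2-D float variable plus an integer
region-label variable; scenario/species/run metadata as global attributes).
Tabular inputs (baseline mortality, age shares) are plain CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import xarray as xr

SPECIES = ("total_pm25", "soa", "sia", "primary_pm25")
RUN_KINDS = ("NPC", "PC")
SOURCES = ("re", "bi", "in", "tr")
PERTURBED_CHOICES = SOURCES + ("none",)

#: 5-year age groups from birth to the open-ended 85+ bin.
AGE_GROUPS = tuple(
    [f"{lo}–{lo + 4}" for lo in range(0, 85, 5)] + ["85+"]
)

ENDPOINTS = (
    "all_cause_chronic",
    "all_cause_acute",
    "LC",
    "COPD",
    "IHD",
    "stroke",
    "LRI",
    "NCD_LRI",
)


class GridAlignmentError(ValueError):
    """Two gridded objects do not share an identical grid specification."""


class FieldFormatError(ValueError):
    """A file does not contain the gridded variable/metadata expected."""


class FieldValidationError(ValueError):
    """A field violates a domain invariant (negative/non-finite values...)."""


@dataclass(frozen=True)
class GridSpec:
    """Regular raster with uniform cell area and per-cell region labels.

    Parameters
    ----------
    n_rows, n_cols
        Raster dimensions; the product must be positive.
    cell_area_km2
        Uniform cell area in km^2 (50 km cells -> 2500).
    region_labels
        ``(n_rows, n_cols)`` array of region names, one per cell.
    """

    n_rows: int
    n_cols: int
    cell_area_km2: float
    region_labels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise FieldValidationError("grid dimensions must be positive")
        labels = np.asarray(self.region_labels, dtype=object)
        if labels.shape != (self.n_rows, self.n_cols):
            raise FieldValidationError(
                f"region_labels shape {labels.shape} != "
                f"({self.n_rows}, {self.n_cols})"
            )
        object.__setattr__(self, "region_labels", labels)

    @classmethod
    def uniform(
        cls, n_rows: int, n_cols: int, cell_area_km2: float = 2500.0,
        region: str = "all",
    ) -> "GridSpec":
        labels = np.full((n_rows, n_cols), region, dtype=object)
        return cls(n_rows, n_cols, cell_area_km2, labels)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(sorted(np.unique(self.region_labels.astype(str))))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GridSpec):
            return NotImplemented
        return (
            self.shape == other.shape
            and self.cell_area_km2 == other.cell_area_km2
            and np.array_equal(
                self.region_labels.astype(str), other.region_labels.astype(str)
            )
        )

    def __hash__(self) -> int:  # labels excluded; eq stays authoritative
        return hash((self.n_rows, self.n_cols, self.cell_area_km2))


@dataclass
class ConcentrationField:
    """Gridded annual-mean concentration of one species for one model run.

    ``run_kind`` distinguishes the unperturbed reference run (NPC) from a run
    in which one emission source was reduced (PC); for NPC runs
    ``perturbed_source`` must be ``"none"``.
    """

    grid: GridSpec
    values: np.ndarray
    species: str
    scenario_id: str
    year: int
    run_kind: str = "NPC"
    perturbed_source: str = "none"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise FieldValidationError(
                f"values shape {self.values.shape} != grid {self.grid.shape}"
            )
        if self.species not in SPECIES:
            raise FieldValidationError(f"unknown species {self.species!r}")
        if self.run_kind not in RUN_KINDS:
            raise FieldValidationError(f"unknown run_kind {self.run_kind!r}")
        if self.perturbed_source not in PERTURBED_CHOICES:
            raise FieldValidationError(
                f"unknown perturbed_source {self.perturbed_source!r}"
            )
        if self.run_kind == "NPC" and self.perturbed_source != "none":
            raise FieldValidationError(
                "NPC run must have perturbed_source='none'"
            )
        if not np.all(np.isfinite(self.values)):
            n = int(np.sum(~np.isfinite(self.values)))
            raise FieldValidationError(f"{n} non-finite concentration cells")
        if np.any(self.values < 0):
            n = int(np.sum(self.values < 0))
            raise FieldValidationError(f"{n} negative concentration cells")

    def mean(self) -> float:
        """Unweighted grid mean (cells have uniform area)."""
        return float(self.values.mean())


@dataclass
class SourceRunPair:
    """Matched NPC/PC runs for one perturbed source, input to apportionment.

    ``reduction_fraction`` is the fractional emission cut applied to the
    source in the PC run (0.30 in the sensitivity design this emulates).
    """

    npc: ConcentrationField
    pc: ConcentrationField
    reduction_fraction: float = 0.30

    def __post_init__(self) -> None:
        if not (0.0 < self.reduction_fraction <= 1.0):
            raise FieldValidationError(
                "reduction_fraction must lie in (0, 1]"
            )
        if self.npc.run_kind != "NPC" or self.pc.run_kind != "PC":
            raise FieldValidationError("pair must be (NPC, PC) in that order")
        for attr in ("species", "scenario_id", "year"):
            if getattr(self.npc, attr) != getattr(self.pc, attr):
                raise FieldValidationError(
                    f"NPC/PC mismatch on {attr}: "
                    f"{getattr(self.npc, attr)!r} vs {getattr(self.pc, attr)!r}"
                )
        validate_alignment([self.npc, self.pc])

    @property
    def source(self) -> str:
        return self.pc.perturbed_source


@dataclass
class PopulationGrid:
    """Gridded head counts disaggregated into 5-year age groups.

    ``counts`` has shape ``(n_rows, n_cols, n_age_groups)``.
    """

    grid: GridSpec
    counts: np.ndarray
    age_groups: tuple[str, ...]
    year: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.age_groups = tuple(self.age_groups)
        expected = self.grid.shape + (len(self.age_groups),)
        if self.counts.shape != expected:
            raise FieldValidationError(
                f"counts shape {self.counts.shape} != {expected}"
            )
        if self.age_groups != AGE_GROUPS:
            raise FieldValidationError(
                "age_groups must be the contiguous 5-year bins 0–4 .. 85+"
            )
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise FieldValidationError("population counts must be finite, >= 0")

    def total(self) -> float:
        return float(self.counts.sum())

    def age_index(self, group: str) -> int:
        return self.age_groups.index(group)


@dataclass
class BaselineMortalityTable:
    """Cause- and age-specific baseline death rates (per person-year).

    Held fixed across projection years, mirroring the use of a single
    reference year of mortality statistics for all scenario years.
    """

    rates: pd.DataFrame  # columns: endpoint, age_group, rate

    def __post_init__(self) -> None:
        required = {"endpoint", "age_group", "rate"}
        if not required.issubset(self.rates.columns):
            raise FieldValidationError(
                f"baseline mortality table needs columns {sorted(required)}"
            )
        r = self.rates["rate"].to_numpy(dtype=float)
        if np.any(r < 0) or np.any(r >= 1) or not np.all(np.isfinite(r)):
            raise FieldValidationError("rates must satisfy 0 <= rate < 1")
        self._lookup = {
            (row.endpoint, row.age_group): float(row.rate)
            for row in self.rates.itertuples()
        }

    def rate(self, endpoint: str, age_group: str) -> float:
        try:
            return self._lookup[(endpoint, age_group)]
        except KeyError:
            raise KeyError(
                f"no baseline mortality rate for ({endpoint!r}, {age_group!r})"
            ) from None

    def rate_vector(self, endpoint: str, age_groups: Sequence[str]) -> np.ndarray:
        return np.array([self.rate(endpoint, g) for g in age_groups])

    def to_csv(self, path: str | Path) -> None:
        self.rates.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BaselineMortalityTable":
        return cls(pd.read_csv(path))


BURDEN_COLUMNS = ["scenario_id", "year", "endpoint", "source", "region", "deaths"]


@dataclass
class BurdenTable:
    """Long-format table of attributable deaths.

    One row per (scenario, year, endpoint, source, region); ``source`` is one
    of re/bi/in/tr or ``"all"`` for total-concentration burdens, ``region`` a
    grid region label or ``"all"`` for the national row.
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(BURDEN_COLUMNS) - set(self.rows.columns)
        if missing:
            raise FieldValidationError(f"burden table missing {sorted(missing)}")
        if np.any(self.rows["deaths"].to_numpy(dtype=float) < 0):
            raise FieldValidationError("deaths must be >= 0")
        self._check_region_sums()

    def _check_region_sums(self, rtol: float = 1e-9) -> None:
        df = self.rows
        keys = ["scenario_id", "year", "endpoint", "source"]
        nat = df[df["region"] == "all"].set_index(keys)["deaths"]
        parts = (
            df[df["region"] != "all"].groupby(keys)["deaths"].sum()
        )
        common = nat.index.intersection(parts.index)
        if len(common):
            a = nat.loc[common].to_numpy(float)
            b = parts.loc[common].to_numpy(float)
            scale = np.maximum(np.abs(a), 1.0)
            if np.any(np.abs(a - b) > rtol * scale):
                raise FieldValidationError(
                    "regional deaths do not sum to the national row"
                )

    def deaths(
        self,
        scenario_id: str,
        year: int,
        endpoint: str,
        source: str = "all",
        region: str = "all",
    ) -> float:
        df = self.rows
        sel = df[
            (df["scenario_id"] == scenario_id)
            & (df["year"] == year)
            & (df["endpoint"] == endpoint)
            & (df["source"] == source)
            & (df["region"] == region)
        ]
        if len(sel) != 1:
            raise KeyError(
                f"expected one row for ({scenario_id}, {year}, {endpoint}, "
                f"{source}, {region}); found {len(sel)}"
            )
        return float(sel["deaths"].iloc[0])

    def to_csv(self, path: str | Path) -> None:
        self.rows.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BurdenTable":
        return cls(pd.read_csv(path))

    @classmethod
    def concat(cls, tables: Iterable["BurdenTable"]) -> "BurdenTable":
        return cls(
            pd.concat([t.rows for t in tables], ignore_index=True)
        )


# ---------------------------------------------------------------------------
# alignment and I/O


def validate_alignment(objs: Sequence) -> None:
    """Check that all gridded objects share an identical :class:`GridSpec`.

    Raises
    ------
    GridAlignmentError
        Naming the first differing dimension or label set.
    """
    if len(objs) < 2:
        raise ValueError("need at least two objects to compare")
    grids = [o.grid if hasattr(o, "grid") else o for o in objs]
    ref = grids[0]
    for k, g in enumerate(grids[1:], start=1):
        if g.shape != ref.shape:
            raise GridAlignmentError(
                f"object {k}: grid shape {g.shape} != reference {ref.shape}"
            )
        if g.cell_area_km2 != ref.cell_area_km2:
            raise GridAlignmentError(
                f"object {k}: cell_area_km2 {g.cell_area_km2} != "
                f"{ref.cell_area_km2}"
            )
        if not np.array_equal(
            g.region_labels.astype(str), ref.region_labels.astype(str)
        ):
            raise GridAlignmentError(
                f"object {k}: region labels differ from reference"
            )


def _region_codes(grid: GridSpec) -> tuple[np.ndarray, list[str]]:
    regions = list(grid.regions)
    code = {r: i for i, r in enumerate(regions)}
    arr = np.vectorize(code.__getitem__)(grid.region_labels.astype(str))
    return arr.astype(np.int32), regions


def write_field(f: ConcentrationField, path: str | Path) -> None:
    """Write a field to NetCDF with enough metadata to reconstruct it."""
    codes, regions = _region_codes(f.grid)
    ds = xr.Dataset(
        {
            "concentration": (("row", "col"), f.values),
            "region_code": (("row", "col"), codes),
        },
        attrs={
            "species": f.species,
            "scenario_id": f.scenario_id,
            "year": int(f.year),
            "run_kind": f.run_kind,
            "perturbed_source": f.perturbed_source,
            "cell_area_km2": float(f.grid.cell_area_km2),
            "region_names": ",".join(regions),
            "units": "ug m-3",
        },
    )
    ds.to_netcdf(path, engine="scipy")


def read_field(
    path: str | Path,
    species: str | None = None,
    scenario_id: str | None = None,
    year: int | None = None,
    run_kind: str | None = None,
    perturbed_source: str | None = None,
) -> ConcentrationField:
    """Read a field from NetCDF, optionally checking it matches a selector.

    Any selector argument given must match the file's metadata; a mismatch
    raises :class:`FieldFormatError` naming the selector.
    """
    with xr.open_dataset(path, engine="scipy") as ds:
        if "concentration" not in ds:
            raise FieldFormatError(
                f"{path}: no 'concentration' variable"
            )
        attrs = dict(ds.attrs)
        values = ds["concentration"].to_numpy().astype(float)
        codes = ds["region_code"].to_numpy()
    regions = str(attrs["region_names"]).split(",")
    labels = np.array(regions, dtype=object)[codes]
    grid = GridSpec(
        values.shape[0], values.shape[1], float(attrs["cell_area_km2"]), labels
    )
    meta = {
        "species": str(attrs["species"]),
        "scenario_id": str(attrs["scenario_id"]),
        "year": int(attrs["year"]),
        "run_kind": str(attrs["run_kind"]),
        "perturbed_source": str(attrs["perturbed_source"]),
    }
    selector = {
        "species": species,
        "scenario_id": scenario_id,
        "year": year,
        "run_kind": run_kind,
        "perturbed_source": perturbed_source,
    }
    for key, want in selector.items():
        if want is not None and meta[key] != want:
            raise FieldFormatError(
                f"{path}: selector {key}={want!r} does not match "
                f"stored {meta[key]!r}"
            )
    return ConcentrationField(grid=grid, values=values, **meta)
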