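"""Scenario statistics over burden tables.

This stage turns death-count series into the headline numbers a scenario
comparison reports: percent changes against the 2010 baseline, multi-year
annual averages, the relative gap between the linear and nonlinear
pathways, cause shares, absolute avoided deaths, and the per-source
decomposition of a 2010→2049 reduction.

All operations are pure functions of their tables.  Internal values keep
full precision; rounding (half away from zero — integer percents, 2-decimal
millions) happens only at this reporting boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core_grid import BurdenTable, SOURCES

DEFAULT_AVERAGE_YEARS = (2020, 2030, 2040, 2049)


class ReportingError(ValueError):
    """Zero baseline/denominator or missing year."""


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of the reported tables).

    Python's built-in ``round`` is banker's rounding; reported statistics
    use the arithmetic convention (2.5 → 3, −2.5 → −3).
    """
    scale = 10 ** ndigits
    r = math.floor(abs(x) * scale + 0.5) / scale
    r = math.copysign(r, x)
    return r if ndigits > 0 else int(r)


@dataclass
class ScenarioSeries:
    """Deaths (millions) per year for one endpoint series of one scenario."""

    scenario_id: str
    endpoint: str
    values: dict[int, float]  # year -> deaths, millions
    baseline_year: int = 2010

    def __post_init__(self) -> None:
        if self.baseline_year not in self.values:
            raise ReportingError(
                f"baseline year {self.baseline_year} missing from series"
            )
        if any(v < 0 for v in self.values.values()):
            raise ReportingError("death counts must be >= 0")

    def value(self, year: int) -> float:
        try:
            return self.values[year]
        except KeyError:
            raise ReportingError(
                f"year {year} not in series {self.scenario_id}/{self.endpoint}"
            ) from None

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self.values))


def load_table1_fixture(path: str | Path | None = None) -> pd.DataFrame:
    """Load the transcribed scenario-table fixture (deaths in millions).

    Long format: scenario (HIST/CLE/MFR), year, pathway (linear/nonlinear),
    endpoint, deaths_million.  The 2010 column belongs to the shared
    historical baseline and is reused as each scenario's baseline year.
    """
    if path is None:
        ref = resources.files("pmburden").joinpath(
            "data/table1_china_pm25_deaths.csv"
        )
        with resources.as_file(ref) as p:
            return pd.read_csv(p)
    return pd.read_csv(path)


def series_from_fixture(
    fixture: pd.DataFrame, scenario: str, pathway: str, endpoint: str
) -> ScenarioSeries:
    """Build a scenario series, prepending the shared 2010 baseline row."""
    sel = fixture[
        (fixture["pathway"] == pathway) & (fixture["endpoint"] == endpoint)
    ]
    base = sel[sel["scenario"] == "HIST"]
    scen = sel[sel["scenario"] == scenario]
    if base.empty or scen.empty:
        raise ReportingError(
            f"fixture has no rows for {scenario}/{pathway}/{endpoint}"
        )
    values = dict(zip(scen["year"].astype(int), scen["deaths_million"]))
    values[int(base["year"].iloc[0])] = float(base["deaths_million"].iloc[0])
    return ScenarioSeries(scenario, f"{pathway}_{endpoint}", values)


def percent_change_vs_baseline(
    series: ScenarioSeries, year: int
) -> int:
    """Signed percent change of ``year`` vs the baseline year, rounded.

    Negative values are reductions (a −43 here is rendered as a "43%
    reduction" in prose).
    """
    base = series.value(series.baseline_year)
    if base <= 0:
        raise ReportingError("baseline value must be > 0")
    return round_half_away(100.0 * (series.value(year) - base) / base)


def annual_average(
    series: ScenarioSeries, years: tuple[int, ...] = DEFAULT_AVERAGE_YEARS,
    *, rounded: bool = True,
) -> float:
    """Arithmetic mean of the listed years' values (equal weights)."""
    vals = [series.value(y) for y in years]
    avg = float(np.mean(vals))
    return round_half_away(avg, 2) if rounded else avg


def linear_vs_nonlinear_delta(
    lin: ScenarioSeries, nonlin: ScenarioSeries,
    years: tuple[int, ...] = DEFAULT_AVERAGE_YEARS,
) -> int:
    """Relative gap of the nonlinear vs linear multi-year average, percent."""
    a_lin = annual_average(lin, years, rounded=False)
    a_non = annual_average(nonlin, years, rounded=False)
    if a_lin <= 0:
        raise ReportingError("linear average must be > 0")
    return round_half_away(100.0 * (a_non - a_lin) / a_lin)


def cause_share(
    values: dict[str, float], numerator: str,
    denominator_set: tuple[str, ...],
) -> int:
    """One cause's share of a set of causes for a single year, percent."""
    denom = sum(values[c] for c in denominator_set)
    if denom <= 0:
        raise ReportingError("denominator sum must be > 0")
    return round_half_away(100.0 * values[numerator] / denom)


def scenario_difference(
    series: ScenarioSeries, year_a: int, year_b: int
) -> float:
    """v(year_a) − v(year_b), millions (full precision)."""
    return series.value(year_a) - series.value(year_b)


def source_reduction_decomposition(
    burden_start: BurdenTable,
    burden_end: BurdenTable,
    *,
    endpoint: str = "all_cause_total",
    region: str = "all",
) -> pd.DataFrame:
    """Split a start→end reduction in source-attributable deaths by source.

    Returns one row per source with the absolute reduction and its share of
    the summed four-source reduction (shares sum to 1).
    """
    rows = []
    for source in SOURCES:
        d0 = _source_deaths(burden_start, endpoint, source, region)
        d1 = _source_deaths(burden_end, endpoint, source, region)
        rows.append((source, d0 - d1))
    df = pd.DataFrame(rows, columns=["source", "reduction"])
    total = df["reduction"].sum()
    if total <= 0:
        raise ReportingError("no net reduction to decompose")
    df["share"] = df["reduction"] / total
    return df


def _source_deaths(
    table: BurdenTable, endpoint: str, source: str, region: str
) -> float:
    df = table.rows
    sel = df[
        (df["endpoint"] == endpoint)
        & (df["source"] == source)
        & (df["region"] == region)
    ]
    if sel.empty:
        raise ReportingError(
            f"burden table has no ({endpoint}, {source}, {region}) row"
        )
    return float(sel["deaths"].sum())


def headline_statistics(fixture: pd.DataFrame) -> dict[str, float]:
    """Every fixture-driven headline number, computed in one pass.

    Keys name the statistic; values are on the printed scale (percent as
    signed integers, deaths in millions rounded to 2 decimals).
    """
    out: dict[str, float] = {}
    lin = {s: series_from_fixture(fixture, s, "linear", "total")
           for s in ("CLE", "MFR")}
    non = {s: series_from_fixture(fixture, s, "nonlinear", "total")
           for s in ("CLE", "MFR")}
    for s in ("CLE", "MFR"):
        key = s.lower()
        out[f"{key}_linear_total_pct_change_2049"] = (
            percent_change_vs_baseline(lin[s], 2049)
        )
        out[f"{key}_nonlinear_total_pct_change_2049"] = (
            percent_change_vs_baseline(non[s], 2049)
        )
        out[f"{key}_linear_annual_avg_2020_2049_millions"] = (
            annual_average(lin[s])
        )
        out[f"{key}_nonlinear_annual_avg_2020_2049_millions"] = (
            annual_average(non[s])
        )
        out[f"{key}_nonlinear_vs_linear_delta_pct"] = (
            linear_vs_nonlinear_delta(lin[s], non[s])
        )
        out[f"{key}_linear_total_decrease_2010_2049_millions"] = (
            round_half_away(scenario_difference(lin[s], 2010, 2049), 2)
        )
    # IHD share of the five causes across every scenario-year column
    shares = []
    causes = ("LC", "COPD", "IHD", "stroke", "LRI")
    nl = fixture[fixture["pathway"] == "nonlinear"]
    for (_, _), grp in nl.groupby(["scenario", "year"]):
        vals = dict(zip(grp["endpoint"], grp["deaths_million"]))
        shares.append(cause_share(vals, "IHD", causes))
    out["ihd_share_min_pct"] = min(shares)
    out["ihd_share_max_pct"] = max(shares)
    # linear 2010 split
    ad = series_from_fixture(fixture, "CLE", "linear", "AD").value(2010)
    cd = series_from_fixture(fixture, "CLE", "linear", "CD").value(2010)
    out["linear_2010_total_millions"] = round_half_away(ad + cd, 2)
    out["linear_2010_cd_share_of_total_pct"] = cause_share(
        {"AD": ad, "CD": cd}, "CD", ("AD", "CD")
    )
    return out
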