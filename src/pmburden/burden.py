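"""Attributable-mortality accounting.

For an endpoint with baseline death rate b(age), population N(cell, age) and
concentration c(cell), attributable deaths are

    D = Σ_cells Σ_age∈applicable  N(cell, age) · b(endpoint, age)
                                  · AF(RR(c(cell)))

aggregated by region label and nationally.  The relative risk comes either
from the linear all-cause function (acute and chronic pathways) or from a
per-cause GEMM hazard function; GEMM causes apply to adults (25+) by
default, reflecting the adult cohorts the hazard functions were fitted on.

Per-source burdens evaluate the same machinery on the apportioned
per-source concentration fields with the linear all-cause pathway; with the
``delta`` attributable-fraction form the per-source deaths are exactly
additive in concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping

import numpy as np
import pandas as pd

from .core_grid import (
    AGE_GROUPS,
    BaselineMortalityTable,
    BurdenTable,
    BURDEN_COLUMNS,
    ConcentrationField,
    GridSpec,
    PopulationGrid,
    validate_alignment,
)
from .exposure_response import (
    DEFAULT_ACUTE_ERF,
    DEFAULT_CHRONIC_ERF,
    GEMMParams,
    LinearERF,
    attributable_fraction,
    gemm_rr,
    linear_rr,
)

NONLINEAR_CAUSES = ("LC", "COPD", "IHD", "stroke", "LRI")

ADULT_25PLUS = tuple(g for i, g in enumerate(AGE_GROUPS) if i >= 5)


class BurdenConfigError(ValueError):
    """Missing baseline rates, ERF parameters or causes."""


@dataclass
class EndpointSpec:
    """How one mortality endpoint is evaluated.

    ``erf`` holds a :class:`LinearERF` or :class:`GEMMParams` matching
    ``erf_kind``; ``applicable_ages`` restricts the age groups whose
    baseline deaths the endpoint draws on (all ages for the linear
    all-cause pathway, 25+ for GEMM causes).
    """

    endpoint: str
    erf_kind: str  # "linear" | "gemm"
    erf: LinearERF | GEMMParams
    applicable_ages: tuple[str, ...] = dc_field(default_factory=tuple)
    af_form: str = "ratio"

    def __post_init__(self) -> None:
        if self.erf_kind not in ("linear", "gemm"):
            raise BurdenConfigError(f"unknown erf_kind {self.erf_kind!r}")
        if self.erf_kind == "gemm" and not isinstance(self.erf, GEMMParams):
            raise BurdenConfigError(
                f"endpoint {self.endpoint}: erf_kind='gemm' needs GEMMParams"
            )
        if not self.applicable_ages:
            self.applicable_ages = (
                ADULT_25PLUS if self.erf_kind == "gemm" else AGE_GROUPS
            )

    def relative_risk(self, conc: np.ndarray) -> np.ndarray:
        if self.erf_kind == "gemm":
            return gemm_rr(conc, self.erf)
        return linear_rr(conc, self.erf)


def _regional_sums(
    grid: GridSpec, per_cell: np.ndarray
) -> dict[str, float]:
    out = {"all": float(per_cell.sum())}
    labels = grid.region_labels.astype(str)
    for region in grid.regions:
        out[region] = float(per_cell[labels == region].sum())
    return out


def attributable_deaths(
    conc: ConcentrationField | np.ndarray,
    pop: PopulationGrid,
    base: BaselineMortalityTable,
    spec: EndpointSpec,
) -> dict[str, float]:
    """Deaths attributable to the exposure field, by region plus ``"all"``.

    ``conc`` may be a ConcentrationField (grid-checked against the
    population) or a bare array on the population's grid (as produced by the
    apportionment stage).
    """
    if isinstance(conc, ConcentrationField):
        validate_alignment([conc, pop])
        values = conc.values
    else:
        values = np.asarray(conc, dtype=float)
        if values.shape != pop.grid.shape:
            raise ValueError(
                f"concentration shape {values.shape} != grid {pop.grid.shape}"
            )
    try:
        rates = base.rate_vector(spec.endpoint, spec.applicable_ages)
    except KeyError as e:
        raise BurdenConfigError(str(e)) from None
    idx = [pop.age_index(g) for g in spec.applicable_ages]
    af = attributable_fraction(spec.relative_risk(values), form=spec.af_form)
    # per-cell deaths: (pop_slice @ rates) * AF(cell)
    exposed_deaths = pop.counts[..., idx] @ rates
    per_cell = exposed_deaths * af
    return _regional_sums(pop.grid, per_cell)


def linear_total_deaths(acute: float, chronic: float) -> float:
    """Linear-pathway total: acute plus chronic deaths."""
    if acute < 0 or chronic < 0:
        raise ValueError("death counts must be >= 0")
    return acute + chronic


def nonlinear_total_deaths(
    cause_deaths: Mapping[str, float], mode: str = "sum_causes"
) -> float:
    """Total deaths in the nonlinear pathway.

    ``sum_causes`` adds the five cause-specific counts (LC, COPD, IHD,
    stroke, LRI); ``ncd_lri`` instead expects the death count computed from
    the joint NCD+LRI hazard function under the key ``"NCD_LRI"``.  Which
    totalization a given published table used is not always stated; both
    are first-class here.
    """
    if mode == "sum_causes":
        missing = [c for c in NONLINEAR_CAUSES if c not in cause_deaths]
        if missing:
            raise BurdenConfigError(f"missing causes: {missing}")
        return float(sum(cause_deaths[c] for c in NONLINEAR_CAUSES))
    if mode == "ncd_lri":
        if "NCD_LRI" not in cause_deaths:
            raise BurdenConfigError("missing NCD_LRI death count")
        return float(cause_deaths["NCD_LRI"])
    raise BurdenConfigError(f"unknown totalization mode {mode!r}")


def source_attributable_deaths(
    src,
    pop: PopulationGrid,
    base: BaselineMortalityTable,
    *,
    acute_erf: LinearERF = DEFAULT_ACUTE_ERF,
    chronic_erf: LinearERF = DEFAULT_CHRONIC_ERF,
    af_form: str = "delta",
    gemm_params: GEMMParams | None = None,
) -> BurdenTable:
    """Per-source burden rows from an apportioned concentration set.

    Source burdens use the linear acute+chronic pathway; the ``delta`` AF
    form (default here) makes them exactly additive across sources.
    Passing ``gemm_params`` switches to evaluating the GEMM hazard on each
    source field instead — an exploratory mode, not the standard accounting
    (hazard nonlinearity makes per-source GEMM burdens non-additive).
    """
    rows = []
    for source in src.sources:
        field = src.totals[source]
        if gemm_params is not None:
            spec = EndpointSpec(gemm_params.endpoint, "gemm", gemm_params,
                                af_form=af_form)
            regional = attributable_deaths(field, pop, base, spec)
            per_endpoint = {gemm_params.endpoint: regional}
        else:
            per_endpoint = {}
            for ep, erf in (("all_cause_acute", acute_erf),
                            ("all_cause_chronic", chronic_erf)):
                spec = EndpointSpec(ep, "linear",
                                    LinearERF(erf.rr_per_10, ep,
                                              erf.counterfactual),
                                    af_form=af_form)
                per_endpoint[ep] = attributable_deaths(field, pop, base, spec)
            per_endpoint["all_cause_total"] = {
                region: linear_total_deaths(
                    per_endpoint["all_cause_acute"][region],
                    per_endpoint["all_cause_chronic"][region],
                )
                for region in per_endpoint["all_cause_acute"]
            }
        for ep, regional in per_endpoint.items():
            for region, deaths in regional.items():
                rows.append((src.scenario_id, src.year, ep, source, region,
                             deaths))
    df = pd.DataFrame(rows, columns=BURDEN_COLUMNS)
    return BurdenTable(df)


def scenario_burden(
    conc: ConcentrationField,
    pop: PopulationGrid,
    base: BaselineMortalityTable,
    *,
    gemm_params: dict[str, GEMMParams],
    acute_erf: LinearERF = DEFAULT_ACUTE_ERF,
    chronic_erf: LinearERF = DEFAULT_CHRONIC_ERF,
    af_form: str = "ratio",
    nonlinear_mode: str = "sum_causes",
) -> BurdenTable:
    """All-endpoint burden for one scenario-year total-PM2.5 field.

    Evaluates the linear acute/chronic pathway and every GEMM cause present
    in ``gemm_params``, plus the two derived totals (``all_cause_total``,
    ``nonlinear_total``).
    """
    rows = []
    linear_parts: dict[str, dict[str, float]] = {}
    for ep, erf in (("all_cause_acute", acute_erf),
                    ("all_cause_chronic", chronic_erf)):
        spec = EndpointSpec(ep, "linear",
                            LinearERF(erf.rr_per_10, ep, erf.counterfactual),
                            af_form=af_form)
        linear_parts[ep] = attributable_deaths(conc, pop, base, spec)

    cause_regional: dict[str, dict[str, float]] = {}
    for cause, params in gemm_params.items():
        spec = EndpointSpec(cause, "gemm", params, af_form=af_form)
        cause_regional[cause] = attributable_deaths(conc, pop, base, spec)

    regions = list(linear_parts["all_cause_acute"])
    derived: dict[str, dict[str, float]] = {
        "all_cause_total": {
            r: linear_total_deaths(linear_parts["all_cause_acute"][r],
                                   linear_parts["all_cause_chronic"][r])
            for r in regions
        }
    }
    if nonlinear_mode == "sum_causes":
        have = all(c in cause_regional for c in NONLINEAR_CAUSES)
    else:
        have = "NCD_LRI" in cause_regional
    if have:
        derived["nonlinear_total"] = {
            r: nonlinear_total_deaths(
                {c: v[r] for c, v in cause_regional.items()},
                mode=nonlinear_mode,
            )
            for r in regions
        }
    for ep, regional in {**linear_parts, **cause_regional, **derived}.items():
        for region, deaths in regional.items():
            rows.append((conc.scenario_id, conc.year, ep, "all", region,
                         deaths))
    return BurdenTable(pd.DataFrame(rows, columns=BURDEN_COLUMNS))
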