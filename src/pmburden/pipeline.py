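"""End-to-end desk run: synthetic suite → apportionment → burden → report.

Convenience orchestration used by the CLI and by whole-pipeline checks; the
individual stages remain the public API for anything more bespoke.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .apportionment import SourceConcentrationSet, source_concentration
from .burden import source_attributable_deaths
from .core_grid import BurdenTable, SourceRunPair, SOURCES
from .reporting import source_reduction_decomposition
from .synthetic import (
    SyntheticConfig,
    generate_baseline_mortality,
    generate_concentration_suite,
    generate_population,
)


@dataclass
class PipelineResult:
    """Per-scenario-year source burden tables plus derived summaries."""

    source_burdens: dict[tuple[str, int], BurdenTable]
    source_shares: dict[str, dict[str, float]]  # scenario -> source -> share
    reduction_decomposition: dict[str, pd.DataFrame]  # scenario -> table


def run_synthetic_pipeline(
    cfg: SyntheticConfig, *, af_form: str = "delta"
) -> PipelineResult:
    """Generate a suite, apportion every scenario-year, and compute the
    per-source linear burdens and their scenario summaries.

    Source shares are averaged over the post-baseline years (each year's
    share is that source's deaths over the four-source sum).
    """
    fields, _ = generate_concentration_suite(cfg)
    pops = {p.year: p for p in generate_population(cfg)}
    base = generate_baseline_mortality(cfg)

    npc = {
        (f.scenario_id, f.year): f
        for f in fields
        if f.run_kind == "NPC" and f.species == "total_pm25"
    }
    pc = {
        (f.scenario_id, f.year, f.perturbed_source): f
        for f in fields
        if f.run_kind == "PC"
    }

    burdens: dict[tuple[str, int], BurdenTable] = {}
    for (scen, year), npc_field in npc.items():
        totals = {}
        for s in SOURCES:
            pair = SourceRunPair(
                npc=npc_field, pc=pc[(scen, year, s)],
                reduction_fraction=cfg.reduction_fraction,
            )
            totals[s] = source_concentration(pair)
        src_set = SourceConcentrationSet(
            grid=npc_field.grid, totals=totals, scenario_id=scen, year=year
        )
        burdens[(scen, year)] = source_attributable_deaths(
            src_set, pops[year], base, af_form=af_form
        )

    shares: dict[str, dict[str, float]] = {}
    decomp: dict[str, pd.DataFrame] = {}
    y0, y_end = min(cfg.years), max(cfg.years)
    for scen in cfg.scenarios:
        per_year = []
        for year in cfg.years:
            if year == y0:
                continue
            t = burdens[(scen, year)]
            d = {
                s: t.deaths(scen, year, "all_cause_total", source=s)
                for s in SOURCES
            }
            tot = sum(d.values())
            per_year.append({s: d[s] / tot for s in SOURCES})
        shares[scen] = {
            s: sum(p[s] for p in per_year) / len(per_year) for s in SOURCES
        }
        decomp[scen] = source_reduction_decomposition(
            burdens[(scen, y0)], burdens[(scen, y_end)]
        )
    return PipelineResult(burdens, shares, decomp)
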