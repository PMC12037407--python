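"""Synthetic input suites with known ground truth.

Real inputs to this pipeline are chemistry-transport model outputs, gridded
census counts, and vital-statistics tables — none of which ship with the
package.  This module generates internally consistent stand-ins that carry
the statistical structure the analysis actually uses:

* spatially correlated concentration fields with a high-pollution
  "central-eastern" block where most of the population also lives;
* two emission scenarios whose national-mean PM2.5 declines from 2010 to
  2049 by configurable fractions (defaults 34% and 78%, the moderate- and
  aggressive-control trajectories the pipeline is built to compare);
* four additive anthropogenic source contributions (biomass burning,
  industry, residential coal heating, on-road tailpipe — default shares
  40/34/16/10% of the anthropogenic mass);
* per-source perturbed runs constructed so that the run-differencing
  apportionment recovers the true source fields exactly when the
  perturbation response is linear (``nonlinearity_eps = 0``), with a
  controllable curvature term for stress-testing;
* an ageing population pyramid (65+ share 8% in 2010 rising to 23% in 2049)
  and age-increasing baseline mortality held fixed across years.

Everything is deterministic given the seed; the emitted
:class:`GroundTruth` is the oracle downstream tests compare against.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .core_grid import (
    AGE_GROUPS,
    BaselineMortalityTable,
    ConcentrationField,
    GridSpec,
    PopulationGrid,
    SOURCES,
    write_field,
)
from .demography import AgeStructure, interpolate_age_shares, slice_population

import pandas as pd

HOTSPOT_REGION = "central-eastern"
OTHER_REGION = "other"

#: Emission-inventory sector reductions behind each 30%-source perturbation,
#: recorded as run metadata only (the generator works at concentration level).
SECTOR_PERTURBATION_METADATA = {
    "re": {"residential": 0.08},
    "bi": {"residential": 0.21, "agricultural": 0.30, "energy": 0.16},
    "in": {"industry": 0.30},
    "tr": {"road_tailpipe": 0.30},
}


class SyntheticConfigError(ValueError):
    """Inconsistent synthetic-suite configuration."""


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic suite; defaults are the study conditions.

    ``total_mean_2010`` (µg m⁻³) sets the 2010 national-mean PM2.5; with the
    default declines this yields absolute drops of ~6.7 (moderate) and
    ~15.3 µg m⁻³ (aggressive) by 2049.  ``nonlinearity_eps`` bends the
    perturbation response: the perturbed run omits a fraction
    ``eps·f`` of the expected concentration response, so apportionment
    under-recovers by exactly that relative amount.
    """

    seed: int = 0
    n_rows: int = 40
    n_cols: int = 40
    cell_area_km2: float = 2500.0
    background_mean: float = 4.0
    total_mean_2010: float = 19.7
    hotspot_fraction: float = 0.25
    hotspot_boost: float = 4.0
    source_shares: dict[str, float] = dc_field(
        default_factory=lambda: {"bi": 0.40, "in": 0.34, "re": 0.16, "tr": 0.10}
    )
    source_decline_weights: dict[str, float] | None = None
    decline_cle: float = 0.34
    decline_mfr: float = 0.78
    years: tuple[int, ...] = (2010, 2020, 2030, 2040, 2049)
    secondary_split: dict[str, float] = dc_field(
        default_factory=lambda: {"soa": 0.15, "sia": 0.35}
    )
    nonlinearity_eps: float = 0.0
    reduction_fraction: float = 0.30
    noise_sigma: float = 3.0
    noise_amplitude: float = 0.15
    population_totals: dict[int, float] = dc_field(
        default_factory=lambda: {
            2010: 1.34e9, 2020: 1.45e9,
            2030: 1.313e9, 2040: 1.273e9, 2049: 1.193e9,
        }
    )
    population_hotspot_share: float = 0.75

    def __post_init__(self) -> None:
        shares = self.source_shares
        if set(shares) != set(SOURCES):
            raise SyntheticConfigError(f"source_shares must cover {SOURCES}")
        if any(not (0 <= v <= 1) for v in shares.values()):
            raise SyntheticConfigError("source shares must lie in [0, 1]")
        if sum(shares.values()) > 1 + 1e-12:
            raise SyntheticConfigError("source shares must sum to <= 1")
        for d in (self.decline_cle, self.decline_mfr):
            if not (0 <= d < 1):
                raise SyntheticConfigError("declines must lie in [0, 1)")
        sec = self.secondary_split
        if sec["soa"] + sec["sia"] >= 1:
            raise SyntheticConfigError("secondary_split fractions must sum < 1")
        if self.background_mean >= self.total_mean_2010:
            raise SyntheticConfigError(
                "background_mean must be below total_mean_2010"
            )
        if any(t < 0 for t in self.population_totals.values()):
            raise SyntheticConfigError("population totals must be >= 0")

    @property
    def scenarios(self) -> dict[str, float]:
        return {"CLE": self.decline_cle, "MFR": self.decline_mfr}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "years" in raw:
            raw["years"] = tuple(int(y) for y in raw["years"])
        if "population_totals" in raw:
            raw["population_totals"] = {
                int(k): float(v) for k, v in raw["population_totals"].items()
            }
        return cls(**raw)


@dataclass
class GroundTruth:
    """Oracle record: the true decomposition behind each emitted NPC run.

    Keys of every mapping are ``(scenario_id, year)``.  With
    ``nonlinearity_eps = 0``, ``background + Σ source_fields`` reproduces
    the emitted NPC total field exactly.
    """

    grid: GridSpec
    background: np.ndarray
    source_fields: dict[tuple[str, int], dict[str, np.ndarray]]
    soa: dict[tuple[str, int], np.ndarray]
    sia: dict[tuple[str, int], np.ndarray]
    npc_total: dict[tuple[str, int], np.ndarray]


def _make_grid(cfg: SyntheticConfig) -> tuple[GridSpec, np.ndarray]:
    """Grid with a contiguous hotspot block toward the centre-east."""
    frac = cfg.hotspot_fraction
    h = max(1, round(cfg.n_rows * np.sqrt(frac)))
    w = max(1, round(cfg.n_cols * frac * cfg.n_rows / h))
    r0 = (cfg.n_rows - h) // 2
    c0 = min(cfg.n_cols - w, int(cfg.n_cols * 0.55))
    mask = np.zeros((cfg.n_rows, cfg.n_cols), dtype=bool)
    mask[r0:r0 + h, c0:c0 + w] = True
    labels = np.where(mask, HOTSPOT_REGION, OTHER_REGION).astype(object)
    grid = GridSpec(cfg.n_rows, cfg.n_cols, cfg.cell_area_km2, labels)
    return grid, mask


def _correlated_pattern(
    rng: np.random.Generator, shape: tuple[int, int],
    sigma: float, amplitude: float,
) -> np.ndarray:
    """Positive mean-one pattern with smooth spatial correlation."""
    noise = gaussian_filter(rng.standard_normal(shape), sigma=sigma,
                            mode="wrap")
    sd = noise.std()
    if sd > 0:
        noise *= amplitude / sd
    pattern = np.clip(1.0 + noise, 0.05, None)
    return pattern / pattern.mean()


def _decline_rates(
    cfg: SyntheticConfig, bg_mean: float, anthro_mean: float, decline: float
) -> dict[str, float]:
    """Per-source anthropogenic decline rates hitting the total-mean target."""
    r = decline * (bg_mean + anthro_mean) / anthro_mean
    weights = cfg.source_decline_weights
    if weights is None:
        weights = {s: 1.0 for s in SOURCES}
    wsum = sum(cfg.source_shares[s] * weights[s] for s in SOURCES)
    share_sum = sum(cfg.source_shares.values())
    rates = {s: r * weights[s] * share_sum / wsum for s in SOURCES}
    for s, rs in rates.items():
        if rs > 1:
            raise SyntheticConfigError(
                f"source {s}: implied decline {rs:.3f} exceeds 1; lower the "
                "decline target or the source's decline weight"
            )
    return rates


def generate_concentration_suite(
    cfg: SyntheticConfig,
) -> tuple[list[ConcentrationField], GroundTruth]:
    """Emit NPC fields (all species) and per-source PC totals for every
    scenario-year, plus the ground-truth decomposition.

    The 2010 fields are identical across scenarios (a shared baseline year);
    the perturbed total for source s is
    ``NPC_total − f·(1 − eps·f)·C_s`` with f the reduction fraction, so the
    apportionment estimate ``(NPC − PC)/f`` equals ``(1 − eps·f)·C_s``.
    """
    grid, mask = _make_grid(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))

    bg = cfg.background_mean * _correlated_pattern(
        rng, grid.shape, cfg.noise_sigma, cfg.noise_amplitude / 2
    )
    anthro_mean = cfg.total_mean_2010 - cfg.background_mean
    pattern = _correlated_pattern(
        rng, grid.shape, cfg.noise_sigma, cfg.noise_amplitude
    )
    pattern = pattern * np.where(mask, cfg.hotspot_boost, 1.0)
    pattern = pattern / pattern.mean() * anthro_mean
    base_sources = {s: cfg.source_shares[s] * pattern for s in SOURCES}
    covered = sum(cfg.source_shares.values())
    other_anthro = (1.0 - covered) * pattern  # unattributed anthropogenic mass

    f = cfg.reduction_fraction
    eps = cfg.nonlinearity_eps
    span = max(cfg.years) - min(cfg.years)
    y0 = min(cfg.years)

    fields: list[ConcentrationField] = []
    gt = GroundTruth(grid=grid, background=bg, source_fields={}, soa={},
                     sia={}, npc_total={})
    for scen, decline in cfg.scenarios.items():
        rates = _decline_rates(cfg, bg.mean(), anthro_mean, decline)
        other_rate = (
            decline * (bg.mean() + anthro_mean) / anthro_mean
        )  # unattributed mass follows the share-weighted mean trajectory
        for year in cfg.years:
            t = (year - y0) / span
            srcs = {
                s: (1.0 - rates[s] * t) * base_sources[s] for s in SOURCES
            }
            total = bg + sum(srcs.values()) + (1.0 - other_rate * t) * other_anthro
            soa = cfg.secondary_split["soa"] * total
            sia = cfg.secondary_split["sia"] * total
            primary = total - soa - sia
            key = (scen, year)
            gt.source_fields[key] = srcs
            gt.soa[key] = soa
            gt.sia[key] = sia
            gt.npc_total[key] = total

            meta = dict(scenario_id=scen, year=year, run_kind="NPC",
                        perturbed_source="none")
            fields.append(ConcentrationField(grid, total, "total_pm25", **meta))
            fields.append(ConcentrationField(grid, soa, "soa", **meta))
            fields.append(ConcentrationField(grid, sia, "sia", **meta))
            fields.append(
                ConcentrationField(grid, primary, "primary_pm25", **meta)
            )
            for s in SOURCES:
                pc = total - f * (1.0 - eps * f) * srcs[s]
                fields.append(ConcentrationField(
                    grid, pc, "total_pm25", scenario_id=scen, year=year,
                    run_kind="PC", perturbed_source=s,
                ))
    return fields, gt


def generate_population(
    cfg: SyntheticConfig, age_model: AgeStructure | None = None
) -> list[PopulationGrid]:
    """Gridded, age-sliced population per year.

    Population density concentrates in the hotspot block
    (``population_hotspot_share`` of the national total); national age
    shares equal the age model's interpolated shares for each year exactly,
    and the per-year national total equals the configured total.
    """
    if age_model is None:
        age_model = AgeStructure.bundled_default()
    grid, mask = _make_grid(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    density = _correlated_pattern(rng, grid.shape, cfg.noise_sigma,
                                  cfg.noise_amplitude)
    w_in = np.where(mask, density, 0.0)
    w_out = np.where(mask, 0.0, density)
    cell_weights = (
        cfg.population_hotspot_share * w_in / w_in.sum()
        + (1 - cfg.population_hotspot_share) * w_out / w_out.sum()
    )
    out = []
    for year in cfg.years:
        total = cfg.population_totals[year]
        shares = interpolate_age_shares(age_model, year)
        counts = slice_population(total * cell_weights, shares)
        out.append(PopulationGrid(grid=grid, counts=counts,
                                  age_groups=AGE_GROUPS, year=year))
    return out


#: Cause-specific baseline rates as fractions of the all-cause schedule;
#: cause mortality is attributed to adults only (zero below age 25).
_CAUSE_FRACTIONS = {
    "IHD": 0.18,
    "stroke": 0.20,
    "COPD": 0.10,
    "LC": 0.06,
    "LRI": 0.025,
}


def generate_baseline_mortality(cfg: SyntheticConfig) -> BaselineMortalityTable:
    """Age-increasing baseline death rates per endpoint (per person-year).

    The all-cause schedule rises exponentially with age group (crude death
    rate ≈ 0.007 per person-year under the 2010 pyramid); each cause is a
    fixed fraction of all-cause (zero below 25), and the combined NCD+LRI
    endpoint is their sum.  The ramp is chosen gentle enough that scenario
    emission declines outweigh population ageing in the linear pathway —
    the regime the declining-burden trajectories emulate.  Rates are
    deterministic — the table plays the role of a fixed reference-year
    vital-statistics input.
    """
    n = len(AGE_GROUPS)
    all_cause = 8e-4 * np.exp(0.25 * np.arange(n))
    adult = np.arange(n) >= 5  # 25+ groups
    rows = []
    for g, rate in zip(AGE_GROUPS, all_cause):
        rows.append(("all_cause_chronic", g, rate))
        rows.append(("all_cause_acute", g, rate))
    ncd_lri = np.zeros(n)
    for cause, frac in _CAUSE_FRACTIONS.items():
        rates = np.where(adult, frac * all_cause, 0.0)
        ncd_lri += rates
        rows.extend(zip([cause] * n, AGE_GROUPS, rates))
    rows.extend(zip(["NCD_LRI"] * n, AGE_GROUPS, ncd_lri))
    df = pd.DataFrame(rows, columns=["endpoint", "age_group", "rate"])
    return BaselineMortalityTable(df)


def suite_filename(f: ConcentrationField) -> str:
    return (
        f"{f.scenario_id}_{f.year}_{f.run_kind}_"
        f"{f.perturbed_source}_{f.species}.nc"
    )


def write_suite(cfg: SyntheticConfig, out_dir: str | Path) -> Path:
    """Write the full suite (NetCDF fields, CSV tables, ground-truth sidecar)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fields, gt = generate_concentration_suite(cfg)
    for f in fields:
        write_field(f, out / suite_filename(f))
    pops = generate_population(cfg)
    for p in pops:
        np.save(out / f"population_{p.year}.npy", p.counts)
    generate_baseline_mortality(cfg).to_csv(out / "baseline_mortality.csv")
    AgeStructure.bundled_default().to_csv(out / "age_structure.csv")
    sidecar = {
        f"{scen}_{year}_{src}": arr
        for (scen, year), srcs in gt.source_fields.items()
        for src, arr in srcs.items()
    }
    np.savez(out / "ground_truth.npz", background=gt.background, **sidecar)
    with open(out / "sector_perturbations.yaml", "w") as fh:
        yaml.safe_dump(SECTOR_PERTURBATION_METADATA, fh)
    return out
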