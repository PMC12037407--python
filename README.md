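# pmburden

Source-apportioned PM2.5 health-burden pipeline for scenario analysis:
estimate premature deaths attributable to fine-particle exposure over a
gridded, age-structured population, split the burden by emission source
using perturbation-run differencing, and report scenario statistics
(percent changes, multi-year averages, linear-vs-nonlinear gaps, source
decompositions).

It is written for air-quality and environmental-health researchers who have
chemistry-transport model output (annual-mean PM2.5 fields for a reference
run and for runs with individual emission sources reduced by a known
fraction) and want the downstream health accounting: exposure →
relative risk → attributable deaths → scenario tables. A synthetic-data
generator produces complete, internally consistent input suites with known
ground truth, so the whole pipeline is testable without any model output.

## The model

**Source apportionment.** With a reference (non-perturbed, NPC) run and a
run in which source *P*'s emissions are cut by a fraction *f* (PC), the
source's concentration contribution per cell is

    C_P = (C_NPC − C_PC) / f

with *f* = 0.30 by default — large enough to beat numerical noise, small
enough to stay in the near-linear chemistry regime. Primary and secondary
splits follow `C_P,primary = C_P,total − C_P,SIA − C_P,SOA` and
`C_secondary = C_NPC,SOA + C_NPC,SIA`.

**Exposure-response.** Two pathways:

* *Linear all-cause* (acute + chronic): RR(c) = 1 + (RR₁₀ − 1)·(c − c₀)⁺/10,
  default RR₁₀ = 1.08 per 10 µg m⁻³ (the WHO-recommended long-term
  all-cause value), counterfactual c₀ = 0.
* *GEMM* cause-specific hazard ratios (lung cancer, COPD, ischemic heart
  disease, stroke, lower respiratory infections, and the combined
  NCD+LRI function):

      RR(c) = exp( θ · ln(z/α + 1) / (1 + exp(−(z − μ)/ν)) ),
      z = max(0, c − 2.4 µg m⁻³)

  applied to adults (25+) against cause- and age-specific baseline
  mortality.

**Burden.** Deaths = Σ_cells Σ_ages pop · baseline_rate · AF(RR(c)), with
AF = (RR−1)/RR (or the proportional form RR−1, which makes per-source
linear burdens exactly additive), aggregated nationally and by region
label.

## Worked example

```python
from pmburden import (gemm_rr, linear_rr, load_gemm_params,
                      load_table1_fixture, headline_statistics)

print(linear_rr(10.0))                      # 1.08
p = load_gemm_params()["NCD_LRI"]
print(round(gemm_rr(12.4, p), 4))           # e.g. 1.1401 at θ=0.143, α=1.6, μ=15.5, ν=36.8
stats = headline_statistics(load_table1_fixture())
print(stats["cle_linear_total_pct_change_2049"])        # -43
print(stats["cle_linear_annual_avg_2020_2049_millions"])  # 2.39
print(stats["mfr_nonlinear_vs_linear_delta_pct"])       # -9
```

The first two lines evaluate the risk functions directly: +8% relative risk
at 10 µg m⁻³ on the linear pathway, and a 14% excess hazard at 12.4 µg m⁻³
under the combined-cause GEMM shape. The reporting statistics are computed
from the bundled scenario table of premature deaths (millions) for a
2010–2049 projection under a current-legislation (CLE) and a
maximum-feasible-reduction (MFR) emission scenario: by 2049 the linear-total
burden falls 43% under CLE, the 2020–2049 linear annual average is
2.39 million deaths, and the nonlinear (GEMM) pathway averages 9% below the
linear one under MFR.

An end-to-end synthetic run (generate suite → apportion → burden → report):

```python
from pmburden.synthetic import SyntheticConfig
from pmburden.pipeline import run_synthetic_pipeline

res = run_synthetic_pipeline(SyntheticConfig(seed=42))
print({s: round(v, 3) for s, v in res.source_shares["CLE"].items()})
# {'re': 0.16, 'bi': 0.4, 'in': 0.34, 'tr': 0.1}
```

The recovered source shares of the linear burden match the generator's
configured emission shares (biomass burning 40%, industry 34%, residential
coal 16%, tailpipe transport 10%) because the apportionment and the delta-AF
linear burden are both exact linear maps.

There is also a CLI: `pmburden simulate`, `pmburden apportion`,
`pmburden report` (see `pmburden --help`).

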