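import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from pmburden.burden import (
    BurdenConfigError,
    EndpointSpec,
    attributable_deaths,
    linear_total_deaths,
    nonlinear_total_deaths,
    source_attributable_deaths,
)
from pmburden.apportionment import SourceConcentrationSet
from pmburden.core_grid import (
    AGE_GROUPS,
    BaselineMortalityTable,
    ConcentrationField,
    GridSpec,
    PopulationGrid,
)
from pmburden.exposure_response import GEMMParams, LinearERF
from tests.conftest import one_cell_population

N = len(AGE_GROUPS)


def uniform_baseline(rate, endpoints=("all_cause_chronic",)):
    rows = [(e, g, rate) for e in endpoints for g in AGE_GROUPS]
    return BaselineMortalityTable(
        pd.DataFrame(rows, columns=["endpoint", "age_group", "rate"])
    )


def conc_field(values, grid=None):
    values = np.asarray(values, dtype=float)
    if grid is None:
        grid = GridSpec.uniform(*values.shape)
    return ConcentrationField(grid, values, "total_pm25",
                              scenario_id="CLE", year=2010)


class TestWorkedExamples:
    def test_one_cell_linear_delta_example(self):
        """1e6 adults x 0.01 baseline rate x 8% excess risk = 800 deaths."""
        pop = one_cell_population(1_000_000, "45–49")
        base = uniform_baseline(0.01)
        spec = EndpointSpec("all_cause_chronic", "linear",
                            LinearERF(rr_per_10=1.08), af_form="delta")
        out = attributable_deaths(conc_field([[10.0]]), pop, base, spec)
        assert out["all"] == pytest.approx(800.0, abs=1e-9)

    def test_zero_concentration_zero_deaths(self, gemm_fixture_params):
        pop = one_cell_population(1e6, "45–49")
        base = uniform_baseline(0.01, endpoints=("all_cause_chronic",
                                                 "NCD_LRI"))
        for spec in (
            EndpointSpec("all_cause_chronic", "linear", LinearERF()),
            EndpointSpec("NCD_LRI", "gemm", gemm_fixture_params),
        ):
            out = attributable_deaths(conc_field([[0.0]]), pop, base, spec)
            assert out["all"] == 0.0

    def test_gemm_counterfactual_concentration_zero_deaths(
        self, gemm_fixture_params
    ):
        pop = one_cell_population(1e6, "45–49")
        base = uniform_baseline(0.01, endpoints=("NCD_LRI",))
        spec = EndpointSpec("NCD_LRI", "gemm", gemm_fixture_params)
        out = attributable_deaths(conc_field([[2.4]]), pop, base, spec)
        assert out["all"] == 0.0

    def test_missing_baseline_row_names_endpoint_and_age(self):
        pop = one_cell_population(1e6, "45–49")
        base = uniform_baseline(0.01, endpoints=("all_cause_chronic",))
        spec = EndpointSpec("IHD", "gemm",
                            GEMMParams("IHD", 0.1, 1.0, 1.0, 1.0))
        with pytest.raises(BurdenConfigError, match="IHD"):
            attributable_deaths(conc_field([[10.0]]), pop, base, spec)


class TestBruteForceOracle:
    def test_three_cell_enumeration_matches(self, gemm_fixture_params):
        """Independent cell-by-age loop reproduces the vectorized sums."""
        rng = np.random.default_rng(5)
        labels = np.array([["a", "b", "a"]], dtype=object)
        grid = GridSpec(1, 3, 2500.0, labels)
        counts = np.zeros((1, 3, N))
        active = ["30–34", "50–54", "70–74"]
        for g in active:
            counts[0, :, AGE_GROUPS.index(g)] = rng.uniform(1e4, 1e6, 3)
        pop = PopulationGrid(grid=grid, counts=counts,
                             age_groups=AGE_GROUPS, year=2010)
        rates = {g: r for g, r in zip(AGE_GROUPS,
                                      np.linspace(0.001, 0.1, N))}
        base = BaselineMortalityTable(pd.DataFrame(
            [("NCD_LRI", g, r) for g, r in rates.items()],
            columns=["endpoint", "age_group", "rate"],
        ))
        conc = conc_field(rng.uniform(0, 60, (1, 3)), grid=grid)
        spec = EndpointSpec("NCD_LRI", "gemm", gemm_fixture_params,
                            af_form="ratio")

        # independent brute force, scalar math only
        p = gemm_fixture_params
        expected = {"all": 0.0, "a": 0.0, "b": 0.0}
        for j in range(3):
            c = conc.values[0, j]
            z = max(0.0, c - p.counterfactual)
            rr = math.exp(p.theta * math.log(z / p.alpha + 1.0)
                          / (1.0 + math.exp(-(z - p.mu) / p.nu)))
            af = (rr - 1.0) / rr
            for k, g in enumerate(AGE_GROUPS):
                if k < 5:  # GEMM endpoints apply to 25+ only
                    continue
                d = counts[0, j, k] * rates[g] * af
                expected["all"] += d
                expected[labels[0, j]] += d

        out = attributable_deaths(conc, pop, base, spec)
        for key in expected:
            assert out[key] == pytest.approx(expected[key], rel=1e-12)

    def test_region_rows_sum_to_national(self):
        rng = np.random.default_rng(6)
        labels = rng.choice(["r1", "r2", "r3"], size=(5, 5)).astype(object)
        grid = GridSpec(5, 5, 2500.0, labels)
        counts = rng.uniform(0, 1e5, (5, 5, N))
        pop = PopulationGrid(grid=grid, counts=counts,
                             age_groups=AGE_GROUPS, year=2010)
        base = uniform_baseline(0.01)
        spec = EndpointSpec("all_cause_chronic", "linear", LinearERF())
        out = attributable_deaths(
            conc_field(rng.uniform(0, 40, (5, 5)), grid=grid), pop, base, spec
        )
        regional = out["r1"] + out["r2"] + out["r3"]
        assert regional == pytest.approx(out["all"], rel=1e-12)

    def test_monotone_in_concentration(self, gemm_fixture_params):
        pop = one_cell_population(1e6, "45–49")
        base = uniform_baseline(0.01, endpoints=("all_cause_chronic",
                                                 "NCD_LRI"))
        for spec in (
            EndpointSpec("all_cause_chronic", "linear", LinearERF()),
            EndpointSpec("NCD_LRI", "gemm", gemm_fixture_params),
        ):
            deaths = [
                attributable_deaths(conc_field([[c]]), pop, base, spec)["all"]
                for c in (0.0, 5.0, 10.0, 20.0, 50.0)
            ]
            assert all(b >= a for a, b in zip(deaths, deaths[1:]))


class TestTotals:
    @pytest.mark.parametrize("acute,chronic,total",
                             [(0.37, 3.08, 3.45), (0.0, 5.0, 5.0),
                              (0.06, 0.63, 0.69)])
    def test_linear_total(self, acute, chronic, total):
        assert linear_total_deaths(acute, chronic) == pytest.approx(total)

    def test_nonlinear_sum_causes(self):
        causes = {"LC": 0.17, "COPD": 0.29, "IHD": 0.47, "stroke": 0.15,
                  "LRI": 0.07}
        assert nonlinear_total_deaths(causes) == pytest.approx(1.15)
        assert nonlinear_total_deaths(
            {c: 0.0 for c in causes}
        ) == 0.0

    def test_nonlinear_ncd_lri_mode(self):
        assert nonlinear_total_deaths({"NCD_LRI": 1.75},
                                      mode="ncd_lri") == 1.75

    def test_missing_cause_rejected(self):
        with pytest.raises(BurdenConfigError, match="stroke"):
            nonlinear_total_deaths({"LC": 1.0, "COPD": 1.0, "IHD": 1.0,
                                    "LRI": 1.0})


class TestSourceBurdens:
    @staticmethod
    def make_inputs(fields):
        grid = GridSpec.uniform(2, 2)
        counts = np.zeros((2, 2, N))
        counts[..., AGE_GROUPS.index("40–44")] = 2.5e5
        pop = PopulationGrid(grid=grid, counts=counts,
                             age_groups=AGE_GROUPS, year=2010)
        base = uniform_baseline(0.008, endpoints=("all_cause_chronic",
                                                  "all_cause_acute"))
        src = SourceConcentrationSet(grid=grid, totals=fields,
                                     scenario_id="CLE", year=2010)
        return src, pop, base

    def test_identical_fields_identical_deaths(self):
        f = np.full((2, 2), 6.0)
        src, pop, base = self.make_inputs(
            {"re": f.copy(), "bi": f.copy(), "in": f.copy(), "tr": f.copy()}
        )
        table = source_attributable_deaths(src, pop, base)
        deaths = [table.deaths("CLE", 2010, "all_cause_total", source=s)
                  for s in ("re", "bi", "in", "tr")]
        assert len({round(d, 9) for d in deaths}) == 1

    def test_delta_form_is_exactly_additive(self):
        rng = np.random.default_rng(8)
        fields = {s: rng.uniform(0, 8, (2, 2))
                  for s in ("re", "bi", "in", "tr")}
        src, pop, base = self.make_inputs(fields)
        table = source_attributable_deaths(src, pop, base, af_form="delta")
        summed = sum(
            table.deaths("CLE", 2010, "all_cause_total", source=s)
            for s in ("re", "bi", "in", "tr")
        )
        combined = SourceConcentrationSet(
            grid=src.grid, totals={"re": sum(fields.values())},
            scenario_id="CLE", year=2010,
        )
        t2 = source_attributable_deaths(combined, pop, base, af_form="delta")
        assert summed == pytest.approx(
            t2.deaths("CLE", 2010, "all_cause_total", source="re"), rel=1e-12
        )


class TestParameterRecovery:
    def test_linear_slope_recovered_by_root_finding(self, small_cfg,
                                                    small_suite,
                                                    small_population,
                                                    baseline):
        """Invert the national linear death count for its generating slope."""
        fields, _ = small_suite
        conc = next(f for f in fields if f.run_kind == "NPC"
                    and f.species == "total_pm25"
                    and (f.scenario_id, f.year) == ("CLE", 2010))
        pop = next(p for p in small_population if p.year == 2010)
        true_slope = 1.08

        def national_deaths(rr10):
            spec = EndpointSpec("all_cause_chronic", "linear",
                                LinearERF(rr_per_10=rr10), af_form="delta")
            return attributable_deaths(conc, pop, baseline, spec)["all"]

        target = national_deaths(true_slope)
        recovered = brentq(lambda r: national_deaths(r) - target,
                           1.0 + 1e-9, 2.0, xtol=1e-9)
        assert recovered == pytest.approx(true_slope, abs=1e-6)
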