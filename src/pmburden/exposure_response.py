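"""Exposure-response functions: linear all-cause risk and the GEMM hazard ratio.

Two risk pathways are supported:

* a **linear** all-cause function in which relative risk rises by a fixed
  amount per 10 µg m⁻³ of PM2.5 (default +8%, the WHO-recommended
  meta-analytic value for long-term all-cause mortality);
* the **GEMM** (Global Exposure Mortality Model) log-logistic hazard-ratio
  family for cause-specific adult mortality,

      RR(c) = exp( θ · ln(z/α + 1) / (1 + exp(−(z − μ)/ν)) ),
      z = max(0, c − c₀),

  with a counterfactual (cut-off) concentration c₀ = 2.4 µg m⁻³ below which
  no excess risk is attributed.  θ controls the overall slope, α the
  low-concentration curvature, and (μ, ν) the location and width of the
  logistic flattening at high concentration.

The attributable fraction converts a relative risk into the share of
baseline deaths assigned to the exposure; two standard forms are offered,
``ratio`` AF = (RR−1)/RR and ``delta`` AF = RR−1 (the latter exactly linear,
hence exactly additive over sources in the linear pathway).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

GEMM_COUNTERFACTUAL = 2.4  # µg m⁻³
AF_FORMS = ("ratio", "delta")


class ERFDomainError(ValueError):
    """Input outside the domain of an exposure-response function."""


@dataclass(frozen=True)
class LinearERF:
    """Straight-line relative risk: RR(c) = 1 + (rr_per_10 − 1)·(c − c₀)⁺/10."""

    rr_per_10: float = 1.08
    endpoint: str = "all_cause_chronic"
    counterfactual: float = 0.0

    def __post_init__(self) -> None:
        if self.rr_per_10 < 1.0:
            raise ERFDomainError("rr_per_10 must be >= 1")
        if self.counterfactual < 0.0:
            raise ERFDomainError("counterfactual must be >= 0")


#: Placeholder short-term (acute) all-cause coefficient.  The acute RR is a
#: configuration input, not an epidemiological constant of this package; the
#: default is calibrated so that acute deaths are ~11% of the linear total in
#: a high-exposure baseline year, matching the structural acute/chronic split
#: of the scenario tables this pipeline reports on.
DEFAULT_ACUTE_ERF = LinearERF(rr_per_10=1.0096, endpoint="all_cause_acute")
DEFAULT_CHRONIC_ERF = LinearERF(rr_per_10=1.08, endpoint="all_cause_chronic")


@dataclass(frozen=True)
class GEMMParams:
    """Parameters (θ, α, μ, ν, counterfactual) of one GEMM hazard function."""

    endpoint: str
    theta: float
    alpha: float
    mu: float
    nu: float
    counterfactual: float = GEMM_COUNTERFACTUAL
    age_group: str = "adult_25plus"

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.nu <= 0:
            raise ERFDomainError("alpha and nu must be > 0")
        if self.theta < 0:
            raise ERFDomainError("theta must be >= 0")
        if self.counterfactual < 0:
            raise ERFDomainError("counterfactual must be >= 0")


def gemm_rr(c, p: GEMMParams):
    """GEMM relative risk at concentration ``c`` (µg m⁻³; scalar or array).

    Returns 1 exactly for c at or below the counterfactual; strictly
    non-decreasing in c for θ ≥ 0.  Natural logarithm throughout.
    """
    c = np.asarray(c, dtype=float)
    if not np.all(np.isfinite(c)):
        raise ERFDomainError("concentration must be finite")
    if np.any(c < 0):
        raise ERFDomainError("concentration must be >= 0")
    z = np.maximum(0.0, c - p.counterfactual)
    logistic = 1.0 + np.exp(-(z - p.mu) / p.nu)
    rr = np.exp(p.theta * np.log(z / p.alpha + 1.0) / logistic)
    return rr if rr.ndim else float(rr)


def linear_rr(c, erf: LinearERF = DEFAULT_CHRONIC_ERF):
    """Linear relative risk at concentration ``c`` (scalar or array)."""
    c = np.asarray(c, dtype=float)
    if not np.all(np.isfinite(c)):
        raise ERFDomainError("concentration must be finite")
    if np.any(c < 0):
        raise ERFDomainError("concentration must be >= 0")
    excess = np.maximum(0.0, c - erf.counterfactual)
    rr = 1.0 + (erf.rr_per_10 - 1.0) * excess / 10.0
    return rr if rr.ndim else float(rr)


def attributable_fraction(rr, form: str = "ratio"):
    """Share of baseline deaths attributed to the exposure.

    ``ratio`` gives (RR−1)/RR, bounded in [0, 1); ``delta`` gives RR−1, the
    strictly proportional form (can exceed 1 at extreme RR, exactly additive
    over concentration increments in the linear pathway).
    """
    rr = np.asarray(rr, dtype=float)
    if np.any(rr < 1.0):
        raise ERFDomainError("relative risk must be >= 1")
    if form == "ratio":
        af = (rr - 1.0) / rr
    elif form == "delta":
        af = rr - 1.0
    else:
        raise ERFDomainError(f"unknown AF form {form!r}; pick from {AF_FORMS}")
    return af if af.ndim else float(af)


def load_gemm_params(path: str | Path | None = None) -> dict[str, GEMMParams]:
    """Load per-cause GEMM parameters from CSV (endpoint → params).

    With no path, loads the bundled ``data/gemm_params.csv`` transcription of
    the published adult (25+) GEMM fits.  The file is editable data, not
    code: analyses that need different parameter sets point this loader at
    their own CSV with columns endpoint, age_group, theta, alpha, mu, nu,
    counterfactual.
    """
    if path is None:
        ref = resources.files("pmburden").joinpath("data/gemm_params.csv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    out: dict[str, GEMMParams] = {}
    for row in df.itertuples():
        out[row.endpoint] = GEMMParams(
            endpoint=row.endpoint,
            theta=float(row.theta),
            alpha=float(row.alpha),
            mu=float(row.mu),
            nu=float(row.nu),
            counterfactual=float(row.counterfactual),
            age_group=str(row.age_group),
        )
    return out
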