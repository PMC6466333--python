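"""Soil trace-metal accumulation under repeated fertilizer application.

Model: each application year adds a constant flux to a homogeneous 20 cm
plow layer (volume V per hectare, bulk density rho_b), with no loss terms
(leaching, runoff, crop uptake and atmospheric deposition are outside the
model, which therefore slightly overestimates accumulation):

    Qp = IR_f * alpha / (rho_b * V)          [mg metal / kg soil / yr]
    Q(n) = Q0 + n * Qp                       [mg/kg after n years]
    T  = (Cs - Q0) / Qp                      [years to the soil limit Cs]

``alpha`` is the fertilizer concentration (median of the survey for the
deterministic tables), ``IR_f`` the application rate (t/hm2/yr).  The
units work out because one tonne of fertilizer per 10^3 kg cancels the
same factor in the soil mass rho_b * V.

The Monte Carlo variant propagates the fitted concentration distribution
(see :mod:`fertrisk.synthetic`) through the same closed form, yielding the
distribution of T.  Because T is a monotone function of alpha, the median
of the simulated T equals (up to sampling noise) the deterministic T
evaluated at the distribution median — a built-in consistency oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .metals import METALS, Metal
from .params import RegionParameters
from .synthetic import DistributionSpec, sample_spec


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5))


def annual_input(alpha: float, params: RegionParameters, metal: Metal | str = "") -> float:
    """Annual metal input flux Qp (mg per kg plow-layer soil per year).

    ``metal`` is accepted for interface symmetry; the flux depends only on
    the fertilizer concentration ``alpha`` (mg/kg DW) and the regional
    application parameters.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    return params.IR_f * alpha / (params.rho_b * params.V_plow)


def cumulative_concentration(q0: float, qp: float, years: float) -> float:
    """Soil concentration after ``years`` of application: Q0 + years*Qp."""
    if years < 0:
        raise ValueError("years must be >= 0")
    return q0 + years * qp


@dataclass(frozen=True)
class TimeToLimit:
    """Years until the soil concentration reaches the limit Cs.

    ``years`` is +inf when the input flux is zero and 0 (with
    ``already_exceeding`` set) when the background is at or above the
    limit.  When finite and positive it satisfies Q0 + years*Qp == Cs
    exactly.
    """

    years: float
    already_exceeding: bool = False

    @property
    def rounded(self) -> float:
        return math.inf if math.isinf(self.years) else round_half_up(self.years)


def time_to_limit(q0: float, qp: float, cs: float) -> TimeToLimit:
    """Closed-form years for Q0 + T*Qp to reach the soil limit ``cs``."""
    if cs <= 0:
        raise ValueError("cs must be > 0")
    if q0 >= cs:
        return TimeToLimit(years=0.0, already_exceeding=True)
    if qp == 0:
        return TimeToLimit(years=math.inf)
    return TimeToLimit(years=(cs - q0) / qp)


def accumulation_table(
    params: RegionParameters,
    alpha: Mapping[Metal, float],
    soil_limits: Mapping[Metal, float],
) -> pd.DataFrame:
    """Deterministic per-metal flux and time-to-limit for one region.

    ``alpha`` maps each metal to its fertilizer concentration (typically
    the survey median).  Returns a frame indexed by metal with columns
    ``alpha``, ``Qp``, ``T_years`` (unrounded), ``T_rounded`` (half-up,
    computed from the unrounded flux) and ``already_exceeding``.
    """
    rows = []
    for m in METALS:
        qp = annual_input(alpha[m], params, m)
        t = time_to_limit(params.Q0[m], qp, soil_limits[m])
        rows.append(
            {
                "metal": m.value,
                "alpha": float(alpha[m]),
                "Qp": qp,
                "T_years": t.years,
                "T_rounded": t.rounded,
                "already_exceeding": t.already_exceeding,
            }
        )
    out = pd.DataFrame(rows).set_index("metal")
    out.attrs["region"] = params.region_name
    return out


@dataclass(frozen=True)
class SimulationConfig:
    """Monte Carlo settings for the time-to-limit simulation.

    ``truncate_to_range`` restricts fertilizer-concentration draws to the
    observed survey range.  The default is False: the observed extremes
    are a property of the finite survey, and truncating at them biases
    the simulated time distribution (and breaks the median-transform
    identity) wherever the observed maximum is close to the median.
    """

    n_iterations: int = 100_000
    seed: int = 0
    family: str = "lognormal"
    report_quantiles: Sequence[float] = (0.05, 0.5, 0.95)
    truncate_to_range: bool = False

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def mc_time_to_limit(
    specs: Mapping[Metal, DistributionSpec],
    params: RegionParameters,
    soil_limits: Mapping[Metal, float],
    config: SimulationConfig = SimulationConfig(),
    horizons: Sequence[float] = (),
) -> pd.DataFrame:
    """Monte Carlo distribution of the time for soil to reach its limit.

    Per iteration and metal, a fertilizer concentration is drawn from the
    fitted spec, converted to a flux and a time-to-limit.  Returns a frame
    indexed by metal with the flux/time quantiles requested in ``config``
    (columns ``T_q05`` etc.), the deterministic time at the spec median,
    and ``P(T<=h)`` columns for each requested horizon.  Reproducible
    under a fixed seed; all-infinite times yield +inf quantiles.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    empirical_ok = config.family in ("lognormal", "empirical")
    if not empirical_ok:
        raise ValueError(f"unknown family {config.family!r}")
    for m in METALS:
        spec = specs[m]
        if config.family == "lognormal" and spec.family != "lognormal":
            spec = DistributionSpec(
                median=spec.median, cv=spec.cv, range_low=spec.range_low,
                range_high=spec.range_high, family="lognormal",
            )
        alpha = sample_spec(
            spec, config.n_iterations, rng, truncate=config.truncate_to_range
        )
        qp = params.IR_f * alpha / (params.rho_b * params.V_plow)
        cs, q0 = soil_limits[m], params.Q0[m]
        with np.errstate(divide="ignore"):
            t = np.where(qp > 0, (cs - q0) / np.where(qp > 0, qp, 1.0), math.inf)
        t = np.where(q0 >= cs, 0.0, t)
        det = time_to_limit(q0, annual_input(spec.median, params, m), cs)
        row: dict[str, float | str] = {"metal": m.value, "T_det": det.years}
        finite = np.isfinite(t)
        for q in config.report_quantiles:
            label = f"T_q{int(round(q * 100)):02d}"
            row[label] = float(np.quantile(t, q)) if finite.any() else math.inf
        for h in horizons:
            row[f"P(T<={h:g})"] = float((t <= h).mean())
        rows.append(row)
    out = pd.DataFrame(rows).set_index("metal")
    out.attrs["region"] = params.region_name
    out.attrs["seed"] = config.seed
    out.attrs["n_iterations"] = config.n_iterations
    return out
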