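"""Three-pathway human exposure dosimetry and health-risk indexing.

For a soil concentration Qi (mg/kg) the chronic daily doses via soil
ingestion (oral, f), dermal contact (s) and inhalation of suspended
particles (b) are, in mg metal per kg body weight per day:

    Q_f = Qi * IR_p * EF_a * ED_a * c_f / (BW * LT) * 1e-6
    Q_s = Qi * EV * (SA*1e4) * mu * eta * EF_a * ED_a * c_s / (BW * LT) * 1e-6
    Q_b = Qi * omega * IR_b * ED_a * c_b
             * (f_spod*EFOD_a + f_spid*EFID_a) / (BW * LT) * 1e-6

SA is converted m2 -> cm2 before multiplying the adherence eta (mg/cm2);
the 1e-6 converts mg soil to kg soil.  Every dose is exactly linear in Qi.

Coefficient modes
-----------------
``as_written`` applies the route-specific absorption fractions as the
dose equations are usually stated: beta (gastrointestinal) orally, gamma
(skin) dermally, theta (lung) for inhalation.  ``as_published`` — the
default — applies the gastrointestinal beta in all three routes, which is
the convention the study's published risk tables follow (confirmed by
reproducing every table cell).  Both are kept side by side; for a given
metal the two modes differ by the exact factors gamma/beta (dermal) and
theta/beta (respiratory).

Risk indices: HQ_i = sum_j Q_ij / RfD_ij per metal, HI = sum_i HQ_i
(HI > 1 flags potential non-carcinogenic effects); CR_i = sum_j Q_ij *
SF_i for the carcinogens Cr, Ni, As, Cd, TCR = sum_i CR_i (1e-6
negligible, 1e-4 maximum acceptable).  A qualitative grade combines the
HI band and the TCR band through a 4x4 matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping

import pandas as pd

from .metals import CARCINOGENS, METALS, Metal
from .params import (
    ExposureParameters,
    RegionParameters,
    ToxicityParameters,
    load_exposure_parameters,
    load_toxicity_parameters,
)

CoefficientMode = Literal["as_published", "as_written"]

PATHWAYS = ("oral", "dermal", "respiratory")


def _coeff(ep: ExposureParameters, metal: Metal, pathway: str, mode: str) -> float:
    if mode not in ("as_published", "as_written"):
        raise ValueError(f"unknown coefficient mode {mode!r}")
    if mode == "as_published" or pathway == "oral":
        return ep.beta[metal]
    return {"dermal": ep.gamma, "respiratory": ep.theta}[pathway][metal]


def oral_dose(
    qi: float, ep: ExposureParameters, metal: Metal,
    mode: CoefficientMode = "as_published",
) -> float:
    """Chronic daily dose via soil ingestion, mg/kg/day."""
    if qi < 0:
        raise ValueError("qi must be >= 0")
    c = _coeff(ep, metal, "oral", mode)
    return qi * ep.IR_p * ep.EF_a * ep.ED_a * c / (ep.BW * ep.LT) * 1e-6


def dermal_dose(
    qi: float, ep: ExposureParameters, metal: Metal,
    mode: CoefficientMode = "as_published",
) -> float:
    """Chronic daily dose via dermal soil contact, mg/kg/day."""
    if qi < 0:
        raise ValueError("qi must be >= 0")
    c = _coeff(ep, metal, "dermal", mode)
    contact = ep.EV * (ep.SA * 1e4) * ep.mu * ep.eta  # mg soil per day
    return qi * contact * ep.EF_a * ep.ED_a * c / (ep.BW * ep.LT) * 1e-6


def respiratory_dose(
    qi: float, ep: ExposureParameters, metal: Metal,
    mode: CoefficientMode = "as_published",
) -> float:
    """Chronic daily dose via inhaled suspended soil particles, mg/kg/day."""
    if qi < 0:
        raise ValueError("qi must be >= 0")
    c = _coeff(ep, metal, "respiratory", mode)
    ef = ep.f_spod * ep.EFOD_a + ep.f_spid * ep.EFID_a  # day/yr soil-particle exposure
    return qi * ep.omega * ep.IR_b * ep.ED_a * c * ef / (ep.BW * ep.LT) * 1e-6


def dose_profile(
    soil_concentrations: Mapping[Metal, float],
    ep: ExposureParameters,
    mode: CoefficientMode = "as_published",
) -> pd.DataFrame:
    """Doses for all metals and pathways.

    Returns a frame indexed by metal with columns ``Qi``, ``oral``,
    ``dermal``, ``respiratory`` (mg/kg/day).
    """
    rows = []
    for m in METALS:
        qi = float(soil_concentrations[m])
        rows.append(
            {
                "metal": m.value,
                "Qi": qi,
                "oral": oral_dose(qi, ep, m, mode),
                "dermal": dermal_dose(qi, ep, m, mode),
                "respiratory": respiratory_dose(qi, ep, m, mode),
            }
        )
    return pd.DataFrame(rows).set_index("metal")


def hazard_quotients(
    doses: pd.DataFrame, tox: ToxicityParameters
) -> tuple[pd.DataFrame, float]:
    """Per-metal, per-pathway hazard quotients and the hazard index.

    HQ columns mirror the dose pathways plus a ``total``; the returned
    scalar HI is the sum of per-metal totals over all seven metals.
    """
    rfd = {"oral": tox.RfD_f, "dermal": tox.RfD_s, "respiratory": tox.RfD_b}
    rows = []
    for m in METALS:
        hq = {p: doses.loc[m.value, p] / rfd[p][m] for p in PATHWAYS}
        hq["total"] = sum(hq.values())
        rows.append({"metal": m.value, **hq})
    out = pd.DataFrame(rows).set_index("metal")
    return out, float(out["total"].sum())


def cancer_risks(
    doses: pd.DataFrame, tox: ToxicityParameters
) -> tuple[pd.DataFrame, float]:
    """Per-carcinogen, per-pathway cancer risks and the total cancer risk.

    Only Cr, Ni, As and Cd carry slope factors; requesting others is an
    error by construction (they are simply not rows of the output).
    """
    rows = []
    for m in CARCINOGENS:
        sf = tox.SF[m]
        cr = {p: doses.loc[m.value, p] * sf for p in PATHWAYS}
        cr["total"] = sum(cr.values())
        rows.append({"metal": m.value, **cr})
    out = pd.DataFrame(rows).set_index("metal")
    return out, float(out["total"].sum())


#: Table rows: carcinogenic band (TCR); columns: non-carcinogenic band (HI).
_GRADE_MATRIX = (
    ("Low risk", "Low risk", "Moderate risk", "High risk"),
    ("Low risk", "Moderate risk", "Moderate risk", "High risk"),
    ("Moderate risk", "Moderate risk", "High risk", "Extreme risk"),
    ("High risk", "High risk", "Extreme risk", "Extreme risk"),
)
_HI_EDGES = (0.25, 0.50, 0.75, 1.00)   # right-closed bins
_TCR_EDGES = (1e-6, 1e-5, 1e-4)


@dataclass(frozen=True)
class GradeResult:
    """Qualitative combined risk grade with its contributing bands."""

    label: str
    hi_band: int      # 0 = lowest non-carcinogenic band
    tcr_band: int     # 0 = lowest carcinogenic band
    hi_above_one: bool

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.label


def grade(hi: float, tcr: float) -> GradeResult:
    """Combined qualitative health-risk grade.

    HI bins are right-closed at 0.25/0.50/0.75/1.00; HI > 1 clamps into
    the extreme band and is flagged.  TCR bins are right-closed at
    1e-6/1e-5, with >= 1e-4 the extreme band.
    """
    if hi < 0 or tcr < 0:
        raise ValueError("hi and tcr must be >= 0")
    hi_band = next((i for i, e in enumerate(_HI_EDGES) if hi <= e), 3)
    tcr_band = (
        3 if tcr >= 1e-4
        else next((i for i, e in enumerate(_TCR_EDGES) if tcr <= e), 2)
    )
    return GradeResult(
        label=_GRADE_MATRIX[tcr_band][hi_band],
        hi_band=hi_band,
        tcr_band=tcr_band,
        hi_above_one=hi > 1.0,
    )


@dataclass(frozen=True)
class RiskReport:
    """Bundle of doses, hazard and cancer indices and the grade."""

    region: str
    mode: str
    years: float
    doses: pd.DataFrame
    hq: pd.DataFrame
    hi: float
    cr: pd.DataFrame
    tcr: float
    grade: GradeResult


def assess(
    params: RegionParameters,
    alpha: Mapping[Metal, float],
    ep: ExposureParameters | None = None,
    tox: ToxicityParameters | None = None,
    mode: CoefficientMode = "as_published",
    years: float = 1.0,
) -> RiskReport:
    """End-to-end risk assessment for one region.

    The exposure soil concentration is the background plus ``years``
    (default 1) of fertilizer input computed from the concentrations
    ``alpha`` (typically survey medians): Qi = Q0 + years*Qp.
    """
    from .accumulation import annual_input  # local import avoids a cycle

    ep = ep or load_exposure_parameters()
    tox = tox or load_toxicity_parameters()
    qi = {
        m: params.Q0[m] + years * annual_input(alpha[m], params, m) for m in METALS
    }
    doses = dose_profile(qi, ep, mode)
    hq, hi = hazard_quotients(doses, tox)
    cr, tcr = cancer_risks(doses, tox)
    return RiskReport(
        region=params.region_name, mode=mode, years=years,
        doses=doses, hq=hq, hi=hi, cr=cr, tcr=tcr, grade=grade(hi, tcr),
    )


def years_to_hi_threshold(
    params: RegionParameters,
    qp: Mapping[Metal, float],
    ep: ExposureParameters | None = None,
    tox: ToxicityParameters | None = None,
    mode: CoefficientMode = "as_published",
    threshold: float = 1.0,
) -> float:
    """Application years until the hazard index reaches ``threshold``.

    Every dose is linear in the soil concentration Qi = Q0 + n*Qp, so HI
    is affine in the year count n and the crossing is the closed form
    n = (threshold - HI(Q0)) / slope with slope = sum_i u_i * Qp_i, where
    u_i is metal i's hazard quotient per unit Qi.  Returns +inf when the
    slope is zero (no input) and 0 when the background already meets the
    threshold.
    """
    ep = ep or load_exposure_parameters()
    tox = tox or load_toxicity_parameters()
    unit_doses = dose_profile({m: 1.0 for m in METALS}, ep, mode)
    unit_hq, _ = hazard_quotients(unit_doses, tox)
    hi0 = sum(unit_hq.loc[m.value, "total"] * params.Q0[m] for m in METALS)
    slope = sum(unit_hq.loc[m.value, "total"] * qp[m] for m in METALS)
    if hi0 >= threshold:
        return 0.0
    if slope <= 0:
        return math.inf
    return (threshold - hi0) / slope
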