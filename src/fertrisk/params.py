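"""Fixed model parameters, shipped as plain-text CSV inside the package.

The registry holds four families of constants:

* regional soil backgrounds, bulk density and fertilizer application rate
  (:class:`RegionParameters`);
* adult exposure constants and per-metal absorption coefficients for the
  three uptake routes (:class:`ExposureParameters`);
* route-specific reference doses and carcinogenic slope factors
  (:class:`ToxicityParameters`);
* regulatory limits — fertilizer/compost limits by jurisdiction and the
  GB15618-2018 agricultural-soil limits.

All concentrations are mg/kg dry weight.  Files live under
``fertrisk/data`` so every printed constant is diffable and auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Mapping

import pandas as pd

from .metals import CARCINOGENS, METALS, Metal, as_metal

#: Survey regions with their own parameter rows.
REGIONS: tuple[str, ...] = ("north", "northwest", "northeast")

#: Name of the pooled region; its parameters are aggregated on the fly.
POOLED_REGION = "northern"

#: Plow-layer soil volume per hectare (20 cm depth), m3/hm2.
DEFAULT_PLOW_VOLUME = 2000.0


def _read_data(name: str) -> pd.DataFrame:
    with resources.files("fertrisk.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, comment="#")


@dataclass(frozen=True)
class RegionParameters:
    """Soil background and fertilizer-application parameters of one region.

    Attributes
    ----------
    Q0 : mapping metal -> mg/kg
        Pre-application soil concentration (background).
    rho_b : float
        Soil bulk density, g/cm3.
    IR_f : float
        Organic fertilizer application rate, t/hm2/yr.
    V_plow : float
        Plow-layer volume, m3/hm2 (default 2000, i.e. a 20 cm layer).
    n_samples : int
        Survey sample count, used as the aggregation weight.
    """

    region_name: str
    Q0: Mapping[Metal, float]
    rho_b: float
    IR_f: float
    n_samples: int
    V_plow: float = DEFAULT_PLOW_VOLUME

    def __post_init__(self) -> None:
        for m in METALS:
            if m not in self.Q0:
                raise ValueError(f"Q0 missing metal {m}")
            if self.Q0[m] <= 0:
                raise ValueError(f"Q0[{m}] must be > 0")
        for name in ("rho_b", "IR_f", "V_plow"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class ExposureParameters:
    """Adult exposure constants for oral, dermal and respiratory uptake.

    Scalars (units in parentheses): IR_p soil ingestion (mg/day), EF_a
    exposure frequency (day/yr), ED_a exposure duration (yr), BW body
    weight (kg), LT averaging time (days), EV contact events (1/day), SA
    skin surface (m2), mu exposed-skin fraction, eta soil-to-skin
    adherence (mg/cm2), omega suspended particulates (mg/m3), IR_b
    breathing rate (m3/day), f_spod/f_spid soil fractions of outdoor and
    indoor suspended particles, EFOD_a/EFID_a outdoor and indoor exposure
    frequencies (day/yr).

    Per-metal absorption fractions: ``beta`` (gastrointestinal), ``gamma``
    (skin), ``theta`` (lung; taken as 1.00 for Cr and As, for which no
    measured value is available).
    """

    IR_p: float
    EF_a: float
    ED_a: float
    BW: float
    LT: float
    EV: float
    SA: float
    mu: float
    eta: float
    omega: float
    IR_b: float
    f_spod: float
    EFOD_a: float
    f_spid: float
    EFID_a: float
    beta: Mapping[Metal, float]
    gamma: Mapping[Metal, float]
    theta: Mapping[Metal, float]

    def __post_init__(self) -> None:
        for coeff_name in ("beta", "gamma", "theta"):
            coeff = getattr(self, coeff_name)
            for m in METALS:
                v = coeff.get(m)
                if v is None:
                    raise ValueError(f"{coeff_name} missing metal {m}")
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{coeff_name}[{m}]={v} outside [0, 1]")
        for frac in ("mu", "f_spod", "f_spid"):
            if not 0.0 <= getattr(self, frac) <= 1.0:
                raise ValueError(f"{frac} outside [0, 1]")


@dataclass(frozen=True)
class ToxicityParameters:
    """Reference doses per route and carcinogenic slope factors.

    ``RfD_f``/``RfD_s``/``RfD_b`` are the oral, dermal and respiratory
    reference doses (mg/kg/day).  ``SF`` (kg day/mg) is present for the
    four carcinogens Cr, Ni, As, Cd only.
    """

    RfD_f: Mapping[Metal, float]
    RfD_s: Mapping[Metal, float]
    RfD_b: Mapping[Metal, float]
    SF: Mapping[Metal, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("RfD_f", "RfD_s", "RfD_b"):
            rfd = getattr(self, name)
            for m in METALS:
                if rfd.get(m, 0.0) <= 0:
                    raise ValueError(f"{name}[{m}] must be present and > 0")
        if set(self.SF) != set(CARCINOGENS):
            raise ValueError(
                "SF must be present for exactly "
                + ", ".join(str(m) for m in CARCINOGENS)
            )


@lru_cache(maxsize=1)
def _region_table() -> pd.DataFrame:
    return _read_data("region_params.csv").set_index("region")


#: Default pooled-region aggregation weights (survey sample counts).
def aggregation_weights() -> dict[str, int]:
    """Sample counts per region, the weights of the pooled aggregate."""
    return {r: int(_region_table().loc[r, "n_samples"]) for r in REGIONS}


def load_region_parameters(
    region_name: str, weights: Mapping[str, float] | None = None
) -> RegionParameters:
    """Load the packaged parameters of one survey region.

    ``north``, ``northwest`` and ``northeast`` return the table rows as
    printed.  ``northern`` is the pooled aggregate: soil backgrounds and
    bulk density are sample-size-weighted means over the three regions
    (default weights 48/55/14, overridable via ``weights``), while the
    application rate is the unweighted mean of the three regional rates.
    """
    table = _region_table()
    if region_name in REGIONS:
        row = table.loc[region_name]
        return RegionParameters(
            region_name=region_name,
            Q0={m: float(row[m.value]) for m in METALS},
            rho_b=float(row["rho_b"]),
            IR_f=float(row["IR_f"]),
            n_samples=int(row["n_samples"]),
        )
    if region_name == POOLED_REGION:
        w = dict(weights) if weights is not None else aggregation_weights()
        total = float(sum(w[r] for r in REGIONS))
        q0 = {
            m: sum(w[r] * float(table.loc[r, m.value]) for r in REGIONS) / total
            for m in METALS
        }
        rho = sum(w[r] * float(table.loc[r, "rho_b"]) for r in REGIONS) / total
        irf = sum(float(table.loc[r, "IR_f"]) for r in REGIONS) / len(REGIONS)
        return RegionParameters(
            region_name=POOLED_REGION,
            Q0=q0,
            rho_b=rho,
            IR_f=irf,
            n_samples=int(sum(w[r] for r in REGIONS)),
        )
    raise ValueError(
        f"unknown region {region_name!r}; valid regions: "
        + ", ".join((*REGIONS, POOLED_REGION))
    )


@lru_cache(maxsize=1)
def load_exposure_parameters() -> ExposureParameters:
    """Load the packaged adult exposure constants."""
    df = _read_data("exposure_params.csv")
    scalars = df[df["metal"].isna()].set_index("parameter")["value"]
    per_metal = df[df["metal"].notna()]
    coeffs: dict[str, dict[Metal, float]] = {}
    for name in ("beta", "gamma", "theta"):
        block = per_metal[per_metal["parameter"] == name]
        coeffs[name] = {
            as_metal(r["metal"]): float(r["value"]) for _, r in block.iterrows()
        }
    return ExposureParameters(
        **{k: float(scalars[k]) for k in (
            "IR_p", "EF_a", "ED_a", "BW", "LT", "EV", "SA", "mu", "eta",
            "omega", "IR_b", "f_spod", "EFOD_a", "f_spid", "EFID_a",
        )},
        **coeffs,
    )


@lru_cache(maxsize=1)
def load_toxicity_parameters() -> ToxicityParameters:
    """Load the packaged reference doses and slope factors."""
    df = _read_data("toxicity.csv").set_index("metal")
    rfd = {
        name: {m: float(df.loc[m.value, name]) for m in METALS}
        for name in ("RfD_f", "RfD_s", "RfD_b")
    }
    sf = {
        m: float(df.loc[m.value, "SF"])
        for m in METALS
        if pd.notna(df.loc[m.value, "SF"])
    }
    return ToxicityParameters(SF=sf, **rfd)


@lru_cache(maxsize=1)
def _standards_table() -> pd.DataFrame:
    return _read_data("fertilizer_standards.csv").set_index("jurisdiction_id")


def list_jurisdictions() -> list[str]:
    """Identifiers of all packaged fertilizer-limit standards."""
    return list(_standards_table().index)


def load_standards(jurisdiction_id: str) -> dict[Metal, float]:
    """Fertilizer limits (mg/kg DW) of one jurisdiction.

    Metals the jurisdiction does not regulate are omitted from the
    returned mapping (never reported as zero).
    """
    table = _standards_table()
    if jurisdiction_id not in table.index:
        raise ValueError(
            f"unknown jurisdiction {jurisdiction_id!r}; available: "
            + ", ".join(table.index)
        )
    row = table.loc[jurisdiction_id]
    return {m: float(row[m.value]) for m in METALS if pd.notna(row[m.value])}


def merge_limits(*jurisdiction_ids: str) -> dict[Metal, float]:
    """Combine standards, taking each metal's limit from the first
    jurisdiction that regulates it.

    The survey's screening combines the Chinese organic-fertilizer limits
    (Cr, As, Cd, Pb) with the German class-I limits (Ni, Cu, Zn):
    ``merge_limits("china_ny525", "germany_I")``.
    """
    merged: dict[Metal, float] = {}
    for jid in jurisdiction_ids:
        for m, v in load_standards(jid).items():
            merged.setdefault(m, v)
    return merged


@lru_cache(maxsize=1)
def load_soil_limits() -> dict[Metal, float]:
    """GB15618-2018 dry-land (pH > 7.5) soil limits Cs, mg/kg."""
    df = _read_data("soil_limits.csv")
    return {as_metal(r["metal"]): float(r["limit"]) for _, r in df.iterrows()}


@lru_cache(maxsize=4)
def load_survey_summary(region: str) -> pd.DataFrame:
    """Published per-metal summary statistics of the fertilizer survey.

    Returns a frame indexed by metal symbol with columns ``range_low``,
    ``range_high``, ``mean``, ``median``, ``sd``, ``cv_percent``.
    """
    df = _read_data("survey_summary.csv")
    valid = sorted(df["region"].unique())
    if region not in valid:
        raise ValueError(f"unknown region {region!r}; valid regions: {', '.join(valid)}")
    out = df[df["region"] == region].set_index("metal").drop(columns="region")
    return out.reindex([m.value for m in METALS])
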