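"""End-to-end pipeline: survey (synthetic or from file) -> summary ->
standards screening -> correlation -> accumulation (deterministic + Monte
Carlo) -> human health risk -> grade.

A run is fully determined by its :class:`PipelineConfig` and seed; every
stage CSV carries the package version, seed and config hash in a comment
header, and a machine-readable ``summary.json`` collects the headline
quantities.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import yaml

from . import accumulation, risk, survey, synthetic
from .io import config_hash, read_concentration_csv, write_concentration_csv, write_csv
from .metals import METALS
from .params import (
    POOLED_REGION,
    REGIONS,
    load_region_parameters,
    load_soil_limits,
    merge_limits,
)

log = logging.getLogger("fertrisk")


@dataclass
class PipelineConfig:
    """Flat configuration of a full run.

    ``input_table``: optional CSV path; when absent, a synthetic survey
    of ``n_synthetic`` samples is generated from the region's published
    summary statistics.  ``jurisdictions``: fertilizer standards used for
    screening, first-match-wins per metal.  ``mode``/``years`` control
    the exposure model; ``mc_iterations`` the time-to-limit simulation.
    """

    region: str = "north"
    seed: int = 1
    input_table: str | None = None
    n_synthetic: int = 48
    jurisdictions: Sequence[str] = ("china_ny525", "germany_I")
    mode: str = "as_published"
    years: float = 1.0
    mc_iterations: int = 100_000
    outdir: str = "fertrisk_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
        return cls(**raw)

    def validate(self) -> None:
        valid = (*REGIONS, POOLED_REGION)
        if self.region not in valid:
            raise ValueError(
                f"unknown region {self.region!r}; valid regions: {', '.join(valid)}"
            )
        if self.input_table is not None and not Path(self.input_table).exists():
            raise FileNotFoundError(self.input_table)
        if self.mode not in ("as_published", "as_written"):
            raise ValueError(f"unknown coefficient mode {self.mode!r}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write all outputs under ``config.outdir``.

    Returns the summary dictionary (also written as ``summary.json``).
    Identical config + seed produces byte-identical outputs.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # hash the scientific configuration only, not the output location
    cfg_dict = {k: v for k, v in asdict(config).items() if k != "outdir"}
    meta = {"seed": config.seed, "config": config_hash(cfg_dict)}
    params = load_region_parameters(config.region)

    def stage(name):
        log.info("stage %s (region=%s seed=%d)", name, config.region, config.seed)

    try:
        stage("survey")
        if config.input_table:
            table = read_concentration_csv(config.input_table)
        else:
            table = synthetic.generate_region(
                n=config.n_synthetic, seed=config.seed, region=config.region
            )
        write_concentration_csv(table, outdir / "samples.csv", metadata=meta)

        stage("summarize")
        summary = survey.summarize(table)
        write_csv(summary, outdir / "summary.csv", metadata=meta)

        stage("screen")
        limits = merge_limits(*config.jurisdictions)
        screening = survey.exceedance_rates(
            table, limits, jurisdiction_id="+".join(config.jurisdictions)
        )
        write_csv(screening, outdir / "exceedance.csv", metadata=meta)

        stage("correlate")
        corr = survey.spearman_matrix(table)
        write_csv(corr.rho, outdir / "spearman_rho.csv", metadata=meta)
        write_csv(corr.pvalues, outdir / "spearman_p.csv", metadata=meta)

        stage("accumulate")
        medians = {m: float(summary.loc[m.value, "median"]) for m in METALS}
        soil_limits = load_soil_limits()
        acc = accumulation.accumulation_table(params, medians, soil_limits)
        write_csv(acc, outdir / "accumulation.csv", metadata=meta)

        stage("mc-time")
        specs = {
            m: synthetic.spec_from_summary(
                medians[m],
                float(summary.loc[m.value, "cv_percent"]),
                (float(summary.loc[m.value, "min"]), float(summary.loc[m.value, "max"])),
            )
            for m in METALS
        }
        mc = accumulation.mc_time_to_limit(
            specs,
            params,
            soil_limits,
            accumulation.SimulationConfig(
                n_iterations=config.mc_iterations, seed=config.seed
            ),
        )
        write_csv(mc, outdir / "mc_time.csv", metadata=meta)

        stage("risk")
        report = risk.assess(params, medians, mode=config.mode, years=config.years)
        long = report.doses.join(report.hq, rsuffix="_HQ")
        write_csv(long, outdir / "risk.csv", metadata=meta)
        write_csv(report.cr, outdir / "cancer_risk.csv", metadata=meta)
    except Exception as err:
        raise RuntimeError(f"pipeline stage failed: {err}") from err

    result = {
        "seed": config.seed,
        "config_hash": meta["config"],
        "region": config.region,
        "n_samples": int(len(table)),
        "min_time_to_limit_years": float(acc["T_rounded"].min()),
        "min_time_metal": str(acc["T_rounded"].idxmin()),
        "mc_median_min_years": float(mc["T_q50"].min()),
        "HI": report.hi,
        "TCR": report.tcr,
        "grade": report.grade.label,
        "exceedance_percent": {
            m: (None if not screening.loc[m, "regulated"]
                else float(screening.loc[m, "rate_percent"]))
            for m in screening.index
        },
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return result
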