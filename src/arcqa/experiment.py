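"""End-to-end experiment: seeded plan cohort, error injection, delivery
onto both detector frames, and a per-plan/summary report.

For each seed the pipeline builds the four plan variants (error-free and
1 mm bank-A error, each rotational and gantry-collapsed), accumulates the
gantry-stationary rotational, couch-stationary rotational and
couch-stationary collapsed dose maps on a fine simulation lattice,
area-averages them to the analysis lattice, and scores

* the percent-difference threshold achieving a 95% point match per
  delivery arm (the headline per-plan statistic),
* gamma pass rates at 2%/2 mm and 3%/3 mm on the couch-stationary
  rotational pair, and
* DVH metric differences over seeded planar ROIs.

Rows that fail at any stage are recorded as failed and do not abort the
cohort.  The report carries full provenance (seeds, config hash, version)
and is deterministic for a given configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import ComparisonConfig, threshold_to_target
from .delivery import (DEFAULT_ANALYSIS_SPACING_CM, DEFAULT_HALF_EXTENT_CM,
                       DEFAULT_SIM_SPACING_CM, DeliveryConfig,
                       accumulate_dose, resample_to_detector,
                       resample_to_grid)
from .dvh import dvh_metrics, metric_relative_difference
from .gamma import GammaCriteria, gamma_map
from .grid import CS, GS, DETECTOR_PRESETS, GridSpec
from .plan import PerturbationSpec, collapse_gantry, inject_bank_error
from .synthetic import GeneratorConfig, generate_arc_plan, generate_roi_masks

log = logging.getLogger("arcqa.experiment")

#: Per-plan threshold columns, one per delivery arm.
THRESHOLD_COLUMNS = ("threshold_cs_collapsed_pct",
                     "threshold_cs_rotational_pct",
                     "threshold_gs_rotational_pct")


@dataclass(frozen=True)
class ExperimentConfig:
    base_seed: int = 20140508
    n_plans: int = 8
    #: Systematic bank error injected into the MLC1PE variant (cm).
    offset_cm: float = 0.1
    bank: str = "A"
    sim_spacing_cm: float = DEFAULT_SIM_SPACING_CM
    analysis_spacing_cm: float = DEFAULT_ANALYSIS_SPACING_CM
    half_extent_cm: float = DEFAULT_HALF_EXTENT_CM
    penumbra_sigma_cm: float = 0.3
    weighting: str = "uniform"
    cos_power: float = 1.0
    low_dose_cutoff_fraction: float = 0.1
    target_match_fraction: float = 0.95
    scan_step_percent: float = 0.1
    scan_max_percent: float = 50.0
    gamma_criteria: tuple[tuple[float, float], ...] = ((2.0, 2.0),
                                                       (3.0, 3.0))
    #: Optional detector preset name (array729 / epid); None analyzes on
    #: the plain analysis lattice.
    detector: str | None = None

    @property
    def seeds(self) -> list[int]:
        return [self.base_seed + i for i in range(self.n_plans)]

    def comparison_config(self) -> ComparisonConfig:
        return ComparisonConfig(
            low_dose_cutoff_fraction=self.low_dose_cutoff_fraction,
            target_match_fraction=self.target_match_fraction,
            scan_step_percent=self.scan_step_percent,
            scan_max_percent=self.scan_max_percent)

    def delivery_config(self) -> DeliveryConfig:
        return DeliveryConfig(penumbra_sigma_cm=self.penumbra_sigma_cm,
                              weighting=self.weighting,
                              cos_power=self.cos_power)

    def sim_grid(self) -> GridSpec:
        return GridSpec(self.sim_spacing_cm, self.half_extent_cm)

    def config_hash(self) -> str:
        doc = json.dumps(dataclasses.asdict(self), sort_keys=True,
                         default=str)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "gamma_criteria" in doc:
            doc["gamma_criteria"] = tuple(
                tuple(float(v) for v in pair)
                for pair in doc["gamma_criteria"])
        return cls(**doc)

    def to_yaml(self, path) -> None:
        doc = dataclasses.asdict(self)
        doc["gamma_criteria"] = [list(p) for p in doc["gamma_criteria"]]
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class ExperimentReport:
    rows: list[dict]
    summary: dict[str, dict[str, float]]
    provenance: dict

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def _gamma_col(dose_pct: float, dist_mm: float) -> str:
    return f"gamma_pass_{dose_pct:g}pct_{dist_mm:g}mm_pct"


def run_plan(seed: int, cfg: ExperimentConfig) -> dict:
    """One cohort row: build, deliver, and score a single seeded plan."""
    gen_cfg = GeneratorConfig(seed=seed)
    plan0 = generate_arc_plan(gen_cfg)
    plan1 = inject_bank_error(
        plan0, PerturbationSpec(bank=cfg.bank, offset_cm=cfg.offset_cm))
    plan0_col = collapse_gantry(plan0)
    plan1_col = collapse_gantry(plan1)

    sim_grid = cfg.sim_grid()
    dcfg = cfg.delivery_config()

    def deliver(plan, frame):
        dose = accumulate_dose(plan, frame, sim_grid, dcfg)
        if cfg.detector:
            return resample_to_detector(dose, DETECTOR_PRESETS[cfg.detector])
        return resample_to_grid(dose, cfg.analysis_spacing_cm)

    d0_gs = deliver(plan0, GS)
    d1_gs = deliver(plan1, GS)
    d0_cs = deliver(plan0, CS)
    d1_cs = deliver(plan1, CS)
    d0_cc = deliver(plan0_col, CS)
    d1_cc = deliver(plan1_col, CS)

    ccfg = cfg.comparison_config()
    row = {
        "plan_id": plan0.plan_id,
        "seed": seed,
        "status": "ok",
        "threshold_cs_collapsed_pct": threshold_to_target(d0_cc, d1_cc, ccfg),
        "threshold_cs_rotational_pct": threshold_to_target(d0_cs, d1_cs,
                                                           ccfg),
        "threshold_gs_rotational_pct": threshold_to_target(d0_gs, d1_gs,
                                                           ccfg),
    }
    for dose_pct, dist_mm in cfg.gamma_criteria:
        crit = GammaCriteria(
            dose_diff_percent=dose_pct, distance_mm=dist_mm,
            low_dose_cutoff_fraction=cfg.low_dose_cutoff_fraction)
        row[_gamma_col(dose_pct, dist_mm)] = gamma_map(
            d0_cs, d1_cs, crit).pass_percent

    # DVH scoring happens in the couch (patient-like) frame; the
    # prescription is the median target dose of the error-free map.
    rois = generate_roi_masks(seed, d0_cs.grid)
    target_vals = d0_cs.values[rois[0].mask]
    prescription = float(np.median(target_vals))
    for roi in rois:
        m0 = dvh_metrics(d0_cs, roi, prescription,
                         v_doses=(0.5 * prescription, 0.9 * prescription))
        m1 = dvh_metrics(d1_cs, roi, prescription,
                         v_doses=(0.5 * prescription, 0.9 * prescription))
        deltas = metric_relative_difference(m0, m1)
        row[f"{roi.name}_mean_dose_0"] = m0.mean_dose
        row[f"{roi.name}_mean_dose_1"] = m1.mean_dose
        md = deltas["mean_dose"]
        row[f"{roi.name}_mean_reldiff_pct"] = md.percent
        row[f"{roi.name}_mean_sign"] = md.sign
        if roi.role == "target":
            row[f"{roi.name}_d95_0"] = m0.d95
            row[f"{roi.name}_d95_1"] = m1.d95
            row[f"{roi.name}_v107_0"] = m0.v107_fraction
            row[f"{roi.name}_v107_1"] = m1.v107_fraction
            dd = deltas["d95"]
            row[f"{roi.name}_d95_reldiff_pct"] = dd.percent
    return row


def _summarize(rows: list[dict]) -> dict[str, dict[str, float]]:
    ok = [r for r in rows if r.get("status") == "ok"]
    summary: dict[str, dict[str, float]] = {}
    if not ok:
        return summary
    df = pd.DataFrame(ok)
    for col in df.columns:
        if col in ("plan_id", "seed", "status", "error"):
            continue
        series = pd.to_numeric(df[col], errors="coerce").dropna()
        if series.empty:
            continue
        summary[col] = {"mean": float(series.mean()),
                        "sd": float(series.std(ddof=1))
                        if len(series) > 1 else 0.0,
                        "n": int(len(series))}
    return summary


def run_experiment(cfg: ExperimentConfig | None = None) -> ExperimentReport:
    cfg = cfg or ExperimentConfig()
    rows = []
    for seed in cfg.seeds:
        try:
            rows.append(run_plan(seed, cfg))
            log.info("plan seed=%d done", seed)
        except Exception as exc:  # one bad plan must not sink the cohort
            log.exception("plan seed=%d failed", seed)
            rows.append({"plan_id": f"synthetic-{seed:06d}", "seed": seed,
                         "status": "failed", "error": str(exc)})
    provenance = {
        "seeds": cfg.seeds,
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.config_hash(),
        "version": __version__,
    }
    return ExperimentReport(rows=rows, summary=_summarize(rows),
                            provenance=provenance)


# -- report I/O ------------------------------------------------------------


def write_report(report: ExperimentReport, out_dir) -> dict[str, Path]:
    """Emit report.json (rows, summary, provenance) and report.csv
    (per-plan rows plus Mean/SD footer rows)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    json_path = out / "report.json"
    with open(json_path, "w") as fh:
        json.dump({"rows": report.rows, "summary": report.summary,
                   "provenance": report.provenance}, fh, indent=1,
                  default=float)
        fh.write("\n")
    df = report.frame()
    footer_rows = []
    for stat in ("mean", "sd"):
        footer = {"plan_id": stat.upper()}
        for col, stats in report.summary.items():
            footer[col] = stats[stat]
        footer_rows.append(footer)
    csv_path = out / "report.csv"
    pd.concat([df, pd.DataFrame(footer_rows)], ignore_index=True).to_csv(
        csv_path, index=False)
    return {"json": json_path, "csv": csv_path}


def read_report(path) -> ExperimentReport:
    with open(path) as fh:
        doc = json.load(fh)
    return ExperimentReport(rows=doc["rows"], summary=doc["summary"],
                            provenance=doc["provenance"])
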