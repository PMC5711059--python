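"""Deliver every plan variant onto its detector frames.

Reads results/plans/, accumulates planar dose on the 0.05 cm simulation
lattice (0.3 cm Gaussian penumbra), area-averages to the 0.3 cm analysis
lattice, and writes results/doses/<plan>_<variant>_<arm>.csv for the
three delivery arms: gs_rotational, cs_rotational, cs_collapsed.

The couch-stationary rotational arm is the one that mirrors fluence for
control points beyond +/-90 degrees; the other two never mirror, which
is why they end up identical (checked in 03).
"""

from pathlib import Path

import arcqa

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
CFG = arcqa.ExperimentConfig()

ARMS = {  # (frame, delivery_mode of the source plan)
    "gs_rotational": ("GS", "rotational"),
    "cs_rotational": ("CS", "rotational"),
    "cs_collapsed": ("CS", "collapsed"),
}


def main() -> None:
    (SCRATCH / "doses").mkdir(parents=True, exist_ok=True)
    grid = CFG.sim_grid()
    dcfg = CFG.delivery_config()
    for seed in CFG.seeds:
        for variant in ("MLC0PE", "MLC1PE"):
            for arm, (frame, mode) in ARMS.items():
                plan = arcqa.read_plan(
                    SCRATCH / "plans"
                    / f"synthetic-{seed:06d}_{variant}_{mode}.json")
                dose = arcqa.resample_to_grid(
                    arcqa.accumulate_dose(plan, frame, grid, dcfg),
                    CFG.analysis_spacing_cm)
                out = SCRATCH / "doses" / f"{plan.plan_id}_{variant}_{arm}.csv"
                arcqa.write_dose_csv(dose, out)
        print(f"synthetic-{seed:06d}: 6 dose maps written")
    print(f"\ndose maps under {SCRATCH / 'doses'}")


if __name__ == "__main__":
    main()
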