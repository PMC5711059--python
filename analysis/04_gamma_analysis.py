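"""Gamma analysis of the couch-stationary rotational pairs.

Scores 2%/2 mm and 3%/3 mm gamma pass rates between the error-free and
1 mm bank-A error maps (global normalization, 10% cutoff) and writes
results/gamma.csv.  Unlike the DTA=0 threshold statistic, gamma tolerates
spatial shifts, so the 1 mm leaf error produces mixed pass rates with no
one-sided spatial signature — the reason the threshold statistic, not
gamma, carries the frame-geometry finding.
"""

import warnings
from pathlib import Path

import pandas as pd

import arcqa

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
CFG = arcqa.ExperimentConfig()


def main() -> None:
    rows = []
    for seed in CFG.seeds:
        pid = f"synthetic-{seed:06d}"
        d0 = arcqa.read_dose_csv(SCRATCH / "doses"
                                 / f"{pid}_MLC0PE_cs_rotational.csv")
        d1 = arcqa.read_dose_csv(SCRATCH / "doses"
                                 / f"{pid}_MLC1PE_cs_rotational.csv")
        row = {"plan_id": pid}
        for dose_pct, dist_mm in CFG.gamma_criteria:
            crit = arcqa.GammaCriteria(
                dose_diff_percent=dose_pct, distance_mm=dist_mm,
                low_dose_cutoff_fraction=CFG.low_dose_cutoff_fraction)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # 3 mm grid vs 2 mm DTA
                res = arcqa.gamma_map(d0, d1, crit)
            row[f"pass_{dose_pct:g}pct_{dist_mm:g}mm"] = res.pass_percent
        rows.append(row)
    df = pd.DataFrame(rows).set_index("plan_id")
    summary = pd.DataFrame({"MEAN": df.mean(), "SD": df.std(ddof=1)}).T
    table = pd.concat([df, summary])
    table.to_csv(RESULTS / "gamma.csv")
    print(table.round(1).to_string())
    print("\nLooser criteria always pass at least as many points; the "
          "spread across plans shows gamma's insensitivity to the error's "
          "laterality.")


if __name__ == "__main__":
    main()
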