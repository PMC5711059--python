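"""Generate the plan cohort: 8 seeded modulated single-arc plans, each in
four variants (error-free / 1 mm bank-A error, rotational / collapsed).

Writes results/plans/<plan>_<variant>_<mode>.json.  The cohort stands in
for clinical head-and-neck and esophagus arc plans: high-dose-gradient
apertures, one full arc from -170 to +170 degrees.
"""

from pathlib import Path

import arcqa

OUT = Path(__file__).resolve().parent.parent / "scratch" / "plans"
CFG = arcqa.ExperimentConfig()


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for seed in CFG.seeds:
        plan0 = arcqa.generate_arc_plan(arcqa.GeneratorConfig(seed=seed))
        plan1 = arcqa.inject_bank_error(
            plan0, arcqa.PerturbationSpec(bank=CFG.bank,
                                          offset_cm=CFG.offset_cm))
        for plan in (plan0, plan1, arcqa.collapse_gantry(plan0),
                     arcqa.collapse_gantry(plan1)):
            name = (f"{plan.plan_id}_{plan.variant_label}"
                    f"_{plan.delivery_mode}.json")
            arcqa.write_plan(plan, OUT / name)
        print(f"{plan0.plan_id}: 4 variants written")
    print(f"\n{4 * len(CFG.seeds)} plan files under {OUT}")


if __name__ == "__main__":
    main()
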