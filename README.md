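# arcqa — detector reference frames in VMAT patient-specific QA, simulated

`arcqa` is a desk-scale simulation of a classic question in radiotherapy
quality assurance: **if every leaf of one MLC bank is systematically off by
1 mm, how strongly does a planar QA measurement flag it — and does the answer
depend on whether the detector rides on the gantry or sits on the couch?**

It is written for medical physicists and QA-methods researchers who want the
*geometry* of that question isolated from machine, scatter and detector
response effects, and for anyone building or testing planar dose comparison
statistics (percent-difference pass rates, gamma index, DVH metrics) against
controlled, perfectly known perturbations.

## The mechanism and the statistics

A single-arc VMAT plan is a sequence of control points
(θ_k, w_k, A_k, B_k): gantry angle, MU weight, and the two leaf-bank edge
vectors. The idealized delivered planar fluence in a detector frame is

    D(x, y) = Σ_k  w_k · T_k [ Φ(x, y; A_k, B_k) ]

where Φ is the unit-intensity aperture indicator (exact partial-area
rasterization, optional Gaussian penumbra σ) and T_k is the frame transform:

* **gantry-stationary (GS)** detector (e.g. a portal imager): T_k = identity
  at every angle — the detector keeps a fixed orientation to the collimator;
* **couch-stationary (CS)** detector (e.g. an ion-chamber array, or the
  patient): T_k mirrors x → −x whenever |θ_k| ≥ 90°, because the collimator
  then projects onto the detector from "below".

Opening bank A by δ = 1 mm adds a thin fluence strip at each row's A edge.
In the GS frame every strip lands on the same (bank-A) side and stacks up; in
the CS frame the strips split between both sides of the field, roughly
halving the worst accumulated difference. The headline statistic is the
smallest percent-difference criterion Δ at which 95 % of points agree
(DTA = 0, global normalization to the reference maximum, 10 % low-dose
cutoff — the Van Dyk convention):

    Δ95 = min { δ : #(|D0 − D1| / max D0 ≤ δ/100) / N ≥ 0.95 }

computed exactly as the ceiling-rule 95 % order statistic of the |difference|
map. Gamma analysis (2 %/2 mm, 3 %/3 mm) and planar DVH metrics (D95, V107 %,
mean dose, D1 %) complete the picture.

## Worked example

```python
import arcqa

plan0 = arcqa.generate_arc_plan(arcqa.GeneratorConfig(seed=1))      # MLC0PE
plan1 = arcqa.inject_bank_error(plan0,
                                arcqa.PerturbationSpec(bank="A",
                                                       offset_cm=0.1))
grid = arcqa.GridSpec(0.1, 13.5)
for frame in ("GS", "CS"):
    d0 = arcqa.resample_to_grid(arcqa.accumulate_dose(plan0, frame, grid), 0.3)
    d1 = arcqa.resample_to_grid(arcqa.accumulate_dose(plan1, frame, grid), 0.3)
    print(frame, arcqa.threshold_to_target(d0, d1))
```

prints

```
GS 6.800000000000001
CS 4.1000000000000005
```

the same 1 mm error needs a 6.8 % criterion to pass a 95 % match when "seen"
by a gantry-mounted detector, but only 4.1 % from the couch — the
frame flip dilutes the one-sided accumulation. The full cohort pipeline is

```
arcqa run --out results/          # or: python analysis/01...05 in order
```

which reports, over eight seeded plans (means ± SD, default config in
`config/default.yaml`): CS-rotational 3.98 ± 0.24 %, CS-collapsed and
GS-rotational both 6.39 ± 0.38 % — collapsing the gantry to 0° makes the
couch detector reproduce the gantry-mounted result *exactly*, and the
GS/CS threshold ratio is 1.61, i.e. the gantry-mounted geometry roughly
doubles the apparent error.

The numbered scripts in `analysis/` run the same experiment as a narrative:
plan generation → dual-frame delivery → threshold, gamma and DVH tables
(written under `results/`, heavy intermediates under `scratch/`).

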