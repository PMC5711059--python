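# Methods

## Model

The package simulates planar QA of single-arc VMAT deliveries as pure
fluence geometry at the isocenter plane. A plan is an ordered set of
control points, each with an IEC 61217 gantry angle θ ∈ [−180°, 180°], a
normalized MU weight, and 40 leaf pairs of 1.0 cm projected width whose
aperture on row *i* is the crossplane interval [A_i, B_i] (closed pairs:
A_i = B_i). Bank A occupies the −x half of the crossplane axis, so
"opening bank A by δ" maps A_i → A_i − δ. Coordinates are bounded by the
±13.5 cm maximum measurable field.

Delivered dose in a detector frame is the MU-weighted sum of
frame-transformed, rasterized apertures:

* rasterization is exact partial-area weighting of each leaf-row band
  against the node-centered grid, giving unit fluence inside the aperture;
* the gantry-stationary (GS) frame transform is the identity at every
  angle; the couch-stationary (CS) transform mirrors x → −x for
  |θ| ≥ 90° (the boundary angle belongs to the flipped branch — a
  measurable convention has to be fixed; nothing else in the pipeline
  depends on which side ±90° exactly falls);
* an optional isotropic Gaussian penumbra (σ = 0.3 cm by default) blurs
  the accumulated map; it is linear and mirror-symmetric, so it commutes
  with the frame transform and conserves the fluence integral up to
  boundary truncation;
* the per-angle deposition weight w(θ) is 1 by default, so both frames
  conserve total fluence exactly; |cos θ|^p is available for users who
  want a crude lateral-beam attenuation, at the cost of that exact
  conservation. No physical deposition model is claimed either way.

Magnification, divergence, scatter, phantom attenuation and detector
energy response are deliberately absent: the object of study is the
reference-frame geometry, and every one of those effects would only blur
it.

Two consequences are exact by construction and are asserted as such:
a gantry-collapsed plan produces element-wise identical GS and CS maps,
and (with w ≡ 1) the GS-rotational map of a plan equals the CS map of its
collapsed copy, because neither path ever mirrors. The experimental
contrast therefore reduces to CS-rotational versus everything else.

## Grids and detectors

Simulation runs on a 0.05 cm node-centered lattice (odd node count, one
node on the beam axis so the mirror maps nodes to nodes); comparisons run
on a 0.3 cm analysis lattice, the resolution planar QA software commonly
analyzes at, obtained by exact block averaging (fractional edge weights).
These sizes keep the full eight-plan cohort under a minute on one CPU
while resolving the 1 mm error strips; halving the simulation pitch
changes cohort thresholds by less than one scan step. Detector presets
model a 27 × 27 ion-chamber array (1 cm pitch, 0.5 cm square area
averaging) and a portal imager (0.025 cm pitch at isocenter, point
sampling); the default experiment analyzes on the plain lattice so that
frame geometry, not sampling density, drives the contrast.

## Comparison statistics

Percent differences are DTA = 0 (identical lattices enforced, never
resampled silently), signed, and normalized globally to the reference
maximum (Van Dyk convention) with a 10 % low-dose cutoff; local
normalization is available. The threshold-to-95 %-match is the
ceiling-rule order statistic of |diff| at the 95th percentile, snapped up
to a 0.1 % scan grid (ties resolve to the smallest criterion); a literal
scan of the pass-fraction curve is kept in the test suite as an oracle.
The choice of global normalization and 10 % cutoff follows common planar
QA practice; unit tests use cutoff 0 where hand arithmetic is asserted.

The gamma index is discrete: candidates are grid nodes within a search
radius of 3 × the distance criterion, with no sub-grid interpolation —
determinism and oracle-checkability are worth more here than the small
pass-rate refinement interpolation buys. Whenever a point's true gamma is
below the radius factor the restricted search is provably exact (any
farther candidate already exceeds that gamma through its distance term
alone); larger values are lower bounds, which cannot change a pass/fail
verdict at γ = 1. Pass comparisons use a 1e−9 slack so criteria-boundary
candidates (γ exactly 1) pass.

DVH metrics use the discrete convention D_p = the ⌈p·n⌉-th largest masked
dose value (no interpolation), V_x = fraction ≥ x. Relative differences
are reported unsigned with the direction as a separate sign, the
error-free value as denominator, and a zero denominator flagged as
undefined rather than propagated. Planar ROIs stand in for volumetric
structures; the metric formulas are dimension-agnostic.

## Perturbation conventions

The systematic bank error applies to every *open* pair; parked closed
pairs (A = B) travel as a unit and stay closed. This keeps the injected
aperture-area change exactly δ × leaf width × (number of open pairs) and
avoids manufacturing sliver fields from parked leaves. The edit is linear
(offsets compose additively) and commutes with gantry collapse. A note on
laterality: only the self-consistency of the bank-A = −x convention
matters; every mechanism statement is invariant under relabeling the
banks.

## Synthetic cohort

The generator emulates what the analysis needs from clinical
high-gradient arc plans, nothing more: 72 control points equally spaced
over −170° → +170° (so ~47 % of MU is delivered with |θ| ≥ 90°), a
contiguous central block of 9–13 open leaf pairs, aperture centers and
widths performing bounded random walks (centers within ±1.2 cm of the
axis, widths 4.6–7.4 cm around a 6 cm mean, edge speed ≤ 0.3 cm per
control point), and MU weights uniform ±30 % then normalized. All
randomness flows through one `numpy.random.default_rng(seed)`.

The bounds are load-bearing in two ways: they guarantee every bank-A edge
stays in x < −1.1 (so its CS mirror image lands in x > +1.1 and the
one-sided/two-sided distinction is cleanly measurable), and they
guarantee the central target ROI (ellipse, semi-axes ≤ 1.0 × 3.0 cm) lies
inside every control point's aperture. ROI generation is seeded
independently of the plan: one central target plus two lateral organ
surrogates near ±4.5 cm, which straddle the leaf-edge bands where an
opened bank actually deposits its extra fluence.

What the generator does *not* emulate — optimizer-driven modulation,
closed-pair sweeps across the target, dose-rate/gantry-speed constraints,
anatomy — bounds what passing tests show: they validate the frame
mechanism and the statistics on plans with realistic modulation scale,
not agreement with any clinical cohort's absolute numbers.

## Experiment and findings

The default experiment (config/default.yaml): 8 seeds, 1 mm bank-A error,
three delivery arms per plan. Observed with the shipped defaults:
CS-rotational threshold 3.98 ± 0.24 %, CS-collapsed = GS-rotational
6.39 ± 0.38 %, GS/CS ratio 1.61; gamma pass rates 77 ± 2 % (2 %/2 mm) and
88 ± 1 % (3 %/3 mm) on the CS-rotational pairs; organ-surrogate mean dose
rises 3–25 % while the flat target interior is nearly unchanged — in a
uniform-intensity aperture model the error manifests only in edge bands,
so target hot-spot metrics are insensitive by construction. The ratio
sits below the ideal factor 2 because the mirrored strip population
retains ~47 % of the MU rather than half, and because the 95th-percentile
statistic samples the band fringes, not its peak.

## Numerical choices and degenerate inputs

MU weights are normalized on read (only relative weights matter) and
validated to sum to 1 within 1e−9. Plan JSON writes coordinates at 6
decimals; round-trips are exact at that precision. Comparisons on empty
inclusion masks, ROIs with no voxels, targets unreachable within the 50 %
scan range, apertures entirely off-grid, and detector lattices exceeding
the dose grid all raise typed errors rather than returning numbers.
All-closed apertures rasterize to a valid zero map. The experiment
records a failed row and continues when any stage of one plan raises.

## Known limitations

* 2D fluence only — no depth dose, no 3D gamma, no absolute calibration.
* The CS mirror is a step function of angle; a physical coronal-plane
  measurement transitions smoothly near ±90° in a device-dependent way
  the package does not attempt to reconstruct.
* Gamma values above the search-radius factor are lower bounds.
* Collimator and couch angles are fixed at 0; backup jaws are not
  modelled.
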