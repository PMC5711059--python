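"""Seeded generators for modulated single-arc plans and planar ROIs.

The generator emulates the structure the analysis needs from a clinical
single-arc plan — equally spaced gantry angles over a full arc, a
contiguous block of open leaf pairs whose aperture centers and widths
wander smoothly from control point to control point (high-dose gradients
without optimizer machinery), and uneven MU weights — not clinical
deliverability or anatomy.  Aperture centers are kept within a small
excursion of the axis and widths above a floor, which guarantees the
central target ROI produced by :func:`generate_roi_masks` always lies
inside every control point's aperture footprint.

All randomness flows through one ``numpy.random.default_rng(seed)``;
identical seeds give byte-identical plans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dvh import ROIMask
from .grid import GridSpec
from .plan import ArcPlan, ControlPoint, normalize_mu


class GeneratorConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_control_points: int = 72
    arc_start_deg: float = -170.0
    arc_end_deg: float = 170.0
    n_leaf_pairs: int = 40
    leaf_width_cm: float = 1.0
    #: Mean and initial jitter of the aperture width (cm).
    mean_aperture_width_cm: float = 6.0
    aperture_jitter_cm: float = 1.2
    #: Hard bounds the width random walk is clipped to (cm).
    min_aperture_width_cm: float = 4.6
    max_aperture_width_cm: float = 7.4
    #: Max per-control-point travel of any single leaf edge (cm).
    max_leaf_speed_cm_per_cp: float = 0.3
    #: Smallest allowed open-pair aperture width (cm).
    min_gap_cm: float = 0.5
    #: Inclusive range for the number of contiguous open leaf pairs.
    n_open_pairs: tuple[int, int] = (9, 13)
    #: Max |aperture center| excursion from the axis (cm).
    max_center_excursion_cm: float = 1.2
    #: Relative spread of the raw MU weights around uniform.
    mu_weight_dispersion: float = 0.3

    def validate(self) -> None:
        if not (-180.0 <= self.arc_start_deg < self.arc_end_deg <= 180.0):
            raise GeneratorConfigError(
                "need arc_start < arc_end within [-180, 180]")
        if self.n_control_points < 2:
            raise GeneratorConfigError("need at least 2 control points")
        if self.min_gap_cm < 0:
            raise GeneratorConfigError("min_gap_cm must be >= 0")
        if self.min_gap_cm > self.mean_aperture_width_cm:
            raise GeneratorConfigError(
                "min_gap_cm exceeds the mean aperture width; no feasible "
                "aperture exists")
        if not (0 < self.min_aperture_width_cm
                <= self.max_aperture_width_cm):
            raise GeneratorConfigError("invalid aperture width bounds")
        if self.min_aperture_width_cm < self.min_gap_cm:
            raise GeneratorConfigError(
                "width floor must be at least min_gap_cm")
        lo, hi = self.n_open_pairs
        if not (1 <= lo <= hi <= self.n_leaf_pairs):
            raise GeneratorConfigError("invalid n_open_pairs range")
        if self.max_leaf_speed_cm_per_cp <= 0:
            raise GeneratorConfigError("leaf speed bound must be positive")
        if not 0 <= self.mu_weight_dispersion < 1:
            raise GeneratorConfigError(
                "mu_weight_dispersion must be in [0, 1)")


def generate_arc_plan(cfg: GeneratorConfig | None = None,
                      variant_label: str = "MLC0PE") -> ArcPlan:
    """Seeded modulated single-arc plan obeying all plan invariants."""
    cfg = cfg or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    angles = np.linspace(cfg.arc_start_deg, cfg.arc_end_deg,
                         cfg.n_control_points)
    n_open = int(rng.integers(cfg.n_open_pairs[0], cfg.n_open_pairs[1] + 1))
    first_open = (cfg.n_leaf_pairs - n_open) // 2
    open_rows = np.arange(first_open, first_open + n_open)

    # Per-edge step budget: center and half-width steps together never
    # exceed the leaf speed bound.
    step_c = cfg.max_leaf_speed_cm_per_cp * 2.0 / 3.0
    step_w = cfg.max_leaf_speed_cm_per_cp * 2.0 / 3.0

    centers = rng.uniform(-cfg.max_center_excursion_cm * 0.8,
                          cfg.max_center_excursion_cm * 0.8, n_open)
    widths = np.clip(
        cfg.mean_aperture_width_cm
        + rng.uniform(-cfg.aperture_jitter_cm, cfg.aperture_jitter_cm,
                      n_open),
        cfg.min_aperture_width_cm, cfg.max_aperture_width_cm)

    raw_mu = 1.0 + cfg.mu_weight_dispersion * rng.uniform(
        -1.0, 1.0, cfg.n_control_points)
    cps = []
    for t in range(cfg.n_control_points):
        if t > 0:
            centers = np.clip(
                centers + rng.uniform(-step_c, step_c, n_open),
                -cfg.max_center_excursion_cm, cfg.max_center_excursion_cm)
            widths = np.clip(
                widths + rng.uniform(-step_w, step_w, n_open),
                cfg.min_aperture_width_cm, cfg.max_aperture_width_cm)
        bank_a = np.zeros(cfg.n_leaf_pairs)
        bank_b = np.zeros(cfg.n_leaf_pairs)
        bank_a[open_rows] = centers - widths / 2.0
        bank_b[open_rows] = centers + widths / 2.0
        cps.append(ControlPoint(index=t, gantry_angle_deg=float(angles[t]),
                                mu_weight=float(raw_mu[t]),
                                bankA_edges=bank_a, bankB_edges=bank_b))
    plan = ArcPlan(plan_id=f"synthetic-{cfg.seed:06d}",
                   control_points=cps, n_leaf_pairs=cfg.n_leaf_pairs,
                   leaf_width_cm=cfg.leaf_width_cm,
                   variant_label=variant_label)
    plan = normalize_mu(plan)
    plan.validate()
    return plan


#: Geometry guaranteed by the default generator bounds: every control
#: point's aperture covers this crossplane interval for every open row.
_GUARANTEED_X_CM = 1.0  # |center| <= 1.2, width >= 4.6  ->  covers +/-1.1


def generate_roi_masks(seed: int, grid: GridSpec) -> list[ROIMask]:
    """Deterministic planar ROIs: one central target ellipse inside the
    high-dose footprint, plus two lateral organ-like ellipses."""
    rng = np.random.default_rng(seed)
    x = grid.coords
    xx, yy = np.meshgrid(x, x)  # yy varies along rows (inplane axis)

    def ellipse(cx, cy, ax, ay):
        if abs(cx) + ax > grid.half_extent_cm or \
                abs(cy) + ay > grid.half_extent_cm:
            raise GeneratorConfigError("ROI exceeds the grid extent")
        m = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0
        return m

    target = ellipse(0.0, float(rng.uniform(-0.4, 0.4)),
                     _GUARANTEED_X_CM * float(rng.uniform(0.85, 1.0)),
                     float(rng.uniform(2.6, 3.0)))
    organ_a = ellipse(float(rng.uniform(-5.0, -4.2)),
                      float(rng.uniform(-1.0, 1.0)),
                      float(rng.uniform(1.0, 1.4)),
                      float(rng.uniform(1.8, 2.4)))
    organ_b = ellipse(float(rng.uniform(4.2, 5.0)),
                      float(rng.uniform(-1.0, 1.0)),
                      float(rng.uniform(1.0, 1.4)),
                      float(rng.uniform(1.8, 2.4)))
    return [ROIMask("target", target, "target"),
            ROIMask("organ_a", organ_a, "parallel-organ"),
            ROIMask("organ_b", organ_b, "serial-organ")]
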