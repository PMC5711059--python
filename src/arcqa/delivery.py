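"""Planar dose accumulation in gantry- and couch-stationary frames.

This module carries the geometric mechanism the whole analysis rests on.
A detector mounted on the gantry (GS) keeps a fixed orientation relative
to the collimator, so fluence from every control point lands in collimator
coordinates unchanged and a one-bank MLC error accumulates on one side of
the map.  A detector fixed on the couch (CS) sees the collimator flip
left-for-right whenever the beam comes from "below" (|gantry angle| >= 90
degrees), exactly as a supine patient does, so the same error is smeared
onto both sides of the map over a full arc.

Accumulation is an idealized unit-fluence model: each control point's
aperture is rasterized with exact partial-area weighting, optionally
blurred with an isotropic Gaussian to emulate penumbra, weighted by its
MU fraction, frame-transformed, and summed.  Source-detector magnification
and beam divergence are ignored (all geometry at the isocenter plane);
scatter, attenuation and detector energy response are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d, gaussian_filter

from .grid import (BEV, CS, GS, DetectorSpec, ExtentError, GridSpec,
                   PlanarDose)
from .plan import ArcPlan, ControlPoint

#: Fine lattice the apertures are rasterized on (cm).
DEFAULT_SIM_SPACING_CM = 0.05
#: Coarser lattice the comparisons run on (cm), the resolution planar QA
#: software typically analyzes at.
DEFAULT_ANALYSIS_SPACING_CM = 0.3
DEFAULT_HALF_EXTENT_CM = 13.5


@dataclass(frozen=True)
class DeliveryConfig:
    """Knobs of the accumulation model.

    penumbra_sigma_cm
        Isotropic Gaussian blur applied to the accumulated map (0 = sharp
        ideal collimation).  The blur conserves the fluence integral up to
        truncation at the grid boundary.
    weighting
        Per-control-point deposition weight w(theta): "uniform" (w = 1,
        both frames then conserve total fluence exactly) or "cos"
        (|cos theta| ** cos_power, a crude lateral-beam attenuation).
    """

    penumbra_sigma_cm: float = 0.3
    weighting: str = "uniform"
    cos_power: float = 1.0

    def __post_init__(self) -> None:
        if self.penumbra_sigma_cm < 0:
            raise ValueError("penumbra_sigma_cm must be >= 0")
        if self.weighting not in ("uniform", "cos"):
            raise ValueError("weighting must be 'uniform' or 'cos'")


def angle_weight(gantry_angle_deg: float, config: DeliveryConfig) -> float:
    if config.weighting == "uniform":
        return 1.0
    return abs(math.cos(math.radians(gantry_angle_deg))) ** config.cos_power


def _overlap_fraction(lo: float, hi: float, centers: np.ndarray,
                      spacing: float) -> np.ndarray:
    """Fraction of each node-centered cell covered by interval [lo, hi]."""
    left = np.maximum(lo, centers - spacing / 2.0)
    right = np.minimum(hi, centers + spacing / 2.0)
    return np.clip((right - left) / spacing, 0.0, 1.0)


def rasterize_aperture(cp: ControlPoint, grid: GridSpec,
                       leaf_width_cm: float = 1.0) -> PlanarDose:
    """Unit-intensity fluence map of one control point's MLC aperture.

    Leaf-pair ``i`` occupies the inplane band
    ``[(i - n/2) * w, (i + 1 - n/2) * w]`` (bank stack centered on the
    axis); within its band the map is 1 inside ``[A_i, B_i]``, 0 outside,
    with exact partial-area weighting for cells cut by an aperture edge.
    Raises ExtentError when open pairs exist but none overlaps the grid.
    """
    n_pairs = cp.bankA_edges.shape[0]
    xc = grid.coords
    yc = grid.coords
    values = np.zeros((yc.size, xc.size))
    open_any = False
    for i in np.flatnonzero(cp.open_pairs):
        open_any = True
        y_lo = (i - n_pairs / 2.0) * leaf_width_cm
        y_hi = y_lo + leaf_width_cm
        yw = _overlap_fraction(y_lo, y_hi, yc, grid.spacing_cm)
        if not yw.any():
            continue
        xw = _overlap_fraction(cp.bankA_edges[i], cp.bankB_edges[i], xc,
                               grid.spacing_cm)
        values += np.outer(yw, xw)
    if open_any and values.sum() == 0.0:
        raise ExtentError(
            "grid does not contain any part of the open aperture")
    return PlanarDose(grid, values, frame=BEV)


def apply_penumbra(dose: PlanarDose, sigma_cm: float) -> PlanarDose:
    """Isotropic Gaussian penumbra blur; no-op for sigma 0."""
    if sigma_cm == 0:
        return dose
    blurred = gaussian_filter(dose.values, sigma=sigma_cm / dose.grid.spacing_cm,
                              mode="constant")
    return PlanarDose(dose.grid, blurred, frame=dose.frame,
                      delivery_mode=dose.delivery_mode)


def frame_transform(fluence: PlanarDose, gantry_angle_deg: float,
                    frame: str, weight: float = 1.0) -> PlanarDose:
    """Map a single-control-point fluence into the detector frame.

    GS: identity at every angle (the detector rides with the collimator).
    CS: identity for |angle| < 90; mirror about the inplane axis
    (x -> -x) for |angle| >= 90, the flipped branch owning the boundary.
    ``weight`` scales the map (deposition weight w(theta)).
    """
    if not -180.0 <= gantry_angle_deg <= 180.0:
        raise ValueError(
            f"gantry angle {gantry_angle_deg} outside [-180, 180]")
    if frame not in (GS, CS):
        raise ValueError("frame must be GS or CS")
    values = fluence.values
    if frame == CS and abs(gantry_angle_deg) >= 90.0:
        values = values[:, ::-1]
    return PlanarDose(fluence.grid, weight * values, frame=frame,
                      delivery_mode=fluence.delivery_mode)


def accumulate_dose(plan: ArcPlan, frame: str, grid: GridSpec,
                    config: DeliveryConfig | None = None) -> PlanarDose:
    """MU-weighted sum of frame-transformed control-point fluences."""
    config = config or DeliveryConfig()
    plan.validate()
    total = np.zeros((grid.n_nodes, grid.n_nodes))
    for cp in plan.control_points:
        fl = rasterize_aperture(cp, grid, plan.leaf_width_cm)
        w = cp.mu_weight * angle_weight(cp.gantry_angle_deg, config)
        total += frame_transform(fl, cp.gantry_angle_deg, frame, w).values
    dose = PlanarDose(grid, total, frame=frame,
                      delivery_mode=plan.delivery_mode)
    return apply_penumbra(dose, config.penumbra_sigma_cm)


# -- detector resampling ---------------------------------------------------


def _window_kernel(size_cm: float, spacing_cm: float) -> np.ndarray:
    """Exact 1D area-average weights of a ``size_cm`` window over cells of
    pitch ``spacing_cm`` centered on a node (normalized to sum 1)."""
    half = size_cm / 2.0
    k = int(math.floor((half + spacing_cm / 2.0) / spacing_cm + 1e-9))
    offs = np.arange(-k, k + 1) * spacing_cm
    left = np.maximum(-half, offs - spacing_cm / 2.0)
    right = np.minimum(half, offs + spacing_cm / 2.0)
    w = np.clip(right - left, 0.0, None)
    return w / w.sum()


def resample_to_detector(dose: PlanarDose, det: DetectorSpec) -> PlanarDose:
    """Sample a dose map onto a detector lattice centered on the axis.

    Point-sample mode reads the nearest dose node at each element center;
    area-average mode takes the exact mean over the square element
    footprint (separable overlap-weight convolution; footprints reaching
    past the grid boundary are zero-padded).  The lattice is the largest
    square array of element centers inside the dose grid; ExtentError if
    even the central element's footprint overhangs the whole grid.
    """
    h = dose.grid.spacing_cm
    if det.mode == "area-average" and h > det.element_size_cm + 1e-12:
        raise ValueError(
            "dose grid pitch must not exceed the detector element size "
            "for area-average resampling")
    if det.element_size_cm / 2.0 > dose.grid.half_extent_cm + h / 2.0:
        raise ExtentError("detector lattice exceeds the dose grid extent")
    m_det = int(math.floor(
        dose.grid.half_extent_cm / det.element_spacing_cm + 1e-9))
    det_coords = np.arange(-m_det, m_det + 1) * det.element_spacing_cm
    if det.mode == "area-average":
        kern = _window_kernel(det.element_size_cm, h)
        field = convolve1d(dose.values, kern, axis=0, mode="constant")
        field = convolve1d(field, kern, axis=1, mode="constant")
    else:
        field = dose.values
    idx = np.rint((det_coords + dose.grid.half_extent_cm) / h).astype(int)
    values = field[np.ix_(idx, idx)]
    out_grid = GridSpec(det.element_spacing_cm,
                        m_det * det.element_spacing_cm)
    return PlanarDose(out_grid, values, frame=dose.frame,
                      delivery_mode=dose.delivery_mode)


def resample_to_grid(dose: PlanarDose, spacing_cm: float) -> PlanarDose:
    """Area-average the map onto a coarser analysis lattice of the given
    pitch (block mean with exact fractional edge weights)."""
    det = DetectorSpec("analysis", spacing_cm, spacing_cm, "area-average")
    return resample_to_detector(dose, det)
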