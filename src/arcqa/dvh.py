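"""Dose-volume-histogram metrics over planar regions of interest.

Planar (2D) ROIs stand in for volumetric structures; the cumulative-DVH
metric definitions are dimension-agnostic.  All quantile metrics use a
discrete convention with no interpolation: ``D_p`` is the largest attained
dose d such that at least a fraction p of the ROI receives >= d, i.e. the
ceiling-rule order statistic of the masked dose values.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from .grid import GridSpec, PlanarDose

ROI_ROLES = ("target", "parallel-organ", "serial-organ")


class EmptyROIError(ValueError):
    pass


@dataclass
class ROIMask:
    name: str
    mask: np.ndarray
    role: str = "target"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.role not in ROI_ROLES:
            raise ValueError(f"role must be one of {ROI_ROLES}")
        if not self.mask.any():
            raise EmptyROIError(f"ROI {self.name!r} has no voxels")


@dataclass
class DVHMetrics:
    """Cumulative-DVH summary of one dose distribution over one ROI.

    d95 / d1pct are doses (same units as the map); v107_fraction and
    v_at_dose values are volume fractions in [0, 1].
    """

    d95: float
    v107_fraction: float
    mean_dose: float
    d1pct: float
    v_at_dose: dict[float, float] = field(default_factory=dict)
    roi_name: str = ""
    prescription: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        out = {"d95": self.d95, "v107_fraction": self.v107_fraction,
               "mean_dose": self.mean_dose, "d1pct": self.d1pct}
        for x, v in self.v_at_dose.items():
            out[f"v_at_{x:g}"] = v
        return out


def dose_at_volume(values: np.ndarray, p: float) -> float:
    """Discrete D_p: largest attained dose received by >= fraction p."""
    if not 0.0 < p <= 1.0:
        raise ValueError("volume fraction must be in (0, 1]")
    desc = np.sort(values)[::-1]
    k = int(math.ceil(p * desc.size - 1e-12))
    return float(desc[k - 1])


def volume_at_dose(values: np.ndarray, dose: float) -> float:
    """V_x: fraction of the ROI receiving at least ``dose``."""
    return float(np.mean(values >= dose))


def dvh_metrics(dose, roi, prescription: float,
                v_doses: tuple[float, ...] = ()) -> DVHMetrics:
    """Compute D95, V107%, mean, D1% and requested V_x over the ROI."""
    if prescription <= 0:
        raise ValueError("prescription must be positive")
    values = dose.values if isinstance(dose, PlanarDose) else np.asarray(
        dose, dtype=float)
    mask = roi.mask if isinstance(roi, ROIMask) else np.asarray(roi,
                                                               dtype=bool)
    if values.shape != mask.shape:
        raise ValueError("ROI mask is not congruent with the dose grid")
    if not mask.any():
        raise EmptyROIError("ROI mask is empty")
    vals = values[mask]
    return DVHMetrics(
        d95=dose_at_volume(vals, 0.95),
        v107_fraction=volume_at_dose(vals, 1.07 * prescription),
        mean_dose=float(vals.mean()),
        d1pct=dose_at_volume(vals, 0.01),
        v_at_dose={x: volume_at_dose(vals, x) for x in v_doses},
        roi_name=roi.name if isinstance(roi, ROIMask) else "",
        prescription=prescription,
    )


@dataclass(frozen=True)
class MetricDelta:
    """Unsigned relative difference with the direction reported separately.

    ``percent`` is 100 * |m0 - m1| / m0 (error-free value as denominator);
    None when the denominator is zero (difference undefined, flagged, not
    propagated as a number).  ``sign`` is the sign of m1 - m0.
    """

    percent: float | None
    sign: int


def metric_relative_difference(m0: DVHMetrics, m1: DVHMetrics
                               ) -> dict[str, MetricDelta]:
    """Per-metric relative differences between the error-free (m0) and
    perturbed (m1) distributions."""
    if m0.roi_name != m1.roi_name:
        raise ValueError("metrics belong to different ROIs")
    if not (np.isnan(m0.prescription) and np.isnan(m1.prescription)) and \
            m0.prescription != m1.prescription:
        raise ValueError("metrics use different prescriptions")
    d0, d1 = m0.as_dict(), m1.as_dict()
    out = {}
    for key in d0:
        v0, v1 = d0[key], d1[key]
        sign = int(np.sign(v1 - v0))
        pct = None if v0 == 0 else 100.0 * abs(v0 - v1) / abs(v0)
        out[key] = MetricDelta(pct, sign)
    return out


# -- ROI CSV serialization -------------------------------------------------

_HEADER_RE = re.compile(r"(\w+)\s*=\s*(\S+)")


def write_roi_csv(roi: ROIMask, grid: GridSpec, path) -> None:
    header = (f"# spacing_cm={grid.spacing_cm!r}\n"
              f"# half_extent_cm={grid.half_extent_cm!r}\n"
              f"# name={roi.name} role={roi.role}")
    np.savetxt(path, roi.mask.astype(int), delimiter=",", header=header,
               comments="", fmt="%d")


def read_roi_csv(path) -> tuple[ROIMask, GridSpec]:
    meta = {}
    with open(path) as fh:
        for _ in range(3):
            for key, val in _HEADER_RE.findall(fh.readline()):
                meta[key] = val
        mask = np.loadtxt(fh, delimiter=",").astype(bool)
    grid = GridSpec(float(meta["spacing_cm"]), float(meta["half_extent_cm"]))
    return ROIMask(meta.get("name", "roi"), np.atleast_2d(mask),
                   meta.get("role", "target")), grid
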