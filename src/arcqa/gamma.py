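"""Discrete 2D gamma-index analysis.

For each included reference point r the gamma index is the minimum, over
evaluation points e within a search radius, of

    sqrt( (dose_diff(r, e) / D_crit)^2 + (dist(r, e) / d_crit)^2 )

with D_crit the dose criterion (percent of the global reference maximum,
or of the local reference value) and d_crit the distance criterion in mm.
A point passes when gamma <= 1.  The search is purely discrete (grid
nodes only, no sub-grid interpolation), which keeps the statistic
deterministic and checkable against an exhaustive all-points search.

The restricted search radius (default 3 x the distance criterion) is
exact whenever the point's true gamma is below the radius factor; points
with larger gamma carry a lower bound, which never changes the pass/fail
verdict at gamma = 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .compare import EmptyMaskError
from .grid import PlanarDose, require_same_lattice

#: Slack on the gamma <= 1 pass test, absorbing float round-off when a
#: candidate sits exactly on the criterion.
PASS_TOL = 1e-9


@dataclass(frozen=True)
class GammaCriteria:
    dose_diff_percent: float = 3.0
    distance_mm: float = 3.0
    normalization: str = "global"
    low_dose_cutoff_fraction: float = 0.1
    search_radius_factor: float = 3.0

    def __post_init__(self) -> None:
        if self.dose_diff_percent <= 0 or self.distance_mm <= 0:
            raise ValueError("both gamma criteria must be positive")
        if self.normalization not in ("global", "local"):
            raise ValueError("normalization must be 'global' or 'local'")


@dataclass
class GammaResult:
    gamma: np.ndarray
    mask: np.ndarray
    pass_rate: float
    criteria: GammaCriteria

    @property
    def pass_percent(self) -> float:
        return 100.0 * self.pass_rate


def _values_spacing(dose, spacing_cm):
    if isinstance(dose, PlanarDose):
        return dose.values, dose.grid.spacing_cm
    if spacing_cm is None:
        raise ValueError("spacing_cm is required for bare-array input")
    return np.asarray(dose, dtype=float), float(spacing_cm)


def gamma_map(ref, eval_, crit: GammaCriteria | None = None,
              spacing_cm: float | None = None) -> GammaResult:
    """Per-point gamma and the pass rate over the low-dose-cutoff mask."""
    crit = crit or GammaCriteria()
    if isinstance(ref, PlanarDose) and isinstance(eval_, PlanarDose):
        require_same_lattice(ref, eval_)
    rv, h = _values_spacing(ref, spacing_cm)
    ev, _ = _values_spacing(eval_, spacing_cm)
    if rv.shape != ev.shape:
        raise ValueError(f"shape mismatch: {rv.shape} vs {ev.shape}")
    pitch_mm = h * 10.0
    if pitch_mm > crit.distance_mm + 1e-9:
        warnings.warn(
            f"grid pitch {pitch_mm:.1f} mm exceeds the distance criterion "
            f"{crit.distance_mm:.1f} mm; discrete gamma will be coarse",
            stacklevel=2)
    ref_max = float(rv.max())
    if ref_max <= 0:
        raise EmptyMaskError("reference map has no positive dose")
    mask = rv >= crit.low_dose_cutoff_fraction * ref_max
    if crit.normalization == "global":
        d_crit = crit.dose_diff_percent / 100.0 * ref_max
        d_crit_map = np.full_like(rv, d_crit)
    else:
        d_crit_map = crit.dose_diff_percent / 100.0 * np.where(rv > 0, rv,
                                                               np.inf)
    radius_mm = crit.search_radius_factor * crit.distance_mm
    r_cells = int(math.floor(radius_mm / pitch_mm + 1e-9))
    ny, nx = rv.shape
    gamma = np.full_like(rv, np.inf)
    padded = np.full((ny + 2 * r_cells, nx + 2 * r_cells), np.inf)
    padded[r_cells:r_cells + ny, r_cells:r_cells + nx] = ev
    for di in range(-r_cells, r_cells + 1):
        for dj in range(-r_cells, r_cells + 1):
            dist_mm = math.hypot(di, dj) * pitch_mm
            if dist_mm > radius_mm + 1e-9:
                continue
            shifted = padded[r_cells + di:r_cells + di + ny,
                             r_cells + dj:r_cells + dj + nx]
            with np.errstate(invalid="ignore"):
                cand = np.sqrt(((shifted - rv) / d_crit_map) ** 2
                               + (dist_mm / crit.distance_mm) ** 2)
            np.fmin(gamma, cand, out=gamma)
    if not np.any(mask):
        raise EmptyMaskError("inclusion mask is empty")
    pass_rate = float(np.mean(gamma[mask] <= 1.0 + PASS_TOL))
    return GammaResult(gamma, mask, pass_rate, crit)
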