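"""Point-to-point planar dose comparison: percent-difference maps,
pass fractions, and the threshold-to-target-match statistic.

The comparison is deliberately DTA = 0: both maps must share one lattice
and every point is compared against itself, which is the right statistic
when the perturbation under study moves leaves, not the detector.  Percent
differences follow the global (Van Dyk) convention by default: signed
difference normalized to the maximum of the reference map, with points
below a low-dose cutoff excluded.

The headline statistic is ``threshold_to_target``: the smallest percent
criterion at which a target fraction (default 95%) of included points
agrees.  It is computed as the exact order statistic of |diff| at the
target quantile (ceiling rule), snapped up to a configurable scan grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .grid import PlanarDose, require_same_lattice


class EmptyMaskError(ValueError):
    """No points survive the low-dose cutoff; statistic undefined."""


class TargetUnreachableError(ValueError):
    """Target match fraction not reachable within the scan range."""


@dataclass(frozen=True)
class ComparisonConfig:
    normalization: str = "global"          # "global" or "local"
    low_dose_cutoff_fraction: float = 0.1  # of the reference maximum
    target_match_fraction: float = 0.95
    scan_step_percent: float = 0.1
    scan_max_percent: float = 50.0
    #: Optional shared normalization value overriding max(ref); used when a
    #: symmetric comparison (ref vs eval and eval vs ref) must share N.
    norm_value: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.low_dose_cutoff_fraction < 1.0:
            raise ValueError("cutoff fraction must be in [0, 1)")
        if not 0.0 < self.target_match_fraction <= 1.0:
            raise ValueError("target fraction must be in (0, 1]")
        if self.normalization not in ("global", "local"):
            raise ValueError("normalization must be 'global' or 'local'")
        if self.scan_step_percent < 0:
            raise ValueError("scan step must be >= 0 (0 = exact quantile)")


@dataclass
class ComparisonResult:
    diff_map: np.ndarray
    mask: np.ndarray
    pass_deltas: np.ndarray
    pass_fractions: np.ndarray
    threshold_at_target: float
    config: ComparisonConfig


def _values(dose) -> np.ndarray:
    return dose.values if isinstance(dose, PlanarDose) else np.asarray(
        dose, dtype=float)


def percent_diff_map(ref, eval_, cfg: ComparisonConfig | None = None):
    """Signed percent-difference map and inclusion mask.

    Per included point: ``100 * (ref - eval) / N`` with N the reference
    maximum (global) or the local reference value.  Points below
    ``cutoff * max(ref)`` are excluded from the mask.  Raises
    GridMismatchError when PlanarDose inputs live on different lattices.
    """
    cfg = cfg or ComparisonConfig()
    if isinstance(ref, PlanarDose) and isinstance(eval_, PlanarDose):
        require_same_lattice(ref, eval_)
    rv, ev = _values(ref), _values(eval_)
    if rv.shape != ev.shape:
        raise ValueError(f"shape mismatch: {rv.shape} vs {ev.shape}")
    ref_max = float(rv.max())
    if ref_max <= 0:
        raise EmptyMaskError("reference map has no positive dose")
    mask = rv >= cfg.low_dose_cutoff_fraction * ref_max
    if cfg.normalization == "global":
        norm = cfg.norm_value if cfg.norm_value is not None else ref_max
        diff = 100.0 * (rv - ev) / norm
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            diff = np.where(rv > 0, 100.0 * (rv - ev) / np.where(rv > 0, rv, 1.0),
                            np.where(ev == rv, 0.0, np.inf))
    return diff, mask


def pass_fraction(diff_map: np.ndarray, mask: np.ndarray,
                  delta_percent: float) -> float:
    """Fraction of included points with |diff| <= delta."""
    if not np.any(mask):
        raise EmptyMaskError("inclusion mask is empty")
    return float(np.mean(np.abs(diff_map[mask]) <= delta_percent))


def threshold_to_target(ref, eval_, cfg: ComparisonConfig | None = None
                        ) -> float:
    """Smallest percent criterion achieving the target match fraction.

    Equals the ceiling-rule order statistic of |diff| over the mask,
    snapped up to the scan grid (``scan_step_percent``; 0 keeps the exact
    quantile).  Raises TargetUnreachableError beyond ``scan_max_percent``.
    """
    cfg = cfg or ComparisonConfig()
    diff, mask = percent_diff_map(ref, eval_, cfg)
    if not np.any(mask):
        raise EmptyMaskError("inclusion mask is empty")
    q = np.sort(np.abs(diff[mask]))
    n = q.size
    k = int(math.ceil(cfg.target_match_fraction * n - 1e-12))
    t_exact = float(q[k - 1])
    if cfg.scan_step_percent > 0:
        t = cfg.scan_step_percent * math.ceil(
            t_exact / cfg.scan_step_percent - 1e-9)
    else:
        t = t_exact
    if t > cfg.scan_max_percent + 1e-9:
        raise TargetUnreachableError(
            f"target fraction {cfg.target_match_fraction} needs "
            f"{t_exact:.2f}%, beyond the {cfg.scan_max_percent}% scan range")
    return float(t)


def pass_fraction_curve(diff_map: np.ndarray, mask: np.ndarray,
                        cfg: ComparisonConfig | None = None):
    """Pass fraction sampled on the scan grid (delta -> fraction)."""
    cfg = cfg or ComparisonConfig()
    step = cfg.scan_step_percent or 0.1
    deltas = np.arange(0.0, cfg.scan_max_percent + step / 2, step)
    absd = np.abs(diff_map[mask])
    fractions = np.searchsorted(np.sort(absd), deltas + 1e-12) / absd.size
    return deltas, fractions


def compare_doses(ref, eval_, cfg: ComparisonConfig | None = None
                  ) -> ComparisonResult:
    """Full DTA=0 comparison: diff map, pass curve and threshold."""
    cfg = cfg or ComparisonConfig()
    diff, mask = percent_diff_map(ref, eval_, cfg)
    deltas, fractions = pass_fraction_curve(diff, mask, cfg)
    threshold = threshold_to_target(ref, eval_, cfg)
    return ComparisonResult(diff, mask, deltas, fractions, threshold, cfg)
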