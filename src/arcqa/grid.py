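"""Planar dose grids, detector descriptions and their CSV serialization.

All dose maps live on square node-centered grids in the isocenter plane
with an odd number of nodes per axis, so one node sits exactly on the
beam axis and the x -> -x mirror used by the couch-stationary frame maps
nodes onto nodes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

GS = "GS"   # gantry-stationary frame (detector rides on the gantry)
CS = "CS"   # couch-stationary frame (detector fixed on the couch)
BEV = "BEV"  # beam's-eye-view collimator frame (pre-transform fluence)

_FRAMES = (GS, CS, BEV)


class GridMismatchError(ValueError):
    """Two maps that must share a lattice do not."""


class ExtentError(ValueError):
    """A lattice or aperture does not fit the available grid extent."""


@dataclass(frozen=True)
class GridSpec:
    """Square node-centered lattice: pitch ``spacing_cm``, nodes at
    ``k * spacing_cm`` for ``k in [-m, m]`` on each axis."""

    spacing_cm: float
    half_extent_cm: float

    def __post_init__(self) -> None:
        if self.spacing_cm <= 0:
            raise ValueError("spacing_cm must be positive")
        m = self.half_extent_cm / self.spacing_cm
        if abs(m - round(m)) > 1e-6:
            raise ValueError(
                "half_extent_cm must be an integer multiple of spacing_cm "
                "so that a node sits on the isocenter axis")

    @property
    def n_nodes(self) -> int:
        return 2 * int(round(self.half_extent_cm / self.spacing_cm)) + 1

    @property
    def coords(self) -> np.ndarray:
        m = (self.n_nodes - 1) // 2
        return np.arange(-m, m + 1) * self.spacing_cm

    @property
    def cell_area_cm2(self) -> float:
        return self.spacing_cm ** 2


@dataclass(eq=False)
class PlanarDose:
    """2D dose/fluence map at the isocenter plane.

    ``values[iy, ix]``: y (rows) is the inplane leaf-index axis, x (cols)
    the crossplane leaf-travel axis, both increasing with index.
    """

    grid: GridSpec
    values: np.ndarray
    frame: str = BEV
    delivery_mode: str = "rotational"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.grid.n_nodes
        if self.values.shape != (n, n):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({n} x {n})")
        if self.frame not in _FRAMES:
            raise ValueError(f"frame must be one of {_FRAMES}")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("dose values must be finite and non-negative")

    @property
    def integral_cm2(self) -> float:
        """Sum of values times cell area (fluence-area units)."""
        return float(self.values.sum() * self.grid.cell_area_cm2)

    def same_lattice(self, other: "PlanarDose") -> bool:
        return self.grid == other.grid


def require_same_lattice(a: PlanarDose, b: PlanarDose) -> None:
    if not a.same_lattice(b):
        raise GridMismatchError(
            f"grids differ: {a.grid} vs {b.grid}; maps are never silently "
            "resampled")


@dataclass(frozen=True)
class DetectorSpec:
    """Sampling pattern of a planar detector at the isocenter plane."""

    name: str
    element_spacing_cm: float
    element_size_cm: float
    mode: str = "point-sample"  # or "area-average"

    def __post_init__(self) -> None:
        if self.element_spacing_cm <= 0 or self.element_size_cm <= 0:
            raise ValueError("detector pitch and element size must be > 0")
        if self.mode not in ("point-sample", "area-average"):
            raise ValueError("mode must be point-sample or area-average")
        if self.element_size_cm > self.element_spacing_cm + 1e-12:
            raise ValueError("element size must not exceed element spacing")


#: Presets for the two physical devices the simulation emulates: a
#: 27 x 27 ion-chamber array (729 elements, 1 cm pitch, 0.5 cm cubic
#: chambers) and an amorphous-silicon portal imager (0.4 mm pixels,
#: point sampling, dimensions quoted at the isocenter plane).
DETECTOR_PRESETS = {
    "array729": DetectorSpec("array729", 1.0, 0.5, "area-average"),
    "epid": DetectorSpec("epid", 0.025, 0.025, "point-sample"),
}


# -- CSV serialization -----------------------------------------------------

_HEADER_RE = re.compile(r"(\w+)\s*=\s*(\S+)")


def write_dose_csv(dose: PlanarDose, path) -> None:
    """Three-line commented header (spacing, half-extent, frame/mode tags)
    followed by the comma-separated value matrix, rows = y nodes."""
    header = (f"# spacing_cm={dose.grid.spacing_cm!r}\n"
              f"# half_extent_cm={dose.grid.half_extent_cm!r}\n"
              f"# frame={dose.frame} mode={dose.delivery_mode}")
    np.savetxt(path, dose.values, delimiter=",", header=header, comments="",
               fmt="%.9e")


def read_dose_csv(path) -> PlanarDose:
    meta = {}
    with open(path) as fh:
        for _ in range(3):
            line = fh.readline()
            for key, val in _HEADER_RE.findall(line):
                meta[key] = val
        values = np.loadtxt(fh, delimiter=",")
    for key in ("spacing_cm", "half_extent_cm", "frame", "mode"):
        if key not in meta:
            raise ValueError(f"dose CSV header missing {key!r}")
    grid = GridSpec(float(meta["spacing_cm"]), float(meta["half_extent_cm"]))
    return PlanarDose(grid, np.atleast_2d(values), frame=meta["frame"],
                      delivery_mode=meta["mode"])
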