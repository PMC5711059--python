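"""Arc-plan domain model: control points, plan variants, and plan edits.

A single-arc VMAT plan is represented as an ordered sequence of control
points, each carrying an IEC 61217 gantry angle, a monitor-unit (MU)
weight, and the crossplane positions of the two opposing MLC leaf banks
(bank A approaching from the -x side, bank B from +x).  Two plan edits are
provided: injection of a systematic one-bank positional error (the
MLC0PE -> MLC1PE edit) and collapsing every gantry angle to 0 degrees
(static "downward" delivery of the same aperture sequence).

Conventions
-----------
* Coordinates are cm in the isocenter plane; leaf travel is along x
  (crossplane), leaf index along y (inplane).
* The aperture of leaf pair ``i`` is the interval ``[A_i, B_i]``;
  ``A_i == B_i`` means the pair is closed.  "Opening bank A by d" moves
  every open pair's A edge to ``A_i - d``.  Parked (closed) pairs travel
  together and stay closed under a bank offset.
* MU weights are relative and normalized to sum to one.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

MAX_CROSSPLANE_CM = 13.5
ROTATIONAL = "rotational"
COLLAPSED = "collapsed"
MU_SUM_TOL = 1e-9
_EDGE_DECIMALS = 6


class PlanSchemaError(ValueError):
    """Plan file does not conform to the JSON plan schema."""


class PlanValidationError(ValueError):
    """Plan violates a structural invariant (geometry, weights, angles)."""


class LeafRangeError(PlanValidationError):
    """A leaf edge falls outside the mechanical crossplane travel range."""


@dataclass(frozen=True, eq=False)
class ControlPoint:
    """One plan sample: gantry angle, MU weight and both bank edge vectors."""

    index: int
    gantry_angle_deg: float
    mu_weight: float
    bankA_edges: np.ndarray
    bankB_edges: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "bankA_edges",
                           np.asarray(self.bankA_edges, dtype=float))
        object.__setattr__(self, "bankB_edges",
                           np.asarray(self.bankB_edges, dtype=float))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ControlPoint):
            return NotImplemented
        return (self.index == other.index
                and self.gantry_angle_deg == other.gantry_angle_deg
                and self.mu_weight == other.mu_weight
                and np.array_equal(self.bankA_edges, other.bankA_edges)
                and np.array_equal(self.bankB_edges, other.bankB_edges))

    @property
    def open_pairs(self) -> np.ndarray:
        """Boolean vector: True where the leaf pair is open (A < B)."""
        return self.bankA_edges < self.bankB_edges


@dataclass(frozen=True)
class PerturbationSpec:
    """Systematic one-bank positional error.

    ``offset_cm`` is signed; positive opens the named bank (bank A edges
    decrease, bank B edges increase).  The offset is applied identically to
    every open leaf pair of that bank at every control point; closed pairs
    remain closed.
    """

    bank: str = "A"
    offset_cm: float = 0.1
    scope: str = "systematic"

    def __post_init__(self) -> None:
        if self.bank not in ("A", "B"):
            raise ValueError(f"bank must be 'A' or 'B', got {self.bank!r}")
        if self.scope != "systematic":
            raise ValueError("only systematic (all-leaves) scope is supported")


@dataclass(eq=False)
class ArcPlan:
    plan_id: str
    control_points: list[ControlPoint]
    n_leaf_pairs: int = 40
    leaf_width_cm: float = 1.0
    variant_label: str = "MLC0PE"
    delivery_mode: str = ROTATIONAL

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ArcPlan):
            return NotImplemented
        return (self.plan_id == other.plan_id
                and self.n_leaf_pairs == other.n_leaf_pairs
                and self.leaf_width_cm == other.leaf_width_cm
                and self.variant_label == other.variant_label
                and self.delivery_mode == other.delivery_mode
                and len(self.control_points) == len(other.control_points)
                and all(a == b for a, b in
                        zip(self.control_points, other.control_points)))

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Raise PlanValidationError on the first violated invariant."""
        if self.delivery_mode not in (ROTATIONAL, COLLAPSED):
            raise PlanValidationError(
                f"unknown delivery_mode {self.delivery_mode!r}")
        if not self.control_points:
            raise PlanValidationError("plan has no control points")
        if self.n_leaf_pairs < 1 or self.leaf_width_cm <= 0:
            raise PlanValidationError("invalid leaf geometry")
        mu_sum = 0.0
        for cp in self.control_points:
            if cp.bankA_edges.shape != (self.n_leaf_pairs,) or \
                    cp.bankB_edges.shape != (self.n_leaf_pairs,):
                raise PlanValidationError(
                    f"control point {cp.index}: expected {self.n_leaf_pairs} "
                    "edges per bank")
            bad = np.flatnonzero(cp.bankA_edges > cp.bankB_edges)
            if bad.size:
                raise PlanValidationError(
                    f"control point {cp.index}: A_i > B_i at pair indices "
                    f"{bad.tolist()}")
            for bank, edges in (("A", cp.bankA_edges), ("B", cp.bankB_edges)):
                out = np.flatnonzero(np.abs(edges) > MAX_CROSSPLANE_CM + 1e-9)
                if out.size:
                    raise LeafRangeError(
                        f"control point {cp.index}: bank {bank} edges outside "
                        f"+/-{MAX_CROSSPLANE_CM} cm at pairs {out.tolist()}")
            if not math.isfinite(cp.mu_weight) or cp.mu_weight < 0:
                raise PlanValidationError(
                    f"control point {cp.index}: negative or non-finite "
                    "MU weight")
            if not -180.0 <= cp.gantry_angle_deg <= 180.0:
                raise PlanValidationError(
                    f"control point {cp.index}: gantry angle "
                    f"{cp.gantry_angle_deg} outside [-180, 180]")
            mu_sum += cp.mu_weight
        if abs(mu_sum - 1.0) > MU_SUM_TOL:
            raise PlanValidationError(
                f"MU weights sum to {mu_sum!r}, expected 1 within "
                f"{MU_SUM_TOL}")
        angles = [cp.gantry_angle_deg for cp in self.control_points]
        if self.delivery_mode == COLLAPSED:
            if any(a != 0.0 for a in angles):
                raise PlanValidationError(
                    "collapsed plan has nonzero gantry angles")
        else:
            diffs = np.diff(angles)
            if len(angles) > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
                raise PlanValidationError(
                    "rotational plan gantry angles are not strictly monotone")


def normalize_mu(plan: ArcPlan) -> ArcPlan:
    """Return a copy with MU weights rescaled to sum exactly to one."""
    total = sum(cp.mu_weight for cp in plan.control_points)
    if total <= 0:
        raise PlanValidationError("total MU weight is not positive")
    cps = [replace(cp, mu_weight=cp.mu_weight / total)
           for cp in plan.control_points]
    return replace(plan, control_points=cps)


# -- plan edits ------------------------------------------------------------


def inject_bank_error(plan: ArcPlan, spec: PerturbationSpec) -> ArcPlan:
    """Apply a systematic bank positional error; returns the MLC1PE variant.

    Positive ``offset_cm`` opens the bank: each open pair's A edge moves to
    ``A_i - offset`` (bank A) or B edge to ``B_i + offset`` (bank B).
    Closed pairs (A == B) are parked and stay closed.  Raises
    LeafRangeError if any edge would leave the travel range.
    """
    plan.validate()
    cps = []
    for cp in plan.control_points:
        a = cp.bankA_edges.copy()
        b = cp.bankB_edges.copy()
        open_ = cp.open_pairs
        if spec.bank == "A":
            a[open_] -= spec.offset_cm
        else:
            b[open_] += spec.offset_cm
        if np.any(np.abs(a) > MAX_CROSSPLANE_CM + 1e-9) or \
                np.any(np.abs(b) > MAX_CROSSPLANE_CM + 1e-9):
            raise LeafRangeError(
                f"offset {spec.offset_cm} cm pushes edges of control point "
                f"{cp.index} beyond +/-{MAX_CROSSPLANE_CM} cm")
        if np.any(a > b):
            raise PlanValidationError(
                f"offset {spec.offset_cm} cm closes pairs past their "
                f"opposing edge at control point {cp.index}")
        cps.append(replace(cp, bankA_edges=a, bankB_edges=b))
    out = replace(plan, control_points=cps, variant_label="MLC1PE")
    out.validate()
    return out


def collapse_gantry(plan: ArcPlan) -> ArcPlan:
    """Force every gantry angle to 0 degrees (static downward delivery).

    MLC positions and MU weights are untouched; idempotent.
    """
    plan.validate()
    cps = [replace(cp, gantry_angle_deg=0.0) for cp in plan.control_points]
    out = replace(plan, control_points=cps, delivery_mode=COLLAPSED)
    out.validate()
    return out


# -- serialization ---------------------------------------------------------


def write_plan(plan: ArcPlan, path) -> None:
    """Write the plan as JSON; edge coordinates rounded to 6 decimals."""
    doc = {
        "plan_id": plan.plan_id,
        "n_leaf_pairs": plan.n_leaf_pairs,
        "leaf_width_cm": plan.leaf_width_cm,
        "variant_label": plan.variant_label,
        "delivery_mode": plan.delivery_mode,
        "control_points": [
            {
                "index": cp.index,
                "gantry_angle_deg": round(cp.gantry_angle_deg, _EDGE_DECIMALS),
                "mu_weight": round(cp.mu_weight, 12),
                "bankA_edges": [round(v, _EDGE_DECIMALS)
                                for v in cp.bankA_edges.tolist()],
                "bankB_edges": [round(v, _EDGE_DECIMALS)
                                for v in cp.bankB_edges.tolist()],
            }
            for cp in plan.control_points
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


_REQUIRED_PLAN_KEYS = ("plan_id", "n_leaf_pairs", "leaf_width_cm",
                       "control_points")
_REQUIRED_CP_KEYS = ("index", "gantry_angle_deg", "mu_weight",
                     "bankA_edges", "bankB_edges")


def read_plan(path) -> ArcPlan:
    """Read, MU-normalize and validate a JSON plan file."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise PlanSchemaError(f"not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise PlanSchemaError("top level must be a JSON object")
    for key in _REQUIRED_PLAN_KEYS:
        if key not in doc:
            raise PlanSchemaError(f"missing required key {key!r}")
    cps = []
    for k, raw in enumerate(doc["control_points"]):
        for key in _REQUIRED_CP_KEYS:
            if key not in raw:
                raise PlanSchemaError(
                    f"control point {k}: missing required key {key!r}")
        try:
            cps.append(ControlPoint(
                index=int(raw["index"]),
                gantry_angle_deg=float(raw["gantry_angle_deg"]),
                mu_weight=float(raw["mu_weight"]),
                bankA_edges=np.asarray(raw["bankA_edges"], dtype=float),
                bankB_edges=np.asarray(raw["bankB_edges"], dtype=float),
            ))
        except (TypeError, ValueError) as exc:
            raise PlanSchemaError(f"control point {k}: {exc}") from exc
    plan = ArcPlan(
        plan_id=str(doc["plan_id"]),
        control_points=cps,
        n_leaf_pairs=int(doc["n_leaf_pairs"]),
        leaf_width_cm=float(doc["leaf_width_cm"]),
        variant_label=str(doc.get("variant_label", "MLC0PE")),
        delivery_mode=str(doc.get("delivery_mode", ROTATIONAL)),
    )
    plan = normalize_mu(plan)
    plan.validate()
    return plan


def export_plan_csv(plan: ArcPlan, path) -> None:
    """Flat CSV for inspection: one row per control point per leaf pair."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cp_index", "gantry_angle_deg", "mu_weight",
                         "leaf_pair", "bankA_cm", "bankB_cm"])
        for cp in plan.control_points:
            for i in range(plan.n_leaf_pairs):
                writer.writerow([
                    cp.index, f"{cp.gantry_angle_deg:.6f}",
                    f"{cp.mu_weight:.12f}", i,
                    f"{cp.bankA_edges[i]:.6f}", f"{cp.bankB_edges[i]:.6f}"])
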