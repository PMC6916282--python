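"""Core plan data structures: apertures, control points, plans.

Leaf-tip positions are expressed in millimetres in the beam's-eye-view
frame at the nominal source-axis plane.  A closed leaf pair is parked
with ``left == right`` (gap 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

SCHEME_TAGS = ("CKA1", "CKA2", "CKA3", "CKA4", "CKA5", "CKSB")

PlanMode = Literal["dynamic_arc", "static"]


@dataclass
class Aperture:
    """One MLC shape: per-pair left/right tip positions plus segment MU."""

    left: np.ndarray   # (n_pairs,) mm
    right: np.ndarray  # (n_pairs,) mm
    mu: float = 0.0

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.left.shape != self.right.shape:
            raise ValueError("left/right leaf arrays must have equal shape")
        if self.mu < 0:
            raise ValueError("segment MU must be non-negative")

    @property
    def n_pairs(self) -> int:
        return self.left.size

    @property
    def open_pairs(self) -> np.ndarray:
        """Boolean mask of pairs with a strictly positive gap."""
        return self.right > self.left

    @property
    def gaps(self) -> np.ndarray:
        return self.right - self.left

    def is_closed(self) -> bool:
        return not bool(self.open_pairs.any())

    def copy(self) -> "Aperture":
        return Aperture(self.left.copy(), self.right.copy(), self.mu)

    @classmethod
    def closed(cls, n_pairs: int, mu: float = 0.0, park: float = 0.0) -> "Aperture":
        p = np.full(n_pairs, float(park))
        return cls(p.copy(), p.copy(), mu)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Aperture):
            return NotImplemented
        return (
            np.array_equal(self.left, other.left)
            and np.array_equal(self.right, other.right)
            and self.mu == other.mu
        )


@dataclass
class ControlPoint:
    """A delivery control point: orientation index, aperture(s), MU.

    Dynamic plans carry exactly one aperture per control point; static
    (step-and-shoot) plans may hold any number of segments, including
    zero, at a node.
    """

    geometry_index: int
    apertures: list[Aperture] = field(default_factory=list)

    @property
    def mu(self) -> float:
        return float(sum(a.mu for a in self.apertures))


@dataclass
class Plan:
    mode: PlanMode
    control_points: list[ControlPoint]
    prescription_gy: float = 10.0
    scheme: str = "CKA1"
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scheme not in SCHEME_TAGS:
            raise ValueError(f"unknown scheme tag {self.scheme!r}; expected one of {SCHEME_TAGS}")
        if self.mode == "dynamic_arc":
            for cp in self.control_points:
                if len(cp.apertures) != 1:
                    raise ValueError("dynamic_arc plans need exactly one aperture per control point")

    @property
    def n_control_points(self) -> int:
        return len(self.control_points)

    @property
    def total_mu(self) -> float:
        return float(sum(cp.mu for cp in self.control_points))

    def scaled_mu(self, factor: float) -> "Plan":
        """Return a copy with every segment MU multiplied by ``factor``."""
        cps = [
            ControlPoint(cp.geometry_index,
                         [Aperture(a.left.copy(), a.right.copy(), a.mu * factor) for a in cp.apertures])
            for cp in self.control_points
        ]
        return replace(self, control_points=cps)
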