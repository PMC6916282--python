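"""Synthetic voxel phantoms, structures and two-control-point demo plans."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from arcplan.machine import MLCSpec, _rotate
from arcplan.plans import Aperture, ControlPoint, Plan


@dataclass
class VoxelGrid:
    """Regular 3-D grid of scalar values (density or dose).

    ``origin`` is the room-frame position (mm) of the center of voxel
    (0, 0, 0); the target point sits at the room origin.
    """

    origin: np.ndarray   # (3,) mm
    spacing: np.ndarray  # (3,) mm
    values: np.ndarray   # (nx, ny, nz)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.values = np.asarray(self.values)
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive on all axes")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centers(self) -> np.ndarray:
        """(N, 3) room-frame coordinates of all voxel centers, C-order."""
        axes = [self.origin[a] + self.spacing[a] * np.arange(self.dims[a]) for a in range(3)]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        return np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Outer box faces (lo, hi) in mm."""
        lo = self.origin - self.spacing / 2.0
        hi = self.origin + self.spacing * (np.array(self.dims) - 0.5)
        return lo, hi

    def like(self, values: np.ndarray) -> "VoxelGrid":
        if values.shape != self.values.shape:
            raise ValueError("shape mismatch")
        return VoxelGrid(self.origin.copy(), self.spacing.copy(), values)


@dataclass
class Structure:
    name: str
    mask: np.ndarray  # boolean, same shape as the grid
    grid: VoxelGrid

    def __post_init__(self) -> None:
        if self.mask.shape != self.grid.values.shape:
            raise ValueError(f"structure {self.name!r}: mask shape does not match grid")
        if not self.mask.any():
            raise ValueError(f"structure {self.name!r} has an empty mask")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_cm3(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_mm3 / 1000.0


@dataclass
class Phantom:
    grid: VoxelGrid
    structures: dict[str, Structure] = field(default_factory=dict)

    @property
    def ptv(self) -> Structure:
        return self.structures["PTV"]

    @property
    def body(self) -> Structure:
        return self.structures["BODY"]


def make_water_phantom(
    width: float = 300.0,
    length: float = 300.0,
    height: float = 200.0,
    spacing: float = 2.5,
    ptv_diameter: float = 60.0,
) -> Phantom:
    """Uniform unit-density water box with a central spherical PTV.

    The box is centered on the target point (room origin): x spans the
    width, y the length, z the height.  Returns the phantom with
    ``BODY`` (the whole box) and ``PTV`` structures.
    """
    if min(width, length, height, spacing) <= 0:
        raise ValueError("dimensions and spacing must be positive")
    if ptv_diameter >= min(width, length, height):
        raise ValueError("PTV sphere does not fit inside the phantom box")

    dims = tuple(max(1, int(round(s / spacing))) for s in (width, length, height))
    sp = np.full(3, float(spacing))
    origin = -(np.array(dims) - 1) * sp / 2.0
    grid = VoxelGrid(origin, sp, np.ones(dims, dtype=float))

    r = grid.voxel_centers()
    dist2 = np.einsum("ij,ij->i", r, r).reshape(dims)
    ptv_mask = dist2 <= (ptv_diameter / 2.0) ** 2
    body_mask = np.ones(dims, dtype=bool)

    ph = Phantom(grid)
    ph.structures["BODY"] = Structure("BODY", body_mask, grid)
    ph.structures["PTV"] = Structure("PTV", ptv_mask, grid)
    return ph


def _demo_directions() -> list[tuple[float, float, float]]:
    """Vertical beam and a beam 5 degrees from vertical (rotation about +y)."""
    down = np.array([0.0, 0.0, -1.0])
    tilted = _rotate(down, np.array([0.0, 1.0, 0.0]), 5.0)
    tilted /= np.linalg.norm(tilted)
    return [tuple(down), tuple(tilted)]


def _chord_half_width(y: float, radius: float) -> float:
    if abs(y) >= radius:
        return 0.0
    return math.sqrt(radius * radius - y * y)


def _semicircle_aperture(mlc: MLCSpec, radius: float, side: str, mu: float) -> Aperture:
    """MLC-conformal half-disc: ``side`` in {'left','right'} along leaf travel."""
    yc = mlc.pair_centers()
    left = np.zeros(mlc.n_leaf_pairs)
    right = np.zeros(mlc.n_leaf_pairs)
    for k, y in enumerate(yc):
        c = _chord_half_width(y, radius)
        if c <= 0:
            continue
        if side == "left":
            left[k], right[k] = -c, 0.0
        else:
            left[k], right[k] = 0.0, c
    return Aperture(left, right, mu)


def _crescent_aperture(mlc: MLCSpec, radius: float, side: str, mu: float,
                       width: float = 10.0) -> Aperture:
    """Crescent of fixed-width leaf openings hugging one side of the disc."""
    yc = mlc.pair_centers()
    left = np.zeros(mlc.n_leaf_pairs)
    right = np.zeros(mlc.n_leaf_pairs)
    for k, y in enumerate(yc):
        c = _chord_half_width(y, radius)
        if c <= 0:
            continue
        if side == "left":
            left[k], right[k] = -c, min(-c + width, c)
        else:
            left[k], right[k] = max(c - width, -c), c
    return Aperture(left, right, mu)


def make_two_cp_demo(
    kind: str,
    mlc: MLCSpec | None = None,
    ptv_diameter: float = 60.0,
    orientation: str = "left_first",
    prescription_gy: float = 10.0,
) -> Plan:
    """Two-control-point demonstration plans.

    ``semicircle_pair``: complementary semicircular apertures covering
    the two halves of the PTV's beam's-eye-view disc, 1000 MU each.
    ``crescent_pair``: 10-mm-wide crescents along opposite sides of the
    disc, 500 and 5500 MU.  The two beams are vertical and 5 degrees
    off vertical.  ``orientation`` selects which half/side the first
    control point covers.
    """
    mlc = mlc or MLCSpec()
    radius = ptv_diameter / 2.0
    first, second = ("left", "right") if orientation == "left_first" else ("right", "left")

    if kind == "semicircle_pair":
        ap1 = _semicircle_aperture(mlc, radius, first, 1000.0)
        ap2 = _semicircle_aperture(mlc, radius, second, 1000.0)
        scheme = "CKA1"
    elif kind == "crescent_pair":
        ap1 = _crescent_aperture(mlc, radius, first, 500.0)
        ap2 = _crescent_aperture(mlc, radius, second, 5500.0)
        scheme = "CKA4"
    else:
        raise ValueError(f"unknown demo kind {kind!r}")

    cps = [ControlPoint(0, [ap1]), ControlPoint(1, [ap2])]
    return Plan("dynamic_arc", cps, prescription_gy=prescription_gy, scheme=scheme,
                meta={"demo": kind, "directions": _demo_directions()})
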