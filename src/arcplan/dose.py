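"""Simplified divergent beamlet dose engine.

Each beamlet (bixel) column d_ij combines an inverse-square factor, a
build-up/attenuation depth-dose curve and an error-function lateral
profile (a bixel-sized rectangle convolved with a Gaussian penumbra).
Columns are truncated by dropping voxels below a fixed fraction of the
column maximum, and total dose is the weighted sum over beamlets:
D_i = sum_j d_ij w_j.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.special import erf

from arcplan.machine import SAD_MM, ControlPointGeometry, MLCSpec
from arcplan.phantom import Phantom, VoxelGrid

TRUNCATION_FRACTION = 1.5e-4  # drop d_ij below this fraction of the column max


@dataclass(frozen=True)
class KernelConfig:
    """Water depth-dose and penumbra parameters (6-MV-like defaults)."""

    mu_attenuation: float = 0.005  # /mm
    beta_buildup: float = 0.14     # /mm
    sigma_penumbra: float = 2.5    # mm at the SAD plane
    dose_per_mu: float = 0.01      # Gy per MU at the calibration point

    @property
    def buildup_depth(self) -> float:
        """Depth of the central-axis dose maximum, mm."""
        b, m = self.beta_buildup, self.mu_attenuation
        return math.log((b + m) / m) / b

    def depth_dose(self, depth_mm: np.ndarray) -> np.ndarray:
        """Unnormalized depth-dose: build-up times exponential attenuation."""
        d = np.asarray(depth_mm, dtype=float)
        out = (1.0 - np.exp(-self.beta_buildup * d)) * np.exp(-self.mu_attenuation * d)
        return np.where(d > 0, out, 0.0)

    def calibration_factor(self, ssd_mm: float) -> float:
        """Gy/MU per unit kernel output at the build-up maximum.

        The reference geometry is the central axis of a broad open
        field with the surface at ``ssd_mm`` from the source.
        """
        dmax = self.buildup_depth
        ref = self.depth_dose(np.array([dmax]))[0] * (SAD_MM / (ssd_mm + dmax)) ** 2
        return self.dose_per_mu / ref


@dataclass(frozen=True)
class BixelGrid:
    """2-D fluence grid at the SAD plane.

    Rows align with paired MLC leaves (height = paired_leaf_width);
    columns run along leaf travel.  ``pair_indices`` maps rows to MLC
    pair indices; beamlet j enumerates rows-major (row, column).
    """

    mlc: MLCSpec
    pair_indices: tuple[int, ...]
    x0: float            # mm, left edge of the first column
    n_cols: int
    col_width: float = 5.0

    def __post_init__(self) -> None:
        if self.n_cols < 1 or len(self.pair_indices) < 1:
            raise ValueError("bixel grid must have at least one row and one column")

    @property
    def n_rows(self) -> int:
        return len(self.pair_indices)

    @property
    def n_bixels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def row_height(self) -> float:
        return self.mlc.paired_leaf_width

    def col_edges(self) -> np.ndarray:
        return self.x0 + self.col_width * np.arange(self.n_cols + 1)

    def col_centers(self) -> np.ndarray:
        return self.x0 + self.col_width * (np.arange(self.n_cols) + 0.5)

    def row_centers(self) -> np.ndarray:
        return self.mlc.pair_centers()[list(self.pair_indices)]

    def bixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) centers of all bixels, rows-major, each (n_bixels,)."""
        xc, yc = self.col_centers(), self.row_centers()
        yy, xx = np.meshgrid(yc, xc, indexing="ij")
        return xx.ravel(), yy.ravel()

    @classmethod
    def centered(cls, mlc: MLCSpec, half_span_x: float = 40.0,
                 half_span_y: float = 40.0, col_width: float = 5.0) -> "BixelGrid":
        """Grid covering +/- the given spans around the beam axis."""
        pairs = tuple(
            int(k) for k, y in enumerate(mlc.pair_centers())
            if abs(y) <= half_span_y + 1e-9
        )
        n_cols = int(math.ceil(2.0 * half_span_x / col_width))
        x0 = -n_cols * col_width / 2.0
        return cls(mlc, pairs, x0, n_cols, col_width)


def _ray_entry_depth(source: np.ndarray, points: np.ndarray,
                     lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Water-equivalent depth of each point along the source->point ray.

    ``lo``/``hi`` bound the phantom box.  Points outside the box or on
    rays that miss it get depth <= 0.
    """
    v = points - source
    dist = np.linalg.norm(v, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_lo = (lo - source) / v
        t_hi = (hi - source) / v
    t_near = np.minimum(t_lo, t_hi)
    t_entry = np.nanmax(t_near, axis=1)
    t_entry = np.clip(t_entry, 0.0, None)
    return (1.0 - t_entry) * dist


def _rect_profile(offset: np.ndarray, width: float, sigma: float) -> np.ndarray:
    """Rectangle of ``width`` convolved with a Gaussian, evaluated at offset."""
    s = sigma * math.sqrt(2.0)
    return 0.5 * (erf((offset + width / 2.0) / s) - erf((offset - width / 2.0) / s))


class NodeInfluence:
    """Sparse dose-influence matrix (voxels x beamlets) for one node."""

    def __init__(self, node_index: int, matrix: sp.csc_matrix, bixels: BixelGrid,
                 truncation_fraction: float = TRUNCATION_FRACTION):
        self.node_index = node_index
        self.matrix = matrix
        self.bixels = bixels
        self.truncation_fraction = truncation_fraction

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_beamlets(self) -> int:
        return self.matrix.shape[1]

    @property
    def nbytes(self) -> int:
        m = self.matrix
        return m.data.nbytes + m.indices.nbytes + m.indptr.nbytes

    def dose(self, weights: np.ndarray) -> np.ndarray:
        w = np.asarray(weights, dtype=float).ravel()
        if w.size != self.n_beamlets:
            raise ValueError("weight vector length does not match beamlet count")
        return self.matrix @ w

    def backproject(self, voxel_grad: np.ndarray) -> np.ndarray:
        """Adjoint: gradient w.r.t. beamlet weights from a voxel gradient."""
        return self.matrix.T @ np.asarray(voxel_grad, dtype=float).ravel()


class _NodeCache:
    """Per-node voxel quantities shared by every beamlet of the node."""

    def __init__(self, geom: ControlPointGeometry, grid: VoxelGrid,
                 kernel: KernelConfig):
        src = geom.source_position
        pts = grid.voxel_centers()
        lo, hi = grid.bounds()
        v = pts - src
        self.dist = np.linalg.norm(v, axis=1)
        depth = _ray_entry_depth(src, pts, lo, hi)
        ex, ey = geom.bev_axes()
        # back-projected BEV coordinates at the SAD plane
        s_axis = v @ geom.direction_vec
        scale = SAD_MM / np.where(s_axis > 1e-6, s_axis, np.inf)
        self.X = (v @ ex) * scale
        self.Y = (v @ ey) * scale
        inv_sq = (SAD_MM / np.where(self.dist > 1e-6, self.dist, np.inf)) ** 2
        self.axial = kernel.depth_dose(depth) * inv_sq
        self.axial[depth <= 0] = 0.0


def compute_beamlet_column(
    geometry: ControlPointGeometry,
    bixel: int,
    phantom: Phantom,
    kernel: KernelConfig | None = None,
    bixels: BixelGrid | None = None,
    truncation_fraction: float = TRUNCATION_FRACTION,
    _cache: _NodeCache | None = None,
) -> sp.csc_matrix:
    """Sparse dose column (n_voxels x 1) for one beamlet of one node."""
    kernel = kernel or KernelConfig()
    bixels = bixels or BixelGrid.centered(MLCSpec())
    cache = _cache or _NodeCache(geometry, phantom.grid, kernel)
    xs, ys = bixels.bixel_centers()
    prof = (_rect_profile(cache.X - xs[bixel], bixels.col_width, kernel.sigma_penumbra)
            * _rect_profile(cache.Y - ys[bixel], bixels.row_height, kernel.sigma_penumbra))
    col = cache.axial * prof * kernel.calibration_factor(SAD_MM - 100.0)
    if truncation_fraction > 0 and col.max() > 0:
        col[col < truncation_fraction * col.max()] = 0.0
    return sp.csc_matrix(col.reshape(-1, 1))


def compute_node_influence(
    geometry: ControlPointGeometry,
    bixels: BixelGrid,
    phantom: Phantom,
    kernel: KernelConfig | None = None,
    truncation_fraction: float = TRUNCATION_FRACTION,
) -> NodeInfluence:
    """Influence matrix for all beamlets of one node."""
    kernel = kernel or KernelConfig()
    cache = _NodeCache(geometry, phantom.grid, kernel)
    xs, ys = bixels.bixel_centers()
    calib = kernel.calibration_factor(SAD_MM - 100.0)
    sigma = kernel.sigma_penumbra

    # lateral profiles are separable: precompute per unique row/column offset
    px = {x: _rect_profile(cache.X - x, bixels.col_width, sigma)
          for x in np.unique(xs)}
    py = {y: _rect_profile(cache.Y - y, bixels.row_height, sigma)
          for y in np.unique(ys)}

    cols = []
    for j in range(bixels.n_bixels):
        col = cache.axial * px[xs[j]] * py[ys[j]] * calib
        cmax = col.max()
        if truncation_fraction > 0 and cmax > 0:
            col[col < truncation_fraction * cmax] = 0.0
        cols.append(sp.csc_matrix(col.reshape(-1, 1)))
    matrix = sp.hstack(cols, format="csc")
    return NodeInfluence(geometry.index, matrix, bixels, truncation_fraction)


def assemble_influence(
    nodes: list[ControlPointGeometry],
    bixels: BixelGrid,
    phantom: Phantom,
    kernel: KernelConfig | None = None,
    truncation_fraction: float = TRUNCATION_FRACTION,
) -> dict[int, NodeInfluence]:
    """One influence matrix per trajectory node, keyed by node index."""
    if not nodes:
        raise ValueError("node list is empty")
    out = {}
    for g in nodes:
        out[g.index] = compute_node_influence(g, bixels, phantom, kernel,
                                              truncation_fraction)
    return out


def accumulate_dose(
    influence: dict[int, NodeInfluence],
    weights: dict[int, np.ndarray],
    grid: VoxelGrid,
) -> VoxelGrid:
    """Total dose grid D_i = sum over beams and beamlets of d_ij w_j."""
    total = np.zeros(int(np.prod(grid.dims)))
    for idx, w in weights.items():
        inf = influence[idx]
        w = np.asarray(w, dtype=float).ravel()
        if np.any(w < 0):
            raise ValueError("beamlet weights must be non-negative")
        total += inf.dose(w)
    return grid.like(total.reshape(grid.dims))
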