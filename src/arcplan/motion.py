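"""Effective fluence of moving apertures and direct aperture optimization.

With leaves moving at constant speed between control points, the
fluence a point x receives during one interval is the fraction of the
interval it spends inside the aperture.  For a leaf moving linearly
from p0 to p1, the fraction of time the leaf tip lies below x is a
clipped linear ramp in x (a step when the leaf is stationary), and the
point fluence is phi = Phi * (rampL(x) - rampR(x)), which reduces to
the single-leaf ramp forms when only one leaf sweeps the point.
Per-bixel values average the point fluence across the bixel, so a
static leaf tip halfway across a bixel exposes half the open-field
fluence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from arcplan.dose import BixelGrid, NodeInfluence
from arcplan.fluence import ObjectiveSpec, OptimizerState, objective, projected_lbfgs
from arcplan.machine import DeliveryConstraints, MLCSpec, apply_mlc_constraints
from arcplan.phantom import Structure, VoxelGrid
from arcplan.plans import Aperture, ControlPoint, Plan


@dataclass(frozen=True)
class LeafTransition:
    """One leaf pair's motion over one interval with open-field fluence Phi."""

    l_init: float
    l_fin: float
    r_init: float
    r_fin: float
    phi: float = 1.0

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise ValueError("interval fluence must be non-negative")
        if self.l_init > self.r_init + 1e-9 or self.l_fin > self.r_fin + 1e-9:
            raise ValueError("left tip must not pass the right tip")


def _ramp(x, p0: float, p1: float):
    """Fraction of the interval during which the linearly moving tip is
    below x; a step function when the tip is stationary."""
    lo, hi = (p0, p1) if p0 <= p1 else (p1, p0)
    x = np.asarray(x, dtype=float)
    if hi - lo < 1e-12:
        return (x > lo).astype(float)
    return np.clip((x - lo) / (hi - lo), 0.0, 1.0)


def effective_fluence(transition: LeafTransition, x) -> np.ndarray | float:
    """Point effective fluence phi(x) for one moving leaf pair."""
    t = transition
    val = t.phi * np.clip(_ramp(x, t.l_init, t.l_fin) - _ramp(x, t.r_init, t.r_fin),
                          0.0, 1.0)
    if np.isscalar(x):
        return float(val)
    return val


def _ramp_antideriv(x: np.ndarray, p0: float, p1: float) -> np.ndarray:
    """Antiderivative of the clipped ramp, for exact bixel averages."""
    lo, hi = (p0, p1) if p0 <= p1 else (p1, p0)
    x = np.asarray(x, dtype=float)
    if hi - lo < 1e-12:
        return np.maximum(x - lo, 0.0)
    out = np.zeros_like(x)
    mid = (x > lo) & (x < hi)
    out[mid] = (x[mid] - lo) ** 2 / (2.0 * (hi - lo))
    out[x >= hi] = x[x >= hi] - (lo + hi) / 2.0
    return out


def _mean_ramp(edges: np.ndarray, p0: float, p1: float) -> np.ndarray:
    """Bixel-averaged ramp over each [edges[i], edges[i+1]]."""
    I = _ramp_antideriv(edges, p0, p1)
    return np.diff(I) / np.diff(edges)


def pair_transition_profile(l0: float, l1: float, r0: float, r1: float,
                            edges: np.ndarray) -> np.ndarray:
    """Per-bixel unit-fluence profile (0..1) of one pair's transition."""
    prof = _mean_ramp(edges, l0, l1) - _mean_ramp(edges, r0, r1)
    return np.clip(prof, 0.0, 1.0)


def interval_fluence_map(prev: Aperture, next_: Aperture, mu: float,
                         bixels: BixelGrid) -> np.ndarray:
    """Effective fluence map (rows x cols) for one interval, Phi = mu."""
    if prev.n_pairs != next_.n_pairs:
        raise ValueError("leaf-pair count mismatch between interval apertures")
    if mu < 0:
        raise ValueError("interval MU must be non-negative")
    edges = bixels.col_edges()
    out = np.zeros(bixels.shape)
    for r, k in enumerate(bixels.pair_indices):
        closed_both = (prev.right[k] - prev.left[k] < 1e-12
                       and next_.right[k] - next_.left[k] < 1e-12)
        if closed_both:
            continue
        out[r] = mu * pair_transition_profile(
            prev.left[k], next_.left[k], prev.right[k], next_.right[k], edges)
    return out


def static_aperture_fluence(aperture: Aperture, mu: float,
                            bixels: BixelGrid) -> np.ndarray:
    """Partial-bixel fluence of a stationary aperture (exposed-fraction
    weighting at leaf tips)."""
    return interval_fluence_map(aperture, aperture, mu, bixels)


def plan_fluence_maps(plan: Plan, bixels: BixelGrid,
                      model: str = "discrete") -> dict[int, np.ndarray]:
    """Per-control-point fluence maps for a plan.

    ``discrete``: each control point contributes its aperture(s)
    statically.  ``effective``: the first control point is static and
    each later one carries the moving-aperture fluence of the interval
    ending at it, attributed to that control point's orientation.
    """
    if model not in ("discrete", "effective"):
        raise ValueError(f"unknown motion model {model!r}")
    maps: dict[int, np.ndarray] = {}
    cps = plan.control_points
    for n, cp in enumerate(cps):
        total = np.zeros(bixels.shape)
        if model == "discrete" or n == 0:
            for ap in cp.apertures:
                total += static_aperture_fluence(ap, ap.mu, bixels)
        elif model == "effective":
            if plan.mode != "dynamic_arc":
                raise ValueError("effective model applies to dynamic plans only")
            total += interval_fluence_map(cps[n - 1].apertures[0],
                                          cp.apertures[0], cp.mu, bixels)
        else:
            raise ValueError(f"unknown motion model {model!r}")
        maps[cp.geometry_index] = total
    return maps


def _renormalize(plan: Plan, dose_flat: np.ndarray,
                 ptv: Structure) -> tuple[Plan, float]:
    """Scale MU so PTV D95 equals the prescription."""
    d95 = float(np.percentile(dose_flat[ptv.mask.ravel()], 5.0))
    if d95 <= 0:
        return plan, 1.0
    factor = plan.prescription_gy / d95
    return plan.scaled_mu(factor), factor


class _DaoProblem:
    """Variable packing and dose evaluation for direct aperture optimization.

    Variables per control point: left/right tips of the bixel-grid leaf
    pairs plus the segment MU, all in one flat vector.  Constraint
    projection runs sequentially along the trajectory so the arc travel
    limit always refers to the already-projected predecessor.
    """

    def __init__(self, plan: Plan, influence: dict[int, NodeInfluence],
                 structures: dict[str, Structure], spec: ObjectiveSpec,
                 motion_model: str, constraints: DeliveryConstraints,
                 mlc: MLCSpec, bixels: BixelGrid):
        self.plan = plan
        self.influence = influence
        self.structures = structures
        self.spec = spec
        self.model = motion_model
        self.constraints = constraints
        self.mlc = mlc
        self.bixels = bixels
        self.pairs = list(bixels.pair_indices)
        self.np_grid = len(self.pairs)
        self.block = 2 * self.np_grid + 1
        self.n_cp = plan.n_control_points
        self.n_vox = influence[plan.control_points[0].geometry_index].n_voxels

    # ---- packing -------------------------------------------------------
    def pack(self, plan: Plan) -> np.ndarray:
        x = np.zeros(self.n_cp * self.block)
        for n, cp in enumerate(plan.control_points):
            ap = cp.apertures[0]
            o = n * self.block
            x[o:o + self.np_grid] = ap.left[self.pairs]
            x[o + self.np_grid:o + 2 * self.np_grid] = ap.right[self.pairs]
            x[o + 2 * self.np_grid] = ap.mu
        return x

    def unpack(self, x: np.ndarray) -> list[Aperture]:
        aps = []
        for n in range(self.n_cp):
            o = n * self.block
            left = np.zeros(self.mlc.n_leaf_pairs)
            right = np.zeros(self.mlc.n_leaf_pairs)
            left[self.pairs] = x[o:o + self.np_grid]
            right[self.pairs] = x[o + self.np_grid:o + 2 * self.np_grid]
            lo = np.minimum(left, right)  # raw steps may invert a pair
            hi = np.maximum(left, right)
            aps.append(Aperture(lo, hi, max(float(x[o + 2 * self.np_grid]), 0.0)))
        return aps

    def project(self, x: np.ndarray) -> np.ndarray:
        aps = self.unpack(x)
        mode = "arc" if self.plan.mode == "dynamic_arc" else "static"
        projected: list[Aperture] = []
        prev = None
        for ap in aps:
            pr = apply_mlc_constraints(ap, prev, self.constraints, mode=mode,
                                       mlc=self.mlc)
            pr.mu = min(max(ap.mu, self.constraints.min_mu_per_segment),
                        self.constraints.max_mu_per_segment)
            projected.append(pr)
            prev = pr
        return self.pack(self.to_plan(projected))

    def to_plan(self, aps: list[Aperture]) -> Plan:
        cps = [ControlPoint(cp.geometry_index, [ap])
               for cp, ap in zip(self.plan.control_points, aps)]
        p = self.plan
        return Plan(p.mode, cps, prescription_gy=p.prescription_gy,
                    scheme=p.scheme, seed=p.seed, meta=dict(p.meta))

    # ---- dose and objective -------------------------------------------
    def maps(self, aps: list[Aperture]) -> list[np.ndarray]:
        out = []
        for n, ap in enumerate(aps):
            if self.model == "effective" and n > 0:
                out.append(interval_fluence_map(aps[n - 1], ap, ap.mu, self.bixels))
            else:
                out.append(static_aperture_fluence(ap, ap.mu, self.bixels))
        return out

    def dose(self, maps: list[np.ndarray]) -> np.ndarray:
        d = np.zeros(self.n_vox)
        for cp, m in zip(self.plan.control_points, maps):
            d += self.influence[cp.geometry_index].dose(m.ravel())
        return d

    def value_and_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        aps = self.unpack(x)
        maps = self.maps(aps)
        dose = self.dose(maps)
        f, _, gd = objective(dose, self.structures, self.spec)

        # adjoint fluence gradients per control point
        gphi = [self.influence[cp.geometry_index].backproject(gd).reshape(self.bixels.shape)
                for cp in self.plan.control_points]

        grad = np.zeros_like(x)
        edges = self.bixels.col_edges()
        h = 1e-2  # mm, finite-difference step on the piecewise-linear profile
        for n, ap in enumerate(aps):
            o = n * self.block
            # MU gradient: only map n scales with mu_n (Phi = mu)
            if ap.mu > 0:
                grad[o + 2 * self.np_grid] = float(np.sum(gphi[n] * maps[n])) / ap.mu
            else:
                unit = self._unit_maps(aps, n)
                grad[o + 2 * self.np_grid] = float(np.sum(gphi[n] * unit[n]))
            # leaf gradients via central differences on the affected rows
            for r, k in enumerate(self.pairs):
                for side, oi in (("L", o + r), ("R", o + self.np_grid + r)):
                    g = 0.0
                    for m in self._affected(n):
                        g += self._row_fd(aps, n, m, k, r, side, h, edges, gphi[m])
                    grad[oi] = g
        return f, grad

    def _affected(self, n: int) -> list[int]:
        """Control points whose fluence map depends on aperture n."""
        if self.model != "effective":
            return [n]
        out = [n] if n > 0 or self.n_cp == 1 else [0]
        if n == 0 and self.n_cp > 1:
            out = [0, 1]
        elif n + 1 < self.n_cp:
            out.append(n + 1)
        return out

    def _unit_maps(self, aps: list[Aperture], n: int) -> dict[int, np.ndarray]:
        out = {}
        for m in self._affected(n):
            if self.model == "effective" and m > 0:
                out[m] = interval_fluence_map(aps[m - 1], aps[m], 1.0, self.bixels)
            else:
                out[m] = static_aperture_fluence(aps[m], 1.0, self.bixels)
        return out

    def _row_fd(self, aps, n, m, k, r, side, h, edges, gphi_m) -> float:
        """d(objective)/d(tip) through control point m's row r profile."""
        def row_profile(delta: float) -> np.ndarray:
            # mirror unpack(): an inverted pair is re-ordered, so the
            # profile matches the objective actually being minimized
            def tips(ap: Aperture, node: int):
                l, rt = ap.left[k], ap.right[k]
                if node == n:
                    if side == "L":
                        l = l + delta
                    else:
                        rt = rt + delta
                return min(l, rt), max(l, rt)
            if self.model == "effective" and m > 0:
                l0, r0 = tips(aps[m - 1], m - 1)
                l1, r1 = tips(aps[m], m)
            else:
                l0, r0 = tips(aps[m], m)
                l1, r1 = l0, r0
            if r0 - l0 < 1e-12 and r1 - l1 < 1e-12:
                return np.zeros(self.bixels.n_cols)
            return pair_transition_profile(l0, l1, r0, r1, edges)

        mu = aps[m].mu
        if mu == 0:
            return 0.0
        dprof = (row_profile(h) - row_profile(-h)) / (2.0 * h)
        return mu * float(gphi_m[r] @ dprof)


def optimize_apertures(
    plan: Plan,
    influence: dict[int, NodeInfluence],
    structures: dict[str, Structure],
    spec: ObjectiveSpec,
    motion_model: str = "effective",
    n_iter: int = 40,
    constraints: DeliveryConstraints | None = None,
    mlc: MLCSpec | None = None,
    bixels: BixelGrid | None = None,
    grid: VoxelGrid | None = None,
) -> tuple[Plan, OptimizerState, VoxelGrid | None]:
    """Direct aperture optimization of leaf positions and segment MU.

    Uses the shared projected L-BFGS driver with dose evaluated through
    the static partial-bixel fluence (``discrete``) or the moving
    aperture's effective fluence (``effective``).  MLC/arc constraints
    are applied at every iteration; the returned plan is renormalized so
    the PTV D95 equals the prescription.
    """
    if motion_model not in ("discrete", "effective"):
        raise ValueError(f"unknown motion model {motion_model!r}")
    constraints = constraints or DeliveryConstraints()
    mlc = mlc or MLCSpec()
    if bixels is None:
        raise ValueError("a bixel grid is required")

    prob = _DaoProblem(plan, influence, structures, spec, motion_model,
                       constraints, mlc, bixels)
    x0 = prob.project(prob.pack(plan))

    if n_iter == 0:
        aps = prob.unpack(x0)
        dose = prob.dose(prob.maps(aps))
        out, factor = _renormalize(prob.to_plan(aps), dose, structures["PTV"])
        dg = grid.like((dose * factor).reshape(grid.dims)) if grid is not None else None
        return out, OptimizerState(objective_trace=[]), dg

    x, state = projected_lbfgs(prob.value_and_grad, x0, n_iter=n_iter,
                               project=prob.project)
    aps = prob.unpack(prob.project(x))
    dose = prob.dose(prob.maps(aps))
    out, factor = _renormalize(prob.to_plan(aps), dose, structures["PTV"])
    dose_grid = None
    if grid is not None:
        dose_grid = grid.like((dose * factor).reshape(grid.dims))
    return out, state, dose_grid
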