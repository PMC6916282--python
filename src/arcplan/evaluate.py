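"""Plan evaluation: interpolated recalculation, DVH, conformity index,
delivery-time estimation and clinical-goal checks."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from arcplan.dose import BixelGrid, KernelConfig, NodeInfluence, compute_node_influence
from arcplan.machine import ControlPointGeometry, Trajectory
from arcplan.motion import plan_fluence_maps
from arcplan.phantom import Phantom, Structure, VoxelGrid
from arcplan.plans import Aperture, ControlPoint, Plan


# ---------------------------------------------------------------------------
# Interpolated recalculation
# ---------------------------------------------------------------------------

def _slerp(d0: np.ndarray, d1: np.ndarray, t: float) -> np.ndarray:
    dot = float(np.clip(d0 @ d1, -1.0, 1.0))
    omega = math.acos(dot)
    if omega < 1e-12:
        return d0.copy()
    return (math.sin((1 - t) * omega) * d0 + math.sin(t * omega) * d1) / math.sin(omega)


def _lerp_aperture(a: Aperture, b: Aperture, t: float, mu: float) -> Aperture:
    return Aperture((1 - t) * a.left + t * b.left,
                    (1 - t) * a.right + t * b.right, mu)


def plan_geometries(plan: Plan, trajectory: Trajectory | None = None
                    ) -> dict[int, ControlPointGeometry]:
    """Resolve the beam geometry of every control point of a plan.

    Demo plans carry their directions in ``meta``; otherwise a
    trajectory must be supplied.
    """
    if "geometries" in plan.meta:
        return plan.meta["geometries"]
    if "directions" in plan.meta:
        return {i: ControlPointGeometry(i, tuple(d))
                for i, d in enumerate(plan.meta["directions"])}
    if trajectory is None:
        raise ValueError("plan has no embedded geometry; pass a trajectory")
    return {cp.index: cp for cp in trajectory.control_points}


def interpolate_plan(
    plan: Plan,
    geometries: dict[int, ControlPointGeometry],
    n_nodes: int = 5,
    n_apertures: int = 20,
) -> Plan:
    """Expand a dynamic plan with interpolated nodes and apertures.

    Each original interval is replaced by ``n_nodes`` interpolated
    orientations (great-circle between the node directions); between
    consecutive interpolated nodes, ``n_apertures`` interpolated shapes
    are coalesced onto the following interpolated node.  The interval
    MU is divided equally among the n_nodes x n_apertures interpolated
    apertures.  The first original node keeps its own shape and MU.

    The result is a discrete plan whose geometries are embedded in
    ``meta['geometries']``.
    """
    if plan.mode != "dynamic_arc" or plan.n_control_points < 2:
        raise ValueError("interpolation needs a dynamic plan with >= 2 control points")
    if n_nodes < 1 or n_apertures < 1:
        raise ValueError("n_nodes and n_apertures must be at least 1")

    cps_in = plan.control_points
    new_geoms: dict[int, ControlPointGeometry] = {}
    new_cps: list[ControlPoint] = []

    def add_cp(direction: np.ndarray, apertures: list[Aperture]) -> None:
        gi = len(new_geoms)
        d = direction / np.linalg.norm(direction)
        new_geoms[gi] = ControlPointGeometry(gi, tuple(d))
        new_cps.append(ControlPoint(gi, apertures))

    first = cps_in[0]
    d_prev = geometries[first.geometry_index].direction_vec
    add_cp(d_prev, [a.copy() for a in first.apertures])

    per_interval = n_nodes * n_apertures
    for n in range(1, len(cps_in)):
        cp = cps_in[n]
        ap_prev = cps_in[n - 1].apertures[0]
        ap_next = cp.apertures[0]
        d_next = geometries[cp.geometry_index].direction_vec
        mu_each = cp.mu / per_interval
        for j in range(1, n_nodes + 1):
            d_j = _slerp(d_prev, d_next, j / n_nodes)
            aps = []
            for i in range(1, n_apertures + 1):
                t = ((j - 1) * n_apertures + i) / per_interval
                aps.append(_lerp_aperture(ap_prev, ap_next, t, mu_each))
            add_cp(d_j, aps)
        d_prev = d_next

    meta = dict(plan.meta)
    meta.pop("directions", None)
    meta["geometries"] = new_geoms
    meta["interpolated"] = {"n_nodes": n_nodes, "n_apertures": n_apertures}
    out = Plan("static", new_cps, prescription_gy=plan.prescription_gy,
               scheme=plan.scheme, seed=plan.seed, meta=meta)
    return out


# ---------------------------------------------------------------------------
# Dose of a plan
# ---------------------------------------------------------------------------

def compute_plan_dose(
    plan: Plan,
    phantom: Phantom,
    bixels: BixelGrid,
    geometries: dict[int, ControlPointGeometry] | None = None,
    trajectory: Trajectory | None = None,
    model: str = "discrete",
    kernel: KernelConfig | None = None,
    influence: dict[int, NodeInfluence] | None = None,
) -> VoxelGrid:
    """Dose grid of a plan under the requested motion model.

    Influence matrices are computed on demand for orientations missing
    from the optional cache.
    """
    geoms = geometries or plan_geometries(plan, trajectory)
    maps = plan_fluence_maps(plan, bixels, model=model)
    influence = influence if influence is not None else {}
    total = np.zeros(int(np.prod(phantom.grid.dims)))
    for gi, fmap in maps.items():
        if not fmap.any():
            continue
        if gi not in influence:
            influence[gi] = compute_node_influence(geoms[gi], bixels, phantom, kernel)
        total += influence[gi].dose(fmap.ravel())
    return phantom.grid.like(total.reshape(phantom.grid.dims))


# ---------------------------------------------------------------------------
# DVH
# ---------------------------------------------------------------------------

@dataclass
class DVHCurve:
    structure: str
    bin_edges: np.ndarray        # Gy, length n_bins + 1
    volume_fraction: np.ndarray  # cumulative V(>= left edge), length n_bins + 1

    def d_at_volume(self, fraction: float) -> float:
        """Dose received by at least ``fraction`` of the volume (e.g. 0.95 -> D95)."""
        v = self.volume_fraction
        e = self.bin_edges
        if fraction >= v[0]:
            return float(e[0])
        idx = np.nonzero(v >= fraction)[0]
        if idx.size == 0:
            return float(e[0])
        i = idx[-1]
        if i + 1 >= v.size or v[i + 1] == v[i]:
            return float(e[i])
        t = (fraction - v[i]) / (v[i + 1] - v[i])
        return float(e[i] + t * (e[i + 1] - e[i]))

    def v_at_dose(self, dose: float) -> float:
        """Volume fraction receiving at least ``dose``."""
        return float(np.interp(dose, self.bin_edges, self.volume_fraction))

    @property
    def d95(self) -> float:
        return self.d_at_volume(0.95)

    @property
    def dmax(self) -> float:
        nz = np.nonzero(self.volume_fraction > 0)[0]
        return float(self.bin_edges[nz[-1]]) if nz.size else 0.0


def dvh(dose: VoxelGrid, structure: Structure, bin_width: float = 0.05) -> DVHCurve:
    """Cumulative dose-volume histogram of a structure."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    d = dose.values[structure.mask].ravel()
    if d.size == 0:
        raise ValueError(f"structure {structure.name!r} is empty")
    top = max(float(d.max()), bin_width)
    n_bins = int(math.ceil(top / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(d, bins=edges)
    above = np.concatenate([[d.size], d.size - np.cumsum(counts)])
    return DVHCurve(structure.name, edges, above / d.size)


# ---------------------------------------------------------------------------
# Conformity index
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConformityResult:
    ptv_pres_cm3: float
    ptv_cm3: float
    v_pres_cm3: float
    ci: float


def conformity_index(dose: VoxelGrid, ptv: Structure,
                     prescription: float) -> ConformityResult:
    """CI = (PTV_pres / PTV) * (PTV_pres / V_pres) on voxel volumes."""
    if prescription <= 0:
        raise ValueError("prescription must be positive")
    vv = dose.voxel_volume_mm3 / 1000.0
    at_pres = dose.values >= prescription
    ptv_pres = float(np.count_nonzero(at_pres & ptv.mask)) * vv
    v_pres = float(np.count_nonzero(at_pres)) * vv
    ptv_vol = ptv.volume_cm3
    ci = 0.0 if v_pres == 0 else (ptv_pres / ptv_vol) * (ptv_pres / v_pres)
    return ConformityResult(ptv_pres, ptv_vol, v_pres, ci)


# ---------------------------------------------------------------------------
# Delivery time models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimeModelParams:
    dose_rate: float = 1000.0   # MU/min
    t_interval: float = 1.5     # s, dynamic per-interval robot traversal
    t_mlc: float = 3.5          # s, static per-segment MLC positioning
    t_robot: float = 1.5        # s, static per-node robot move

    def __post_init__(self) -> None:
        if min(self.dose_rate, self.t_interval, self.t_mlc, self.t_robot) <= 0:
            raise ValueError("time-model parameters must be positive")


def estimate_time_dynamic(plan: Plan, params: TimeModelParams | None = None
                          ) -> tuple[float, list[float]]:
    """Dynamic arc delivery time: per interval max(60 M / D, T_R), with M
    the MU at the interval's terminal node.  The move to the first node
    is counted as an interval as well."""
    params = params or TimeModelParams()
    if plan.mode != "dynamic_arc":
        raise ValueError("dynamic time model applies to dynamic_arc plans")
    per_interval = [max(60.0 * cp.mu / params.dose_rate, params.t_interval)
                    for cp in plan.control_points]
    return float(sum(per_interval)), per_interval


def estimate_time_static(plan: Plan, params: TimeModelParams | None = None
                         ) -> tuple[float, list[float]]:
    """Step-and-shoot delivery time: each delivered segment costs the MLC
    positioning time plus beam-on time; a visited node with no MU costs
    only the robot move."""
    params = params or TimeModelParams()
    per_node = []
    for cp in plan.control_points:
        live = [a for a in cp.apertures if a.mu > 0]
        if live:
            t = sum(params.t_mlc + 60.0 * a.mu / params.dose_rate for a in live)
        else:
            t = params.t_robot
        per_node.append(float(t))
    return float(sum(per_node)), per_node


# ---------------------------------------------------------------------------
# Clinical goals
# ---------------------------------------------------------------------------

@dataclass
class GoalResult:
    structure: str
    metric: str
    bound: float
    value: float | None
    passed: bool | None
    margin: float | None
    error: str | None = None


def check_goals(
    dvhs: dict[str, DVHCurve],
    goals: list[tuple[str, str, float]],
) -> list[GoalResult]:
    """Evaluate (structure, metric, bound) goals against DVH curves.

    Metrics: ``D<p>%`` (dose to p% of the volume, >= bound passes),
    ``V<d>Gy`` (volume fraction at d Gy, <= bound passes) and ``Dmax``
    (<= bound passes).
    """
    out: list[GoalResult] = []
    for structure, metric, bound in goals:
        if structure not in dvhs:
            out.append(GoalResult(structure, metric, bound, None, None, None,
                                  error=f"unknown structure {structure!r}"))
            continue
        curve = dvhs[structure]
        if metric.startswith("D") and metric.endswith("%"):
            frac = float(metric[1:-1]) / 100.0
            value = curve.d_at_volume(frac)
            margin = value - bound
            passed = margin >= 0
        elif metric.startswith("V") and metric.endswith("Gy"):
            value = curve.v_at_dose(float(metric[1:-2]))
            margin = bound - value
            passed = margin >= 0
        elif metric == "Dmax":
            value = curve.dmax
            margin = bound - value
            passed = margin >= 0
        else:
            out.append(GoalResult(structure, metric, bound, None, None, None,
                                  error=f"unknown metric {metric!r}"))
            continue
        out.append(GoalResult(structure, metric, bound, float(value), bool(passed),
                              float(margin)))
    return out


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    scheme: str
    prescription_gy: float
    ci: ConformityResult
    d95_gy: float
    total_mu: float
    delivery_time_s: float
    goal_results: list[GoalResult] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "prescription_gy": self.prescription_gy,
            "conformity_index": self.ci.ci,
            "ptv_d95_gy": self.d95_gy,
            "total_mu": self.total_mu,
            "delivery_time_s": self.delivery_time_s,
            "goals": [
                {
                    "structure": g.structure, "metric": g.metric, "bound": g.bound,
                    "value": g.value, "passed": g.passed, "margin": g.margin,
                    "error": g.error,
                }
                for g in self.goal_results
            ],
        }


def evaluate_plan(
    plan: Plan,
    dose: VoxelGrid,
    phantom: Phantom,
    goals: list[tuple[str, str, float]] | None = None,
    time_params: TimeModelParams | None = None,
) -> EvaluationReport:
    ptv = phantom.ptv
    curves = {name: dvh(dose, s) for name, s in phantom.structures.items()}
    ci = conformity_index(dose, ptv, plan.prescription_gy)
    if plan.mode == "dynamic_arc":
        t, _ = estimate_time_dynamic(plan, time_params)
    else:
        t, _ = estimate_time_static(plan, time_params)
    goal_results = check_goals(curves, goals or [])
    d95 = float(np.percentile(dose.values[ptv.mask], 5.0))
    return EvaluationReport(plan.scheme, plan.prescription_gy, ci, d95,
                            plan.total_mu, t, goal_results)
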