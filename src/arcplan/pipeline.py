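"""End-to-end planning workflow: fluence optimization, sequencing,
direct aperture optimization and optional interpolated recalculation."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from arcplan.dose import BixelGrid, KernelConfig, assemble_influence
from arcplan.evaluate import (
    TimeModelParams,
    compute_plan_dose,
    dvh,
    evaluate_plan,
    interpolate_plan,
    plan_geometries,
)
from arcplan.fluence import ObjectiveSpec, fluence_node_indices, optimize_fluence
from arcplan.io import load_config, write_dvh_csv, write_plan, write_volume
from arcplan.machine import DeliveryConstraints, MLCSpec, Trajectory, build_arc_trajectory, build_body_path
from arcplan.motion import optimize_apertures
from arcplan.phantom import Phantom, VoxelGrid, make_water_phantom, make_two_cp_demo
from arcplan.plans import ControlPoint, Plan
from arcplan.sequencing import arc_distribute, static_distribute

log = logging.getLogger("arcplan")

# Table 2 scheme taxonomy: optimization motion model and recalculation
# (interpolated nodes, interpolated apertures per node interval).
SCHEME_CONFIG = {
    "CKA1": ("discrete", None),
    "CKA2": ("discrete", (5, 1)),
    "CKA3": ("discrete", (5, 20)),
    "CKA4": ("effective", None),
    "CKA5": ("effective", (5, 20)),
}


def _smooth_map(fmap: np.ndarray, passes: int) -> np.ndarray:
    """Binomial smoothing along leaf travel.

    The limited aperture budget per fluence map cannot reproduce
    high-frequency structure, so maps are lightly smoothed before
    sequencing; the aperture optimizer then refines the shapes.
    """
    out = fmap.copy()
    for _ in range(passes):
        padded = np.pad(out, ((0, 0), (1, 1)), mode="edge")
        out = 0.25 * padded[:, :-2] + 0.5 * padded[:, 1:-1] + 0.25 * padded[:, 2:]
    return out


@dataclass
class PlanResult:
    plan: Plan
    dose_opt: VoxelGrid
    dose_recalc: VoxelGrid | None
    trajectory: Trajectory
    fluence_state: object
    dao_state: object


def run_arc_scheme(
    phantom: Phantom,
    trajectory: Trajectory,
    scheme: str,
    spec: ObjectiveSpec,
    bixels: BixelGrid,
    prescription_gy: float,
    kernel: KernelConfig | None = None,
    constraints: DeliveryConstraints | None = None,
    mlc: MLCSpec | None = None,
    fluence_iterations: int = 40,
    dao_iterations: int = 40,
    smoothing: int = 2,
    seed: int = 0,
) -> PlanResult:
    """Dynamic-arc planning for one CKA scheme."""
    if scheme not in SCHEME_CONFIG:
        raise ValueError(f"not an arc scheme: {scheme!r}")
    motion_model, recalc = SCHEME_CONFIG[scheme]
    kernel = kernel or KernelConfig()
    constraints = constraints or DeliveryConstraints()
    mlc = mlc or bixels.mlc

    t0 = time.time()
    influence = assemble_influence(trajectory.control_points, bixels, phantom, kernel)
    log.info("influence: %d nodes in %.1f s", trajectory.n_nodes, time.time() - t0)

    fl_nodes = fluence_node_indices(trajectory.n_nodes)
    fl_influence = {i: influence[i] for i in fl_nodes}
    weights, fl_state = optimize_fluence(fl_influence, phantom.structures, spec,
                                         n_iter=fluence_iterations, seed=seed)
    log.info("fluence optimization: F %.4g -> %.4g",
             fl_state.objective_trace[0], fl_state.objective_trace[-1])

    fmaps = {i: _smooth_map(w.reshape(bixels.shape), smoothing)
             for i, w in weights.items()}
    cps = arc_distribute(fmaps, trajectory.n_nodes, bixels, constraints)
    plan0 = Plan("dynamic_arc", cps, prescription_gy=prescription_gy,
                 scheme=scheme, seed=seed)

    plan, dao_state, dose_opt = optimize_apertures(
        plan0, influence, phantom.structures, spec, motion_model=motion_model,
        n_iter=dao_iterations, constraints=constraints, mlc=mlc, bixels=bixels,
        grid=phantom.grid)
    if dao_state.objective_trace:
        log.info("DAO (%s): F %.4g -> %.4g", motion_model,
                 dao_state.objective_trace[0], dao_state.objective_trace[-1])

    dose_recalc = None
    if recalc is not None:
        geoms = plan_geometries(plan, trajectory)
        rplan = interpolate_plan(plan, geoms, n_nodes=recalc[0], n_apertures=recalc[1])
        dose_recalc = compute_plan_dose(rplan, phantom, bixels, model="discrete",
                                        kernel=kernel)
        log.info("recalculation: %d interpolated control points",
                 rplan.n_control_points)
    return PlanResult(plan, dose_opt, dose_recalc, trajectory, fl_state, dao_state)


def run_static_scheme(
    phantom: Phantom,
    trajectory: Trajectory,
    spec: ObjectiveSpec,
    bixels: BixelGrid,
    prescription_gy: float,
    kernel: KernelConfig | None = None,
    constraints: DeliveryConstraints | None = None,
    mlc: MLCSpec | None = None,
    fluence_iterations: int = 40,
    dao_iterations: int = 40,
    max_apertures: int = 110,
    seed: int = 0,
) -> PlanResult:
    """Step-and-shoot planning over a static body path (CKSB)."""
    kernel = kernel or KernelConfig()
    constraints = constraints or DeliveryConstraints()
    mlc = mlc or bixels.mlc

    influence = assemble_influence(trajectory.control_points, bixels, phantom, kernel)
    weights, fl_state = optimize_fluence(influence, phantom.structures, spec,
                                         n_iter=fluence_iterations, seed=seed)
    fmaps = {i: w.reshape(bixels.shape) for i, w in weights.items()}
    cps = static_distribute(fmaps, bixels, max_total=max_apertures,
                            constraints=constraints)

    # flatten segments so the DAO sees one aperture per variable block
    flat_cps = [ControlPoint(cp.geometry_index, [ap])
                for cp in cps for ap in cp.apertures]
    if not flat_cps:
        raise RuntimeError("static sequencing produced no apertures")
    plan0 = Plan("static", flat_cps, prescription_gy=prescription_gy,
                 scheme="CKSB", seed=seed)
    plan_flat, dao_state, dose_opt = optimize_apertures(
        plan0, influence, phantom.structures, spec, motion_model="discrete",
        n_iter=dao_iterations, constraints=constraints, mlc=mlc, bixels=bixels,
        grid=phantom.grid)

    # regroup segments per node, keeping zero-segment nodes visible
    by_node: dict[int, list] = {cp.index: [] for cp in trajectory.control_points}
    for cp in plan_flat.control_points:
        by_node[cp.geometry_index].extend(cp.apertures)
    cps_out = [ControlPoint(i, aps) for i, aps in sorted(by_node.items())]
    plan = Plan("static", cps_out, prescription_gy=prescription_gy,
                scheme="CKSB", seed=seed)
    return PlanResult(plan, dose_opt, None, trajectory, fl_state, dao_state)


def run_demo(kind: str, phantom: Phantom, bixels: BixelGrid,
             kernel: KernelConfig | None = None,
             recalc: tuple[int, int] = (5, 20)) -> dict:
    """Two-control-point motion demonstrations.

    ``semicircle_pair``: discrete evaluation vs interpolated
    recalculation (uniform vs grossly non-uniform PTV dose).
    ``crescent_pair``: effective-fluence evaluation vs interpolated
    recalculation (nearly identical).
    """
    kernel = kernel or KernelConfig()
    plan = make_two_cp_demo(kind, mlc=bixels.mlc)
    geoms = plan_geometries(plan)
    model = "effective" if kind == "crescent_pair" else "discrete"
    dose_plan = compute_plan_dose(plan, phantom, bixels, geometries=geoms,
                                  model=model, kernel=kernel)
    rplan = interpolate_plan(plan, geoms, n_nodes=recalc[0], n_apertures=recalc[1])
    dose_recalc = compute_plan_dose(rplan, phantom, bixels, model="discrete",
                                    kernel=kernel)
    return {"plan": plan, "dose_plan": dose_plan, "dose_recalc": dose_recalc}


def _build_trajectory(cfg: dict) -> Trajectory:
    kind = cfg.get("kind", "arc")
    if kind == "arc":
        return build_arc_trajectory(
            n_arcs=cfg.get("n_arcs", 8),
            nodes_per_arc=cfg.get("nodes_per_arc"),
            spacing=cfg.get("spacing", 5.0),
        )
    if kind == "body_path":
        return build_body_path(cfg.get("n_nodes", 110))
    raise ValueError(f"unknown trajectory kind {kind!r}")


def run_pipeline(config_path) -> dict:
    """Run the full workflow from a YAML config; write artifacts to disk.

    Artifacts: plan JSON, optimizer (and, when the scheme recalculates,
    recalculated) dose NIfTI, DVH CSV, evaluation report JSON and a log
    file.  Fully reproducible from config plus seed.
    """
    cfg = load_config(config_path)
    out_dir = Path(cfg.get("output_dir", "arcplan_out"))
    out_dir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out_dir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    try:
        seed = int(cfg.get("seed", 0))
        scheme = cfg.get("scheme", "CKA4")
        presc = float(cfg.get("prescription_gy", 10.0))
        ph_cfg = cfg.get("phantom", {})
        stage = "phantom"
        phantom = make_water_phantom(
            width=ph_cfg.get("width", 300.0), length=ph_cfg.get("length", 300.0),
            height=ph_cfg.get("height", 200.0), spacing=ph_cfg.get("spacing", 5.0),
            ptv_diameter=ph_cfg.get("ptv_diameter", 60.0))

        mlc = MLCSpec()
        bx = cfg.get("bixels", {})
        bixels = BixelGrid.centered(mlc, half_span_x=bx.get("half_span_x", 40.0),
                                    half_span_y=bx.get("half_span_y", 40.0),
                                    col_width=bx.get("col_width", 5.0))
        spec = ObjectiveSpec.phantom_default(presc)
        stage = "trajectory"
        trajectory = _build_trajectory(cfg.get("trajectory", {}))

        stage = "optimization"
        common = dict(spec=spec, bixels=bixels, prescription_gy=presc,
                      fluence_iterations=int(cfg.get("fluence_iterations", 40)),
                      dao_iterations=int(cfg.get("dao_iterations", 40)), seed=seed)
        if scheme == "CKSB":
            result = run_static_scheme(phantom, trajectory,
                                       max_apertures=int(cfg.get("max_apertures", 110)),
                                       **common)
        else:
            result = run_arc_scheme(phantom, trajectory, scheme, **common)

        stage = "evaluation"
        dose_final = result.dose_recalc if result.dose_recalc is not None else result.dose_opt
        goals = [tuple(g) for g in cfg.get("goals", [])]
        report = evaluate_plan(result.plan, dose_final, phantom, goals=goals,
                               time_params=TimeModelParams())

        stage = "artifacts"
        write_plan(result.plan, out_dir / "plan.json")
        write_volume(result.dose_opt, out_dir / "dose_opt.nii.gz")
        if result.dose_recalc is not None:
            write_volume(result.dose_recalc, out_dir / "dose_recalc.nii.gz")
        curves = {n: dvh(dose_final, s) for n, s in phantom.structures.items()}
        write_dvh_csv(curves, out_dir / "dvh.csv")
        rep = report.to_dict()
        rep["seed"] = seed
        rep["config"] = {k: v for k, v in cfg.items() if k != "output_dir"}
        (out_dir / "report.json").write_text(json.dumps(rep, indent=1))
        log.info("pipeline complete: %s", out_dir)
        return {"result": result, "report": report, "output_dir": out_dir}
    except Exception as e:  # noqa: BLE001 - halt with stage name and cause
        log.error("stage %s failed: %s", stage, e)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
    finally:
        log.removeHandler(handler)
        handler.close()
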