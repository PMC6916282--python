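"""Quadratic DVH objective and projected L-BFGS fluence optimization."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from arcplan.dose import NodeInfluence
from arcplan.phantom import Structure


@dataclass(frozen=True)
class StructureObjective:
    """Dose bounds and importance weights for one structure.

    Penalty: a * sum(max(d_min - D, 0)^2) + b * sum(max(D - d_max, 0)^2)
    over the structure's voxels.  Targets use both terms; normal tissue
    uses only the max-dose term (a = 0).
    """

    name: str
    a: float = 0.0
    d_min: float = 0.0
    b: float = 0.0
    d_max: float = np.inf

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ValueError("importance factors must be non-negative")
        if self.a > 0 and self.b > 0 and self.d_min > self.d_max:
            raise ValueError("d_min must not exceed d_max")


@dataclass(frozen=True)
class ObjectiveSpec:
    terms: tuple[StructureObjective, ...]

    @classmethod
    def phantom_default(cls, prescription: float) -> "ObjectiveSpec":
        """Default phantom objective: PTV a=b=1, body max-dose b=0.1."""
        return cls((
            StructureObjective("PTV", a=1.0, d_min=prescription, b=1.0,
                               d_max=1.05 * prescription),
            StructureObjective("BODY", b=0.1, d_max=0.5 * prescription),
        ))


def objective(
    dose_flat: np.ndarray,
    structures: dict[str, Structure],
    spec: ObjectiveSpec,
) -> tuple[float, dict[str, float], np.ndarray]:
    """Objective value, per-structure terms and gradient w.r.t. voxel dose."""
    dose_flat = np.asarray(dose_flat, dtype=float).ravel()
    grad = np.zeros_like(dose_flat)
    per_structure: dict[str, float] = {}
    total = 0.0
    for t in spec.terms:
        if t.name not in structures:
            raise KeyError(f"objective references unknown structure {t.name!r}")
        idx = structures[t.name].mask.ravel()
        d = dose_flat[idx]
        f = 0.0
        g = np.zeros_like(d)
        if t.a > 0:
            under = np.maximum(t.d_min - d, 0.0)
            f += t.a * float(under @ under)
            g -= 2.0 * t.a * under
        if t.b > 0 and np.isfinite(t.d_max):
            over = np.maximum(d - t.d_max, 0.0)
            f += t.b * float(over @ over)
            g += 2.0 * t.b * over
        per_structure[t.name] = f
        total += f
        grad[idx] += g
    return total, per_structure, grad


@dataclass
class OptimizerState:
    """Trace of a projected L-BFGS run."""

    objective_trace: list[float] = field(default_factory=list)
    per_structure_trace: list[dict[str, float]] = field(default_factory=list)
    n_zero_steps: int = 0

    @property
    def n_iterations(self) -> int:
        return max(0, len(self.objective_trace) - 1)


def projected_lbfgs(
    fun: Callable[[np.ndarray], tuple[float, np.ndarray]],
    x0: np.ndarray,
    n_iter: int,
    project: Callable[[np.ndarray], np.ndarray] | None = None,
    history: int = 8,
    armijo_c: float = 1e-4,
    max_backtracks: int = 25,
    callback: Callable[[int, np.ndarray, float], None] | None = None,
) -> tuple[np.ndarray, OptimizerState]:
    """Projected low-memory quasi-Newton descent.

    ``fun`` returns (objective, gradient); ``project`` maps an iterate
    onto the feasible set (default: non-negativity clip).  Steps use the
    two-loop L-BFGS recursion with backtracking line search (Armijo on
    the projected point), so the accepted objective trace is
    non-increasing.  Curvature pairs with non-positive curvature after
    projection are discarded.
    """
    if project is None:
        project = lambda v: np.maximum(v, 0.0)
    x = project(np.asarray(x0, dtype=float).copy())
    f, g = fun(x)
    state = OptimizerState(objective_trace=[f])

    s_hist: list[np.ndarray] = []
    y_hist: list[np.ndarray] = []

    for it in range(n_iter):
        p = _two_loop_direction(g, s_hist, y_hist)
        gnorm = float(np.linalg.norm(g))
        if gnorm == 0.0:
            state.objective_trace.append(f)
            state.n_zero_steps += 1
            continue
        alpha = 1.0 / gnorm if not s_hist else 1.0
        accepted = False
        for _ in range(max_backtracks):
            x_new = project(x - alpha * p)
            f_new, g_new = fun(x_new)
            decrease = f - f_new
            step = x - x_new
            if decrease > armijo_c * float(g @ step) - 1e-15 and f_new <= f:
                accepted = True
                break
            alpha *= 0.5
        if accepted:
            s = x_new - x
            y = g_new - g
            sy = float(s @ y)
            if sy > 1e-12 * float(np.linalg.norm(s)) * float(np.linalg.norm(y) + 1e-300):
                s_hist.append(s)
                y_hist.append(y)
                if len(s_hist) > history:
                    s_hist.pop(0)
                    y_hist.pop(0)
            x, f, g = x_new, f_new, g_new
        else:
            # zero step: keep the iterate and drop stale curvature so the
            # next direction is a fresh steepest descent
            state.n_zero_steps += 1
            s_hist.clear()
            y_hist.clear()
        state.objective_trace.append(f)
        if callback is not None:
            callback(it, x, f)
    return x, state


def _two_loop_direction(g: np.ndarray, s_hist: list[np.ndarray],
                        y_hist: list[np.ndarray]) -> np.ndarray:
    """Two-loop recursion for the quasi-Newton direction (equals the
    steepest-descent direction when the history is empty)."""
    q = g.copy()
    if not s_hist:
        return q
    alphas = []
    rhos = [1.0 / float(y @ s) for s, y in zip(s_hist, y_hist)]
    for s, y, rho in zip(reversed(s_hist), reversed(y_hist), reversed(rhos)):
        a = rho * float(s @ q)
        alphas.append(a)
        q -= a * y
    s_last, y_last = s_hist[-1], y_hist[-1]
    gamma = float(s_last @ y_last) / float(y_last @ y_last)
    q *= gamma
    for (s, y, rho), a in zip(zip(s_hist, y_hist, rhos), reversed(alphas)):
        b = rho * float(y @ q)
        q += (a - b) * s
    return q


def fluence_node_indices(n_nodes: int, stride: int = 3) -> list[int]:
    """Arc-mode fluence nodes: every ``stride``-th node, offset so each
    fluence node has both neighbours inside the trajectory."""
    idx = list(range(1, n_nodes - 1, stride))
    if not idx:
        idx = [n_nodes // 2]
    return idx


def optimize_fluence(
    influence: dict[int, NodeInfluence],
    structures: dict[str, Structure],
    spec: ObjectiveSpec,
    n_iter: int = 40,
    seed: int = 0,
    init_scale: float | None = None,
) -> tuple[dict[int, np.ndarray], OptimizerState]:
    """Optimize non-negative beamlet weights at the given nodes.

    Weights are initialized uniformly inside the target's beam's-eye
    projection (beamlets whose column deposits dose in the PTV), zero
    elsewhere.  Deterministic given inputs and seed.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be at least 1")
    node_ids = sorted(influence)
    sizes = {i: influence[i].n_beamlets for i in node_ids}
    offsets = {}
    off = 0
    for i in node_ids:
        offsets[i] = off
        off += sizes[i]
    n_total = off

    ptv_rows = structures["PTV"].mask.ravel()
    x0 = np.zeros(n_total)
    for i in node_ids:
        m = influence[i].matrix
        in_target = np.asarray(
            (m[ptv_rows].sum(axis=0)).ravel() > 0
        ).ravel()
        x0[offsets[i]:offsets[i] + sizes[i]][in_target] = 1.0

    if init_scale is not None:
        x0 *= init_scale
    else:
        # scale so the initial mean PTV dose is near the first d_min target
        d0 = _total_dose(x0, influence, node_ids, offsets, sizes)
        mean_ptv = float(d0[ptv_rows].mean())
        targets = [t.d_min for t in spec.terms if t.a > 0]
        if targets and mean_ptv > 0:
            x0 *= targets[0] / mean_ptv

    def fun(w: np.ndarray) -> tuple[float, np.ndarray]:
        dose = _total_dose(w, influence, node_ids, offsets, sizes)
        f, _, gd = objective(dose, structures, spec)
        grad = np.empty_like(w)
        for i in node_ids:
            sl = slice(offsets[i], offsets[i] + sizes[i])
            grad[sl] = influence[i].backproject(gd)
        return f, grad

    w, state = projected_lbfgs(fun, x0, n_iter=n_iter)
    assert np.all(w >= 0)
    dose = _total_dose(w, influence, node_ids, offsets, sizes)
    _, per_s, _ = objective(dose, structures, spec)
    state.per_structure_trace.append(per_s)
    return {i: w[offsets[i]:offsets[i] + sizes[i]].copy() for i in node_ids}, state


def _total_dose(w, influence, node_ids, offsets, sizes) -> np.ndarray:
    dose = np.zeros(influence[node_ids[0]].n_voxels)
    for i in node_ids:
        dose += influence[i].dose(w[offsets[i]:offsets[i] + sizes[i]])
    return dose
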