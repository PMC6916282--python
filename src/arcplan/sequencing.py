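"""Reducing-level leaf sequencing and aperture distribution.

``xia_verhey`` decomposes a fluence map into MLC-deliverable segments:
at each step the delivery level is the largest power of two not
exceeding the residual maximum, the open region is the above-level
region rectified to one interval per leaf-pair row (longest run,
leftmost on ties), and the level is subtracted where open.

Arc plans sequence each 15-degree fluence node into three apertures and
redistribute two of them to the neighbouring 5-degree nodes; static
plans allocate a global aperture budget greedily across nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from arcplan.dose import BixelGrid
from arcplan.machine import DeliveryConstraints, apply_mlc_constraints
from arcplan.plans import Aperture, ControlPoint, Plan


@dataclass(frozen=True)
class Segment:
    """One sequenced segment in bixel-index space.

    ``intervals[r]`` is (col_start, col_stop) of the open run in row r
    (half-open), or None when the row is closed.  ``weight`` is the
    delivery level in fluence units.
    """

    intervals: tuple[tuple[int, int] | None, ...]
    weight: float

    def to_map(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape)
        for r, iv in enumerate(self.intervals):
            if iv is not None:
                out[r, iv[0]:iv[1]] = self.weight
        return out

    @property
    def n_open_bixels(self) -> int:
        return sum(iv[1] - iv[0] for iv in self.intervals if iv is not None)


def _longest_run(row_mask: np.ndarray) -> tuple[int, int] | None:
    """Longest True run (leftmost on ties), as a half-open interval."""
    best = None
    best_len = 0
    start = None
    for i, v in enumerate(row_mask.tolist() + [False]):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if i - start > best_len:
                best, best_len = (start, i), i - start
            start = None
    return best


def xia_verhey(fluence: np.ndarray, max_segments: int,
               tol: float = 1e-9) -> list[Segment]:
    """Reducing-level decomposition of a non-negative fluence map."""
    if max_segments < 1:
        raise ValueError("max_segments must be at least 1")
    fluence = np.asarray(fluence, dtype=float)
    if np.any(fluence < -tol):
        raise ValueError("fluence map must be non-negative")
    residual = np.maximum(fluence, 0.0).copy()
    segments: list[Segment] = []
    while len(segments) < max_segments:
        rmax = float(residual.max())
        if rmax <= tol:
            break
        level = 2.0 ** math.floor(math.log2(rmax))
        above = residual >= level - tol
        intervals = tuple(_longest_run(above[r]) for r in range(residual.shape[0]))
        if all(iv is None for iv in intervals):
            break
        # deliver the largest weight that leaves the open region intact:
        # the residual minimum over the rectified region (>= level), so a
        # uniform map is delivered in a single segment
        level = min(
            float(residual[r, iv[0]:iv[1]].min())
            for r, iv in enumerate(intervals) if iv is not None
        )
        seg = Segment(intervals, level)
        segments.append(seg)
        residual -= seg.to_map(residual.shape)
        np.maximum(residual, 0.0, out=residual)
    return segments


def reconstruct(segments: list[Segment], shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape)
    for s in segments:
        out += s.to_map(shape)
    return out


def segment_to_aperture(segment: Segment, bixels: BixelGrid,
                        mu: float) -> Aperture:
    """Convert a bixel-space segment to MLC leaf positions.

    Rows of the bixel grid map to MLC pairs via ``pair_indices``; pairs
    outside the grid are closed.
    """
    n = bixels.mlc.n_leaf_pairs
    left = np.zeros(n)
    right = np.zeros(n)
    edges = bixels.col_edges()
    for r, iv in enumerate(segment.intervals):
        if iv is None:
            continue
        k = bixels.pair_indices[r]
        left[k] = edges[iv[0]]
        right[k] = edges[iv[1]]
    return Aperture(left, right, mu)


def _leaf_travel(a: Aperture, b: Aperture) -> float:
    return float(np.abs(a.left - b.left).sum() + np.abs(a.right - b.right).sum())


def _deliverable(aperture: Aperture, constraints: DeliveryConstraints,
                 mlc) -> Aperture:
    """Project a sequenced aperture onto the static MLC rules so every
    emitted aperture is a fixed point of the constraint projection."""
    out = apply_mlc_constraints(aperture, None, constraints, mode="static", mlc=mlc)
    out.mu = aperture.mu
    return out


def arc_distribute(
    fluence_maps: dict[int, np.ndarray],
    n_nodes: int,
    bixels: BixelGrid,
    constraints: DeliveryConstraints | None = None,
) -> list[ControlPoint]:
    """Assign three sequenced apertures per fluence node to it and its
    two 5-degree neighbours; every trajectory node ends with exactly one
    aperture (closed, 0 MU if none was assigned).

    The middle-weight aperture stays at the fluence node; the other two
    go to the neighbours in the order that minimizes leaf travel across
    the triple.  Total MU is conserved.
    """
    constraints = constraints or DeliveryConstraints()
    cps = {i: ControlPoint(i, [Aperture.closed(bixels.mlc.n_leaf_pairs)])
           for i in range(n_nodes)}
    for node, fmap in sorted(fluence_maps.items()):
        if node - 1 < 0 or node + 1 >= n_nodes:
            raise ValueError("fluence node lacks a neighbour inside the trajectory")
        segs = xia_verhey(fmap, max_segments=3)
        if not segs:
            continue
        aps = [_deliverable(segment_to_aperture(s, bixels, mu=s.weight),
                            constraints, bixels.mlc) for s in segs]
        if len(aps) == 1:
            cps[node] = ControlPoint(node, [aps[0]])
        elif len(aps) == 2:
            order = sorted(range(2), key=lambda i: aps[i].mu)
            main = aps[order[-1]]
            other = aps[order[0]]
            t_prev = _leaf_travel(other, main)
            cps[node] = ControlPoint(node, [main])
            side = node - 1 if t_prev <= _leaf_travel(main, other) else node + 1
            cps[side] = ControlPoint(side, [other])
        else:
            order = sorted(range(3), key=lambda i: aps[i].mu)
            mid = aps[order[1]]
            lo, hi = aps[order[0]], aps[order[2]]
            c1 = _leaf_travel(lo, mid) + _leaf_travel(mid, hi)
            c2 = _leaf_travel(hi, mid) + _leaf_travel(mid, lo)
            first, last = (lo, hi) if c1 <= c2 else (hi, lo)
            cps[node - 1] = ControlPoint(node - 1, [first])
            cps[node] = ControlPoint(node, [mid])
            cps[node + 1] = ControlPoint(node + 1, [last])
    return [cps[i] for i in range(n_nodes)]


def static_distribute(
    fluence_maps: dict[int, np.ndarray],
    bixels: BixelGrid,
    max_total: int = 110,
    constraints: DeliveryConstraints | None = None,
) -> list[ControlPoint]:
    """Allocate a global aperture budget across static nodes.

    Each node's map is fully sequenced; segments are then picked
    greedily by residual-intensity reduction (level times open area)
    until the budget is exhausted.  Nodes may receive zero or several
    segments.
    """
    if max_total < 1:
        raise ValueError("max_total must be at least 1")
    constraints = constraints or DeliveryConstraints()
    per_node: dict[int, list[Segment]] = {}
    for node, fmap in fluence_maps.items():
        # a node can contribute at most the whole budget
        per_node[node] = xia_verhey(fmap, max_segments=max_total)

    candidates = []  # (reduction, node, position in node's sequence)
    for node, segs in per_node.items():
        for pos, s in enumerate(segs):
            candidates.append((s.weight * s.n_open_bixels, node, pos, s))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))

    chosen: dict[int, list[tuple[int, Segment]]] = {}
    taken: dict[int, int] = {}
    budget = max_total
    # respect each node's sequencing order: segment p requires p-1 first
    while budget > 0:
        picked = False
        for red, node, pos, s in candidates:
            if taken.get(node, 0) == pos:
                chosen.setdefault(node, []).append((pos, s))
                taken[node] = pos + 1
                budget -= 1
                picked = True
                break
        if not picked:
            break

    cps = []
    for node in sorted(fluence_maps):
        aps = [_deliverable(segment_to_aperture(s, bixels, mu=s.weight),
                            constraints, bixels.mlc)
               for _, s in sorted(chosen.get(node, []))]
        cps.append(ControlPoint(node, aps))
    return cps


def sequence_arc_plan(
    fluence_maps: dict[int, np.ndarray],
    n_nodes: int,
    bixels: BixelGrid,
    prescription_gy: float,
    scheme: str = "CKA4",
    seed: int = 0,
) -> Plan:
    cps = arc_distribute(fluence_maps, n_nodes, bixels)
    return Plan("dynamic_arc", cps, prescription_gy=prescription_gy,
                scheme=scheme, seed=seed)
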