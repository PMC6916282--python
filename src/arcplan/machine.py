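"""Machine model: MLC geometry, delivery constraints, beam trajectories.

Coordinate convention: right-handed room frame with +z vertical, the
target point at the origin and all sources at the nominal source-axis
distance (SAD).  Beam directions are unit vectors pointing from the
source toward the target; deliverable directions lie in the upper
hemisphere (source above the transverse plane), matching a supine
patient on a couch.

In the beam's-eye-view (BEV) frame, leaves travel along the local
x-axis and leaf pairs stack along the local y-axis; all leaf positions
are in millimetres at the SAD plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from arcplan.plans import Aperture

SAD_MM = 800.0


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class MLCSpec:
    """MLC geometry.  Leaves are paired, so a fluence row spans two leaves."""

    leaf_width: float = 3.85       # mm per single leaf, across travel
    n_leaf_pairs: int = 20
    # travel range chosen so the widest pair (2x range) can always be
    # closed within one 50 mm-per-leaf arc interval
    travel_range: float = 50.0     # mm, leaf tips within [-travel_range, +travel_range]

    def __post_init__(self) -> None:
        if self.n_leaf_pairs < 2:
            raise ValueError("need at least two leaf pairs")
        if self.travel_range <= 0 or self.leaf_width <= 0:
            raise ValueError("leaf_width and travel_range must be positive")

    @property
    def paired_leaf_width(self) -> float:
        """Height of one fluence row (two leaf widths)."""
        return 2.0 * self.leaf_width

    def pair_centers(self) -> np.ndarray:
        """BEV y-coordinates of paired-row centers, mm at the SAD plane."""
        w = self.paired_leaf_width
        return (np.arange(self.n_leaf_pairs) - (self.n_leaf_pairs - 1) / 2.0) * w

    def pair_edges(self) -> np.ndarray:
        w = self.paired_leaf_width
        return (np.arange(self.n_leaf_pairs + 1) - self.n_leaf_pairs / 2.0) * w


@dataclass(frozen=True)
class DeliveryConstraints:
    """MLC and arc motion constraints."""

    min_field_width: float = 7.6       # mm, minimum open-pair gap
    min_field_length: float = 7.7      # mm = two leaf pairs
    min_opposing_gap: float = 5.0      # mm, opposing leaf in adjacent pair
    max_robot_speed: float = 60.0      # mm/s
    interval_time: float = 1.5         # s, time to traverse one arc interval (T_R)
    max_mlc_speed: float = 33.0        # mm/s
    min_mu_per_segment: float = 0.0
    max_mu_per_segment: float = math.inf

    def __post_init__(self) -> None:
        for name in ("max_robot_speed", "interval_time", "max_mlc_speed"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def max_leaf_travel_per_interval(self) -> float:
        """Leaf travel allowed per arc interval, rounded to the nearest mm."""
        return float(_round_half_up(self.max_mlc_speed * self.interval_time))


@dataclass(frozen=True)
class ControlPointGeometry:
    """One beam orientation: source position and unit direction toward the target."""

    index: int
    direction: tuple[float, float, float]

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if not np.isclose(n, 1.0, atol=1e-9):
            raise ValueError("beam direction must be a unit vector")

    @property
    def direction_vec(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float)

    @property
    def source_position(self) -> np.ndarray:
        return -SAD_MM * self.direction_vec

    @property
    def polar_deg(self) -> float:
        """Angle of the beam from vertical (0 = pointing straight down)."""
        return math.degrees(math.acos(np.clip(-self.direction_vec[2], -1.0, 1.0)))

    @property
    def azimuth_deg(self) -> float:
        d = self.direction_vec
        return math.degrees(math.atan2(d[1], d[0])) % 360.0

    def bev_axes(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit BEV axes (ex = leaf travel, ey = pair stacking)."""
        d = self.direction_vec
        ref = np.array([1.0, 0.0, 0.0])
        if abs(d @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        ex = ref - (ref @ d) * d
        ex /= np.linalg.norm(ex)
        ey = np.cross(d, ex)
        return ex, ey


@dataclass
class Trajectory:
    mode: str  # "arc" | "body_path"
    control_points: list[ControlPointGeometry]
    angular_spacing: float | None = None  # degrees, arc mode
    arc_lengths: list[int] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.control_points)

    def directions(self) -> np.ndarray:
        return np.array([cp.direction for cp in self.control_points])

    def to_csv(self, path) -> None:
        rows = [
            (cp.index, cp.polar_deg, cp.azimuth_deg, *cp.source_position)
            for cp in self.control_points
        ]
        arr = np.array(rows)
        header = "index,polar_deg,azimuth_deg,source_x_mm,source_y_mm,source_z_mm"
        np.savetxt(path, arr, delimiter=",", header=header, comments="",
                   fmt=["%d"] + ["%.6f"] * 5)


def _rotate(v: np.ndarray, axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis."""
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return v * c + np.cross(axis, v) * s + axis * (axis @ v) * (1.0 - c)


DEFAULT_ARC_NODES = (13, 13, 13, 13, 13, 13, 13, 13)


def build_arc_trajectory(
    n_arcs: int = 8,
    nodes_per_arc: tuple[int, ...] | list[int] | None = None,
    spacing: float = 5.0,
) -> Trajectory:
    """Build the fixed arc trajectory.

    Each arc is a great-circle sweep through the zenith about a
    horizontal axis; arc k uses the axis at azimuth ``k * 180 / n_arcs``
    so the arcs tile the upper hemisphere of orientations.  Adjacent
    nodes within an arc are separated by exactly ``spacing`` degrees of
    beam direction.  The default fixture has eight arcs of 13 nodes
    (104 control points).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if nodes_per_arc is None:
        nodes_per_arc = DEFAULT_ARC_NODES[:n_arcs]
    if len(nodes_per_arc) != n_arcs:
        raise ValueError("nodes_per_arc length must equal n_arcs")
    if any(n < 1 for n in nodes_per_arc):
        raise ValueError("every arc needs at least one node")

    down = np.array([0.0, 0.0, -1.0])
    cps: list[ControlPointGeometry] = []
    idx = 0
    for k, n_nodes in enumerate(nodes_per_arc):
        span = (n_nodes - 1) * spacing
        if span >= 180.0:
            raise ValueError("arc span must stay below 180 degrees (upper hemisphere)")
        psi = math.radians(k * 180.0 / n_arcs)
        axis = np.array([math.cos(psi), math.sin(psi), 0.0])
        for i in range(n_nodes):
            g = -span / 2.0 + i * spacing
            d = _rotate(down, axis, g)
            d /= np.linalg.norm(d)
            cps.append(ControlPointGeometry(idx, tuple(d)))
            idx += 1
    return Trajectory("arc", cps, angular_spacing=spacing,
                      arc_lengths=list(nodes_per_arc))


def build_body_path(n_nodes: int = 110) -> Trajectory:
    """Quasi-uniform static node set over the upper hemisphere.

    Uses a Fibonacci lattice on the polar cap (beam polar angle up to
    80 degrees from vertical) with a posterior exclusion cone removed
    (no lateral-posterior beams through the couch).  Deterministic for
    a given ``n_nodes``.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be at least 1")
    if n_nodes == 1:
        return Trajectory("body_path", [ControlPointGeometry(0, (0.0, 0.0, -1.0))])

    polar_max = math.radians(80.0)
    golden = math.pi * (3.0 - math.sqrt(5.0))
    cap = 1.0 - math.cos(polar_max)

    m = n_nodes
    while True:
        # source polar angle theta (0 = zenith), azimuth phi
        i = np.arange(m)
        cos_t = 1.0 - cap * (i + 0.5) / m
        theta = np.arccos(np.clip(cos_t, -1.0, 1.0))
        phi = (i * golden) % (2.0 * math.pi)
        # posterior exclusion: low, rear source positions
        az_deg = np.degrees(phi)
        posterior = (np.abs(((az_deg - 180.0) + 180.0) % 360.0 - 180.0) < 30.0) & (
            np.degrees(theta) > 45.0
        )
        keep = ~posterior
        if keep.sum() >= n_nodes:
            theta, phi = theta[keep], phi[keep]
            break
        m += max(1, (n_nodes - int(keep.sum())))

    sel = np.linspace(0, theta.size - 1, n_nodes).round().astype(int)
    cps = []
    for j, s in enumerate(sel):
        t, p = float(theta[s]), float(phi[s])
        src = SAD_MM * np.array([math.sin(t) * math.cos(p),
                                 math.sin(t) * math.sin(p),
                                 math.cos(t)])
        d = -src / np.linalg.norm(src)
        cps.append(ControlPointGeometry(j, tuple(d)))
    return Trajectory("body_path", cps)


def _close_pair(left: np.ndarray, right: np.ndarray, k: int) -> None:
    mid = 0.5 * (left[k] + right[k])
    left[k] = right[k] = mid


def apply_mlc_constraints(
    aperture: Aperture,
    previous: Aperture | None,
    constraints: DeliveryConstraints,
    mode: str = "static",
    mlc: MLCSpec | None = None,
) -> Aperture:
    """Project an aperture onto the deliverable set.

    Rule order (fixed-point iterated): (1) close malformed pairs and
    widen undersized open pairs to the minimum field width, (2) the
    opposing-leaf rule (adjacent-pair gap in (0, min_opposing_gap)
    opened to the minimum; negative gap closes the pair), (3) minimum
    field length (an open pair needs an open neighbour, else it is
    closed), (4) in arc mode, leaf travel relative to ``previous``
    clipped to the per-interval limit.

    The result is idempotent: applying the projection twice equals
    applying it once.
    """
    mlc = mlc or MLCSpec()
    ap = aperture.copy()
    left, right = ap.left, ap.right
    n = left.size
    if previous is not None and previous.left.size != n:
        raise ValueError("previous aperture has a different number of leaf pairs")
    if np.any(left > right):
        raise ValueError("malformed aperture: left tip beyond right tip on an open pair")

    tr = mlc.travel_range
    np.clip(left, -tr, tr, out=left)
    np.clip(right, -tr, tr, out=right)

    limit = constraints.max_leaf_travel_per_interval

    def travel_ok(k: int) -> bool:
        if mode != "arc" or previous is None:
            return True
        return (abs(left[k] - previous.left[k]) <= limit + 1e-9
                and abs(right[k] - previous.right[k]) <= limit + 1e-9)

    def joint_park(k: int, at: float) -> float:
        """Park position reachable by both leaves of pair k from `previous`."""
        lo = max(previous.left[k] - limit, previous.right[k] - limit)
        hi = min(previous.left[k] + limit, previous.right[k] + limit)
        return float(np.clip(at, lo, hi)) if lo <= hi else 0.5 * (lo + hi)

    def clip_travel() -> None:
        if mode != "arc" or previous is None:
            return
        for k in range(n):
            if right[k] - left[k] <= 1e-12:
                left[k] = right[k] = joint_park(k, left[k])
                continue
            left[k] = float(np.clip(left[k], previous.left[k] - limit,
                                    previous.left[k] + limit))
            right[k] = float(np.clip(right[k], previous.right[k] - limit,
                                     previous.right[k] + limit))
            if left[k] > right[k] - 1e-12:  # clipping inverted the pair
                left[k] = right[k] = joint_park(k, 0.5 * (left[k] + right[k]))

    for _ in range(10):
        before = (left.copy(), right.copy())

        # (1) minimum field width
        open_ = right > left
        narrow = open_ & (right - left < constraints.min_field_width - 1e-9)
        for k in np.nonzero(narrow)[0]:
            mid = 0.5 * (left[k] + right[k])
            half = constraints.min_field_width / 2.0
            lo, hi = mid - half, mid + half
            if lo < -tr:
                lo, hi = -tr, -tr + constraints.min_field_width
            if hi > tr:
                lo, hi = tr - constraints.min_field_width, tr
            left[k], right[k] = lo, hi
            if not travel_ok(k):
                _close_pair(left, right, k)

        # (2) opposing-leaf rule between adjacent pairs
        gmin = constraints.min_opposing_gap
        for k in range(n - 1):
            for (li, ri) in ((k, k + 1), (k + 1, k)):
                if right[li] <= left[li] or right[ri] <= left[ri]:
                    continue  # a closed pair cannot interdigitate
                gap = right[ri] - left[li]
                if gap < 0:
                    _close_pair(left, right, li)
                elif gap < gmin - 1e-9:
                    newl = right[ri] - gmin  # retract the left leaf
                    if newl >= left[li] - 1e-12 or True:
                        left[li] = min(left[li], newl)
                    if left[li] < -tr or not travel_ok(li):
                        _close_pair(left, right, li)

        # (3) minimum field length: open pairs need an open neighbour
        open_ = right > left
        for k in np.nonzero(open_)[0]:
            lonely = not (
                (k > 0 and right[k - 1] > left[k - 1])
                or (k < n - 1 and right[k + 1] > left[k + 1])
            )
            if lonely:
                _close_pair(left, right, k)

        # (4) arc-mode travel clipping
        clip_travel()

        if np.array_equal(before[0], left) and np.array_equal(before[1], right):
            break
    else:
        # no fixed point reached: fall back to an all-closed aperture
        # (closed pairs satisfy every rule and survive travel clipping)
        for k in range(n):
            _close_pair(left, right, k)
        clip_travel()

    if mode == "arc" and previous is not None:
        assert np.all(np.abs(left - previous.left) <= limit + 1e-6)
        assert np.all(np.abs(right - previous.right) <= limit + 1e-6)

    return ap
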