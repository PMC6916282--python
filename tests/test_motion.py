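import numpy as np
import pytest

from arcplan.dose import BixelGrid
from arcplan.fluence import ObjectiveSpec, StructureObjective
from arcplan.machine import DeliveryConstraints, apply_mlc_constraints
from arcplan.motion import (
    LeafTransition,
    _DaoProblem,
    effective_fluence,
    interval_fluence_map,
    optimize_apertures,
    pair_transition_profile,
    plan_fluence_maps,
    static_aperture_fluence,
)
from arcplan.plans import Aperture, ControlPoint, Plan


def time_integration_oracle(tr: LeafTransition, x: float, n_steps: int = 200000):
    """Fraction of the interval x spends inside the moving aperture,
    integrated directly over time with linear leaf motion."""
    t = (np.arange(n_steps) + 0.5) / n_steps
    left = tr.l_init + t * (tr.l_fin - tr.l_init)
    right = tr.r_init + t * (tr.r_fin - tr.r_init)
    return tr.phi * np.mean((left < x) & (x < right))


class TestEffectiveFluence:
    def test_point_behind_sweep_start(self):
        tr = LeafTransition(0.0, 40.0, 50.0, 90.0, phi=1.0)
        assert effective_fluence(tr, 0.0) == 0.0

    def test_ramp_midpoint_half(self):
        tr = LeafTransition(0.0, 40.0, 100.0, 100.0, phi=2.0)
        assert effective_fluence(tr, 20.0) == pytest.approx(1.0)

    def test_overlapping_ramps_quarter(self):
        # both ramps active at x=25: 25/40 - 15/40 = 0.25
        tr = LeafTransition(0.0, 40.0, 10.0, 50.0, phi=1.0)
        assert effective_fluence(tr, 25.0) == pytest.approx(0.25)
        oracle = time_integration_oracle(tr, 25.0)
        assert effective_fluence(tr, 25.0) == pytest.approx(oracle, abs=1e-4)

    def test_stationary_aperture_full_fluence(self):
        tr = LeafTransition(-10.0, -10.0, 10.0, 10.0, phi=3.0)
        assert effective_fluence(tr, 0.0) == pytest.approx(3.0)
        assert effective_fluence(tr, 11.0) == 0.0

    def test_matches_time_integration_randomized(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            l0, l1 = np.sort(rng.uniform(-40, 0, 2))
            r0 = rng.uniform(l0 + 1, 40)
            r1 = rng.uniform(l1 + 1, 50)
            tr = LeafTransition(l0, l1, r0, r1, phi=float(rng.uniform(0.1, 5)))
            x = float(rng.uniform(-45, 55))
            assert effective_fluence(tr, x) == pytest.approx(
                time_integration_oracle(tr, x), abs=2e-4 * tr.phi)

    def test_bounds_randomized_10k(self):
        rng = np.random.default_rng(1)
        n = 10_000
        l0 = rng.uniform(-50, 40, n)
        l1 = rng.uniform(-50, 40, n)
        r0 = l0 + rng.uniform(0, 30, n)
        r1 = l1 + rng.uniform(0, 30, n)
        phi = rng.uniform(0, 10, n)
        x = rng.uniform(-60, 80, n)
        for i in range(n):
            tr = LeafTransition(l0[i], l1[i], r0[i], r1[i], phi=phi[i])
            v = effective_fluence(tr, x[i])
            assert 0.0 <= v <= phi[i] + 1e-12

    def test_reduces_to_left_ramp_when_right_inactive(self):
        # right leaf never reaches the probed region: combined form equals
        # the single left-leaf ramp exactly
        for x in np.linspace(-5, 45, 101):
            tr = LeafTransition(0.0, 40.0, 60.0, 95.0, phi=2.0)
            expected = 2.0 * np.clip((x - 0.0) / 40.0, 0.0, 1.0)
            assert effective_fluence(tr, x) == pytest.approx(expected, abs=1e-12)

    def test_reduces_to_right_ramp_when_left_inactive(self):
        for x in np.linspace(5, 55, 101):
            tr = LeafTransition(-60.0, -50.0, 10.0, 50.0, phi=1.5)
            expected = 1.5 * (1.0 - np.clip((x - 10.0) / 40.0, 0.0, 1.0))
            assert effective_fluence(tr, x) == pytest.approx(expected, abs=1e-12)

    def test_negative_phi_rejected(self):
        with pytest.raises(ValueError):
            LeafTransition(0, 1, 2, 3, phi=-1.0)

    def test_inverted_pair_rejected(self):
        with pytest.raises(ValueError):
            LeafTransition(5.0, 0.0, 1.0, 10.0)


def open_aperture(mlc, pairs, left, right, mu=10.0):
    l = np.zeros(mlc.n_leaf_pairs)
    r = np.zeros(mlc.n_leaf_pairs)
    for k in pairs:
        l[k], r[k] = left, right
    return Aperture(l, r, mu)


class TestStaticApertureFluence:
    def test_tip_halfway_across_bixel(self, mlc):
        bx = BixelGrid.centered(mlc)
        # left tip at the center of the column spanning [-40, -35]
        ap = open_aperture(mlc, [9, 10], -37.5, 40.0)
        fmap = static_aperture_fluence(ap, 2.0, bx)
        r = bx.pair_indices.index(9)
        assert fmap[r, 0] == pytest.approx(1.0)  # half of 2.0

    def test_covered_and_exposed_bixels(self, mlc):
        bx = BixelGrid.centered(mlc)
        ap = open_aperture(mlc, [9, 10], -20.0, 20.0)
        fmap = static_aperture_fluence(ap, 3.0, bx)
        r = bx.pair_indices.index(9)
        cols = bx.col_centers()
        assert np.all(fmap[r, (cols > -20) & (cols < 20)] == pytest.approx(3.0))
        assert np.all(fmap[r, cols < -22.5] == 0.0)

    def test_closed_pair_zero(self, mlc):
        bx = BixelGrid.centered(mlc)
        fmap = static_aperture_fluence(Aperture.closed(mlc.n_leaf_pairs), 5.0, bx)
        assert np.all(fmap == 0)


class TestIntervalFluenceMap:
    def test_static_limit(self, mlc):
        bx = BixelGrid.centered(mlc)
        ap = open_aperture(mlc, [8, 9, 10], -17.0, 23.0)
        np.testing.assert_allclose(interval_fluence_map(ap, ap, 4.0, bx),
                                   static_aperture_fluence(ap, 4.0, bx))

    def test_closed_endpoints_zero(self, mlc):
        bx = BixelGrid.centered(mlc)
        closed = Aperture.closed(mlc.n_leaf_pairs)
        assert np.all(interval_fluence_map(closed, closed, 100.0, bx) == 0)

    def test_pair_count_mismatch(self, mlc):
        bx = BixelGrid.centered(mlc)
        with pytest.raises(ValueError):
            interval_fluence_map(Aperture.closed(5), Aperture.closed(6), 1.0, bx)

    def test_semicircle_interval_vs_dense_interpolation(self, mlc):
        from arcplan.phantom import make_two_cp_demo

        bx = BixelGrid.centered(mlc)
        plan = make_two_cp_demo("semicircle_pair", mlc=mlc)
        a, b = (cp.apertures[0] for cp in plan.control_points)
        phi = 1.0
        fmap = interval_fluence_map(a, b, phi, bx)
        oracle = _dense_oracle(a, b, phi, bx, k=100)
        assert np.abs(fmap - oracle).max() <= 0.01 * phi

    def test_oracle_convergence_is_order_one_over_k(self, mlc):
        bx = BixelGrid.centered(mlc)
        a = open_aperture(mlc, [8, 9, 10, 11], -30.0, -5.0)
        b = open_aperture(mlc, [8, 9, 10, 11], 5.0, 30.0)
        fmap = interval_fluence_map(a, b, 1.0, bx)
        errs = [np.abs(_dense_oracle(a, b, 1.0, bx, k) - fmap).max()
                for k in (10, 20, 40)]
        # first-order convergence: errors decrease monotonically with K
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < errs[0] / 2


def _dense_oracle(a, b, phi, bx, k):
    """Average static fluence of k linearly interpolated apertures."""
    total = np.zeros(bx.shape)
    for i in range(k):
        t = (i + 0.5) / k
        ap = Aperture((1 - t) * a.left + t * b.left,
                      (1 - t) * a.right + t * b.right, 0.0)
        total += static_aperture_fluence(ap, phi, bx)
    return total / k


class TestPlanFluenceMaps:
    def test_discrete_sums_segments(self, mlc):
        bx = BixelGrid.centered(mlc)
        ap = open_aperture(mlc, [9, 10], -10.0, 10.0, mu=5.0)
        plan = Plan("static", [ControlPoint(0, [ap, ap.copy()])],
                    scheme="CKSB")
        maps = plan_fluence_maps(plan, bx, "discrete")
        np.testing.assert_allclose(maps[0],
                                   2 * static_aperture_fluence(ap, 5.0, bx))

    def test_effective_first_cp_static(self, mlc):
        bx = BixelGrid.centered(mlc)
        a = open_aperture(mlc, [9, 10], -20.0, 0.0, mu=7.0)
        b = open_aperture(mlc, [9, 10], 0.0, 20.0, mu=9.0)
        plan = Plan("dynamic_arc", [ControlPoint(0, [a]), ControlPoint(1, [b])],
                    scheme="CKA4")
        maps = plan_fluence_maps(plan, bx, "effective")
        np.testing.assert_allclose(maps[0], static_aperture_fluence(a, 7.0, bx))
        np.testing.assert_allclose(maps[1], interval_fluence_map(a, b, 9.0, bx))

    def test_unknown_model(self, mlc):
        bx = BixelGrid.centered(mlc)
        plan = Plan("static", [], scheme="CKSB")
        with pytest.raises(ValueError):
            plan_fluence_maps(plan, bx, "teleport")


@pytest.fixture(scope="module")
def dao_setup(small_arc, small_influence, coarse_phantom, bixels, mlc):
    spec = ObjectiveSpec((
        StructureObjective("PTV", a=1, d_min=10.0, b=1, d_max=10.5),
        StructureObjective("BODY", b=0.1, d_max=5.0),
    ))
    # open pairs span the PTV in y so renormalization has a positive D95
    ap = open_aperture(mlc, list(range(5, 15)), -32.0, 32.0, mu=300.0)
    cps = [ControlPoint(i, [ap.copy()]) for i in range(3)]
    plan = Plan("dynamic_arc", cps, prescription_gy=10.0, scheme="CKA4")
    return plan, small_influence, coarse_phantom, spec


class TestDAO:
    def test_zero_iterations_renormalizes_only(self, dao_setup, bixels, mlc,
                                               constraints):
        plan, inf, ph, spec = dao_setup
        out, state, dose = optimize_apertures(
            plan, inf, ph.structures, spec, "discrete", n_iter=0,
            constraints=constraints, mlc=mlc, bixels=bixels, grid=ph.grid)
        assert state.objective_trace == []
        # shapes unchanged, MU scaled by one global factor
        for cp_in, cp_out in zip(plan.control_points, out.control_points):
            np.testing.assert_allclose(cp_out.apertures[0].left,
                                       cp_in.apertures[0].left)
        d95 = np.percentile(dose.values[ph.ptv.mask], 5)
        assert d95 == pytest.approx(10.0, rel=1e-6)

    @pytest.mark.parametrize("model", ["discrete", "effective"])
    def test_objective_non_increasing(self, dao_setup, bixels, mlc, constraints,
                                      model):
        plan, inf, ph, spec = dao_setup
        _, state, _ = optimize_apertures(
            plan, inf, ph.structures, spec, model, n_iter=8,
            constraints=constraints, mlc=mlc, bixels=bixels, grid=ph.grid)
        tr = state.objective_trace
        assert len(tr) == 9
        assert all(t1 <= t0 + 1e-9 for t0, t1 in zip(tr, tr[1:]))

    @pytest.mark.parametrize("model", ["discrete", "effective"])
    def test_gradient_matches_finite_differences(self, dao_setup, bixels, mlc,
                                                 constraints, model):
        plan, inf, ph, spec = dao_setup
        prob = _DaoProblem(plan, inf, ph.structures, spec, model, constraints,
                           mlc, bixels)
        x = prob.pack(plan)
        f, g = prob.value_and_grad(x)
        rng = np.random.default_rng(4)
        for i in rng.choice(x.size, 20, replace=False):
            h = 1e-2 if (i % prob.block) == prob.block - 1 else 1e-3
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            fd = (prob.value_and_grad(xp)[0] - prob.value_and_grad(xm)[0]) / (2 * h)
            assert abs(fd - g[i]) <= 1e-3 * (abs(fd) + abs(g[i])) + 1e-9

    def test_projection_produces_valid_apertures(self, dao_setup, bixels, mlc,
                                                 constraints):
        plan, inf, ph, spec = dao_setup
        prob = _DaoProblem(plan, inf, ph.structures, spec, "effective",
                           constraints, mlc, bixels)
        rng = np.random.default_rng(12)
        limit = constraints.max_leaf_travel_per_interval
        for _ in range(50):
            x = rng.uniform(-60, 60, prob.n_cp * prob.block)
            aps = prob.unpack(prob.project(x))
            prev = None
            for ap in aps:
                again = apply_mlc_constraints(ap, prev, constraints, "arc", mlc)
                np.testing.assert_allclose(again.left, ap.left, atol=1e-9)
                np.testing.assert_allclose(again.right, ap.right, atol=1e-9)
                if prev is not None:
                    assert np.all(np.abs(ap.left - prev.left) <= limit + 1e-6)
                    assert np.all(np.abs(ap.right - prev.right) <= limit + 1e-6)
                prev = ap

    def test_every_dao_iterate_satisfies_constraints(self, dao_setup, bixels,
                                                     mlc, constraints,
                                                     monkeypatch):
        plan, inf, ph, spec = dao_setup
        seen = []
        orig = _DaoProblem.value_and_grad

        def spy(self, x):
            seen.append(self.unpack(x))
            return orig(self, x)

        monkeypatch.setattr(_DaoProblem, "value_and_grad", spy)
        optimize_apertures(plan, inf, ph.structures, spec, "effective", n_iter=5,
                           constraints=constraints, mlc=mlc, bixels=bixels,
                           grid=ph.grid)
        assert seen
        limit = constraints.max_leaf_travel_per_interval
        for aps in seen:
            prev = None
            for ap in aps:
                if prev is not None:
                    assert np.all(np.abs(ap.left - prev.left) <= limit + 1e-6)
                    assert np.all(np.abs(ap.right - prev.right) <= limit + 1e-6)
                prev = ap

    def test_unknown_model_rejected(self, dao_setup, bixels, mlc, constraints):
        plan, inf, ph, spec = dao_setup
        with pytest.raises(ValueError):
            optimize_apertures(plan, inf, ph.structures, spec, "warp",
                               constraints=constraints, mlc=mlc, bixels=bixels)
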