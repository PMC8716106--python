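"""PBD solver: projections against analytic oracles, convergence, plasticity."""

import math

import numpy as np
import pytest

from rootsim import pbd
from rootsim.cell_complex import CellComplex
from rootsim.errors import GeometryError
from rootsim.params import MechanicsParams

from conftest import make_rect_cell, make_two_cell_mesh


def simple_state(points, inv_mass=None, iterations=1, dt=1.0):
    pos = np.asarray(points, dtype=float)
    w = np.ones(len(pos)) if inv_mass is None else np.asarray(inv_mass, float)
    return pbd.PbdState(pos=pos, prev=pos.copy(), vel=np.zeros_like(pos),
                        inv_mass=w, iterations=iterations, dt=dt)


class TestEffectiveStiffness:
    @pytest.mark.parametrize("k,n,expected", [
        (1.0, 1, 1.0), (1.0, 7, 1.0),
        (0.0, 1, 0.0), (0.0, 9, 0.0),
        (0.75, 2, 0.5),                 # 1 - 0.25^(1/2)
    ])
    def test_values(self, k, n, expected):
        assert pbd.effective_stiffness(k, n) == pytest.approx(expected)

    def test_monotone_in_k_and_n(self):
        ks = np.linspace(0, 1, 11)
        vals = [pbd.effective_stiffness(k, 4) for k in ks]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        ns = [1, 2, 4, 8, 16]
        vals = [pbd.effective_stiffness(0.6, n) for n in ns]
        assert all(b <= a for a, b in zip(vals, vals[1:]))

    def test_repeated_projection_approximates_single_pass(self):
        # n corrected projections should move the pair like one pass at k
        k = 0.6
        for n in (2, 5, 10):
            state = simple_state([[0.0, 0.0], [2.0, 0.0]], iterations=n)
            c = pbd.DistanceConstraint(0, 1, rest=1.0, k_ext=k, k_comp=k)
            for _ in range(n):
                pbd.project_distance(c, state, n_iter=n)
            gap = np.linalg.norm(state.pos[0] - state.pos[1])
            single = simple_state([[0.0, 0.0], [2.0, 0.0]])
            pbd.project_distance(pbd.DistanceConstraint(0, 1, 1.0, k, k),
                                 single, n_iter=1)
            gap1 = np.linalg.norm(single.pos[0] - single.pos[1])
            assert gap == pytest.approx(gap1, rel=0.05)


class TestDistanceProjection:
    def test_symmetric_projection_halves_violation(self):
        state = simple_state([[0.0, 0.0], [2.0, 0.0]])
        pbd.project_distance(pbd.DistanceConstraint(0, 1, rest=1.0), state)
        assert state.pos[0] == pytest.approx([0.5, 0.0])
        assert state.pos[1] == pytest.approx([1.5, 0.0])

    def test_at_rest_no_correction(self):
        state = simple_state([[0.0, 0.0], [1.0, 0.0]])
        corr = pbd.project_distance(pbd.DistanceConstraint(0, 1, rest=1.0), state)
        assert np.allclose(corr, 0)

    def test_pinned_vertex_absorbs_nothing(self):
        state = simple_state([[0.0, 0.0], [2.0, 0.0]], inv_mass=[0.0, 1.0])
        pbd.project_distance(pbd.DistanceConstraint(0, 1, rest=1.0), state)
        assert state.pos[0] == pytest.approx([0.0, 0.0])
        assert state.pos[1] == pytest.approx([1.0, 0.0])

    def test_unequal_masses_split_corrections(self):
        # masses 1 and 3 -> inverse masses 1 and 1/3 -> corrections 3:1
        state = simple_state([[0.0, 0.0], [1.4, 0.0]],
                             inv_mass=[1.0, 1.0 / 3.0])
        pbd.project_distance(pbd.DistanceConstraint(0, 1, rest=1.0), state)
        d1 = abs(state.pos[0, 0] - 0.0)
        d2 = abs(state.pos[1, 0] - 1.4)
        assert d1 == pytest.approx(3 * d2)
        assert d1 + d2 == pytest.approx(0.4)

    def test_coincident_points_skipped(self):
        state = simple_state([[1.0, 1.0], [1.0, 1.0]])
        corr = pbd.project_distance(pbd.DistanceConstraint(0, 1, rest=1.0), state)
        assert np.allclose(corr, 0)


class TestStepAndConvergence:
    def test_no_forces_no_constraints_identity(self):
        state = simple_state([[0.0, 0.0], [3.0, 4.0]], iterations=5)
        before = state.pos.copy()
        pbd.pbd_step(state, pbd.ConstraintSet(), dt=0.1)
        assert np.array_equal(state.pos, before)

    def test_spring_network_residual_non_increasing(self):
        # well-posed network: a spanning chain plus cross links, rest lengths
        # perturbed around the current geometry
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 5, size=(10, 2))
        cs = pbd.ConstraintSet()
        edges = [(i, i + 1) for i in range(9)] + [(0, 5), (2, 7), (4, 9)]
        for i, j in edges:
            d = float(np.linalg.norm(pts[i] - pts[j]))
            cs.distance.append(pbd.DistanceConstraint(
                i, j, rest=d * float(rng.uniform(0.85, 1.15))))
        state = simple_state(pts, iterations=1)
        residuals = [cs.residual(state)]
        for _ in range(50):
            pbd.pbd_step(state, cs, dt=1.0)
            residuals.append(cs.residual(state))
        for a, b in zip(residuals, residuals[1:]):
            assert b <= a + 1e-9
        assert residuals[-1] < 0.05 * residuals[0]

    def test_fixed_point_residual_small_on_three_cell_mesh(self):
        cx = CellComplex()
        vs = cx.add_vertices([[0, 0], [1, 0], [2, 0], [3, 0],
                              [3, 1], [2, 1], [1, 1], [0, 1]])
        cx.new_cell("Vascular", [vs[0], vs[1], vs[6], vs[7]])
        cx.new_cell("Vascular", [vs[1], vs[2], vs[5], vs[6]])
        cx.new_cell("Vascular", [vs[2], vs[3], vs[4], vs[5]])
        cx.rebuild_walls(preserve=False)
        cx.add_centers()
        mech = MechanicsParams(iterations=50, k_internal=1.0, k_shape=1.0,
                               k_bending=1.0)
        cs = pbd.build_constraints(cx, mech)
        state = pbd.PbdState.from_complex(cx, iterations=50, dt=1.0)
        for _ in range(20):
            pbd.pbd_step(state, cs, dt=1.0)
        assert cs.residual(state) <= 1e-6

    def test_pinned_vertices_never_move(self):
        cx, _, _ = make_two_cell_mesh()
        mech = MechanicsParams(iterations=6)
        cs = pbd.build_constraints(cx, mech)
        pbd.set_pressure_targets(cs, cx, 0.02, 0.5)
        pinned = [0, 5]
        state = pbd.PbdState.from_complex(cx, pinned=pinned,
                                          iterations=6, dt=0.02)
        before = cx.vertices[pinned].copy()
        for _ in range(30):
            pbd.set_pressure_targets(cs, cx, 0.02, 0.5)
            pbd.pbd_step(state, cs, dt=0.02)
        assert np.array_equal(cx.vertices[pinned], before)

    def test_fast_path_matches_reference(self):
        cxa, _, _ = make_two_cell_mesh(2.0, 1.0)
        cxb, _, _ = make_two_cell_mesh(2.0, 1.0)
        mech = MechanicsParams(iterations=4)
        for cx, fast in ((cxa, True), (cxb, False)):
            cs = pbd.build_constraints(cx, mech)
            pbd.set_pressure_targets(cs, cx, 0.02, 1.0)
            state = pbd.PbdState.from_complex(cx, iterations=4, dt=0.02)
            for _ in range(5):
                pbd.pbd_step(state, cs, dt=0.02, fast=fast)
        assert np.allclose(cxa.vertices, cxb.vertices, atol=1e-12)


class TestPressureAndStrain:
    def _iterate(self, cx, cs, steps, mech):
        state = pbd.PbdState.from_complex(cx, iterations=mech.iterations,
                                          dt=mech.dt)
        for _ in range(steps):
            pbd.pbd_step(state, cs, dt=mech.dt)
        return state

    def test_zero_correction_at_rest(self):
        cx, cell = make_rect_cell(1, 1)
        mech = MechanicsParams()
        cs = pbd.build_constraints(cx, mech)
        before = cx.vertices.copy()
        self._iterate(cx, cs, 3, mech)
        assert np.allclose(cx.vertices, before, atol=1e-9)

    def test_pressure_target_equal_area_no_correction(self):
        cx, cell = make_rect_cell(1, 1)
        state = simple_state(cx.vertices.copy())
        c = pbd.PressureConstraint(ids=list(cell.ring), target_area=1.0,
                                   compliance=0.0)
        before = state.pos.copy()
        pbd.project_pressure(c, state, dt=1.0)
        assert np.allclose(state.pos, before, atol=1e-12)

    def test_pressure_converges_to_target(self):
        cx, cell = make_rect_cell(1, 1)
        mech = MechanicsParams(iterations=1, pressure_compliance=1e-6)
        cs = pbd.ConstraintSet()
        cs.pressure.append(pbd.PressureConstraint(
            ids=list(cell.ring), target_area=1.2, compliance=1e-6,
            cell=cell.id))
        state = pbd.PbdState.from_complex(cx, iterations=1, dt=1.0)
        for _ in range(200):
            pbd.pbd_step(state, cs, dt=1.0)
        assert cx.cell_area(cell.id) == pytest.approx(1.2, rel=0.01)

    def test_strain_constraint_suppresses_growth_along_af(self):
        cx, cell = make_rect_cell(1, 1)
        cell.af = np.array([1.0, 0.0])
        mech = MechanicsParams(iterations=8, k_internal=0.0, k_shape=0.0,
                               k_bending=0.0)
        cs = pbd.build_constraints(cx, mech)
        for c in cs.distance:
            c.k_ext = c.k_comp = 0.0
        pbd.refresh_strain_stiffness(cs, cx, k_strain_max=1.0)
        for c in cs.pressure:
            c.target_area = 1.5
        state = pbd.PbdState.from_complex(cx, iterations=8, dt=1.0)
        for _ in range(200):
            pbd.pbd_step(state, cs, dt=1.0)
        width = np.ptp(cx.vertices[cell.ring][:, 0])
        height = np.ptp(cx.vertices[cell.ring][:, 1])
        assert width / height < 1.0   # expansion along af (x) is suppressed


class TestStrainMeasurement:
    def test_definition(self):
        cx, cell = make_rect_cell(1, 1)
        strains = pbd.measure_strain(cx)
        assert all(v == 0.0 for v in strains.values())
        # stretch the top edge by moving a vertex
        cx.vertices[2] = [1.1, 1.0]
        strains = pbd.measure_strain(cx)
        stretched = [v for v in strains.values() if v > 1e-12]
        assert any(v == pytest.approx(0.1, rel=1e-6) for v in stretched)

    def test_zero_rest_length_raises(self):
        cx, cell = make_rect_cell(1, 1)
        next(iter(cx.walls.values())).rest_length = 0.0
        with pytest.raises(GeometryError):
            pbd.measure_strain(cx)

    def test_plastic_relaxation_matches_closed_form(self):
        cx, cell = make_rect_cell(1, 1)
        wall = next(iter(cx.walls.values()))
        cx.vertices[wall.v2] = cx.vertices[wall.v1] + \
            (cx.vertices[wall.v2] - cx.vertices[wall.v1]) * 1.2
        L = cx.edge_length(wall.v1, wall.v2)
        rest0 = wall.rest_length
        r, dt, n = 0.1, 0.05, 400
        for _ in range(n):
            pbd.measure_strain(cx, dt=dt, yield_rate=r)
        # the nth call reports strain against rest_(n-1) = L - (L-rest0)(1-r dt)^(n-1)
        expected_rest = L - (L - rest0) * (1 - r * dt) ** (n - 1)
        expected_eps = (L - expected_rest) / expected_rest
        assert wall.strain == pytest.approx(expected_eps, abs=1e-6)
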