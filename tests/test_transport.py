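"""Auxin transport: fluxes, degradation, carrier life cycle, conservation."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from rootsim import transport
from rootsim.errors import ContractError
from rootsim.params import BoundaryParams, TransportParams

from conftest import make_rect_cell, make_two_cell_mesh


def closed_params(**kw):
    """Parameters with production, degradation and boundary exchange off."""
    defaults = dict(b_IAA=0.0, d_IAAb=0.0, d_IAAMax=0.0)
    defaults.update(kw)
    return TransportParams(**defaults)


class TestCarrierFluxes:
    def test_zero_carriers_zero_flux(self):
        cx, cell = make_rect_cell(1, 1)
        wall = cx.walls[cell.walls[0]]
        wall.iaa = 5.0
        cell.iaa = 3.0
        assert transport.carrier_fluxes(cell, wall, 1.0, TransportParams()) \
            == (0.0, 0.0)

    def test_export_value(self):
        # E = K_PIN * PIN_mem * IAA_cell * L = 1.4 * 2 * 1 * 5
        cx, cell = make_rect_cell(1, 1)
        wall = cx.walls[cell.walls[0]]
        wall.sides[cell.id].pin = 2.0
        cell.iaa = 1.0
        imp, exp = transport.carrier_fluxes(cell, wall, 5.0, TransportParams())
        assert exp == pytest.approx(14.0)
        assert imp == 0.0

    def test_linear_in_length(self):
        cx, cell = make_rect_cell(1, 1)
        wall = cx.walls[cell.walls[0]]
        wall.sides[cell.id].pin = 1.0
        wall.sides[cell.id].aux1 = 1.0
        wall.iaa = 2.0
        cell.iaa = 3.0
        p = TransportParams()
        i1, e1 = transport.carrier_fluxes(cell, wall, 1.0, p)
        i2, e2 = transport.carrier_fluxes(cell, wall, 2.0, p)
        assert i2 == pytest.approx(2 * i1)
        assert e2 == pytest.approx(2 * e1)


class TestDegradation:
    def test_basal_at_zero(self):
        assert transport.auxin_degradation(0.0, TransportParams()) == \
            pytest.approx(0.0125)

    def test_half_max(self):
        # at IAA = K_IAAMax: basal + half the span = 0.0125 + 0.1125/2
        assert transport.auxin_degradation(5.0, TransportParams()) == \
            pytest.approx(0.06875)

    def test_saturation_limit(self):
        assert transport.auxin_degradation(1e9, TransportParams()) == \
            pytest.approx(0.125, rel=1e-9)


class TestCellAuxin:
    def test_all_zero_stays_zero(self):
        cx, cell = make_rect_cell(1, 1)
        p = closed_params()
        new = transport.step_cell_auxin(cx, cell, p, dt=0.01)
        assert new == 0.0

    def test_qc_synthesis_matches_scalar_ode(self):
        # b_IAA = 10, no transport: compare to an independent scalar
        # integration and to a high-accuracy ODE solution
        cx, cell = make_rect_cell(1, 1)
        p = TransportParams(b_IAA=10.0, P_IAA=0.0, DI_IAA=0.0)
        dt, hours = 0.001, 5.0
        n = int(hours / dt)
        ref = 0.0
        for _ in range(n):
            transport.step_cell_auxin(cx, cell, p, dt=dt)
            ref = max(ref + dt * (10.0 - transport.auxin_degradation(ref, p)
                                  * ref), 0.0)
        assert cell.iaa == pytest.approx(ref, abs=1e-9)
        sol = solve_ivp(
            lambda t, y: 10.0 - transport.auxin_degradation(y[0], p) * y[0],
            (0, hours), [0.0], rtol=1e-10, atol=1e-12)
        assert cell.iaa == pytest.approx(sol.y[0, -1], rel=1e-4)

    def test_closed_two_cell_system_conserves_mass(self):
        cx, left, right = make_two_cell_mesh()
        rng = np.random.default_rng(3)
        for cell in (left, right):
            cell.iaa = rng.uniform(0, 5)
            cell.aux1_c = 1.0
            cell.pin_c = 0.5
            for wid in cell.walls:
                side = cx.walls[wid].sides[cell.id]
                side.pin = rng.uniform(0, 3)
                side.aux1 = rng.uniform(0, 3)
        for wall in cx.walls.values():
            wall.iaa = rng.uniform(0, 2)
        p = closed_params()
        nmap = transport.build_wall_neighbor_map(cx)
        total0 = cx.total_auxin(p.wall_thickness)
        for _ in range(100):
            before = cx.total_auxin(p.wall_thickness)
            transport.transport_substep(cx, p, None, 0.002, nmap)
            after = cx.total_auxin(p.wall_thickness)
            assert after == pytest.approx(before, abs=1e-8)
        assert cx.total_auxin(p.wall_thickness) == pytest.approx(total0, abs=1e-6)

    def test_randomized_meshes_conserve_mass(self, small_template):
        cx = small_template
        rng = np.random.default_rng(11)
        for cell in cx.cells.values():
            cell.iaa = rng.uniform(0, 3)
            for wid in cell.walls:
                side = cx.walls[wid].sides[cell.id]
                side.pin = rng.uniform(0, 2)
                side.aux1 = rng.uniform(0, 2)
        for wall in cx.walls.values():
            wall.iaa = rng.uniform(0, 2)
        p = closed_params()
        nmap = transport.build_wall_neighbor_map(cx)
        for _ in range(20):
            before = cx.total_auxin(p.wall_thickness)
            transport.transport_substep(cx, p, None, 0.002, nmap)
            assert cx.total_auxin(p.wall_thickness) == \
                pytest.approx(before, abs=1e-8)


class TestApoplast:
    def test_isolated_wall_unchanged(self):
        cx, cell = make_rect_cell(1, 1)
        wall = cx.walls[cell.walls[0]]
        wall.iaa = 2.0
        p = closed_params(P_IAA=0.0)
        transport.step_apoplast(cx, wall, [], p, dt=0.1)
        assert wall.iaa == pytest.approx(2.0)

    def test_two_compartment_diffusion_closed_form(self):
        cx, left, right = make_two_cell_mesh()
        walls = list(cx.walls.values())
        wa, wb = walls[0], walls[1]
        wa.iaa, wb.iaa = 2.0, 0.0
        p = closed_params(P_IAA=0.0)
        La = cx.edge_length(wa.v1, wa.v2)
        Lb = cx.edge_length(wb.v1, wb.v2)
        lam = p.DI_IAA / (La + Lb) * (1 / (La * p.wall_thickness) +
                                      1 / (Lb * p.wall_thickness))
        dt, n = 0.001, 2000
        last_gap = 2.0
        for _ in range(n):
            snap = transport.Snapshot(cx)
            transport.step_apoplast(cx, wa, [wb], p, dt, snapshot=snap)
            transport.step_apoplast(cx, wb, [wa], p, dt, snapshot=snap)
            total = wa.iaa * La * p.wall_thickness + \
                wb.iaa * Lb * p.wall_thickness
            assert total == pytest.approx(2.0 * La * p.wall_thickness,
                                          abs=1e-10)
            gap = wa.iaa - wb.iaa
            assert gap <= last_gap + 1e-12          # monotone approach
            last_gap = gap
        expected_gap = 2.0 * np.exp(-lam * dt * n)
        assert last_gap == pytest.approx(expected_gap, rel=0.01)

    def test_symmetric_fluxes_cancel(self):
        cx, cell = make_rect_cell(1, 1)
        wall = cx.walls[cell.walls[0]]
        wall.iaa = 1.0
        cell.iaa = 1.0
        wall.sides[cell.id].pin = 1.0 / 1.4   # K_PIN * pin = K_AUX1 * aux1
        wall.sides[cell.id].aux1 = 1.0
        p = closed_params(P_IAA=0.0)
        transport.step_apoplast(cx, wall, [], p, dt=0.1)
        assert wall.iaa == pytest.approx(1.0, abs=1e-12)


class TestCarrierExpression:
    def test_basal_only_without_auxin(self):
        cx, cell = make_rect_cell(1, 1)
        p = TransportParams()
        dt = 0.01
        transport.step_carrier_expression(cell, p, dt)
        assert cell.aux1_c == pytest.approx(dt * p.b_AUX1)
        assert cell.pin_c == pytest.approx(dt * p.b_PIN)

    def test_half_max_induction(self):
        cx, cell = make_rect_cell(1, 1)
        cell.iaa = TransportParams().AUX1_K
        p = TransportParams()
        dt = 0.01
        transport.step_carrier_expression(cell, p, dt)
        # induction at AUX1_expr / 2 = 15
        assert cell.aux1_c == pytest.approx(dt * (p.b_AUX1 + 15.0))

    def test_pools_capped(self):
        cx, cell = make_rect_cell(1, 1)
        cell.iaa = 100.0
        p = TransportParams()
        for _ in range(5000):
            transport.step_carrier_expression(cell, p, 0.01)
            assert cell.aux1_c <= p.AUX1_Max
            assert cell.pin_c <= p.PIN_Max
        assert cell.aux1_c == p.AUX1_Max
        assert cell.pin_c == p.PIN_Max

    def test_isolated_cell_carrier_fixed_point(self):
        # analytic steady state of the linear pool dynamics at fixed auxin
        cx, cell = make_rect_cell(1, 1)
        cell.iaa = 0.5
        p = TransportParams(AUX1_Max=1e9, PIN_Max=1e9)
        for _ in range(40000):
            transport.step_carrier_expression(cell, p, 0.005)
        i2 = cell.iaa ** 2
        expect_aux1 = (p.b_AUX1 + p.AUX1_expr * i2 / (p.AUX1_K ** 2 + i2)) / \
            (p.AUX1_tr + p.d_AUX1)
        expect_pin = (p.b_PIN + p.PIN_expr * i2 / (p.PIN_K ** 2 + i2)) / \
            (p.PIN_tr + p.d_PIN)
        assert cell.aux1_c == pytest.approx(expect_aux1, abs=1e-6)
        assert cell.pin_c == pytest.approx(expect_pin, abs=1e-6)


class TestTrafficking:
    def test_aux1_equal_lengths_equal_gains(self):
        cx, cell = make_rect_cell(1, 1)
        cell.aux1_c = 1.0
        p = TransportParams()
        transport.traffic_aux1(cx, cell, p, dt=0.01)
        vals = [cx.walls[w].sides[cell.id].aux1 for w in cell.walls]
        assert all(v == pytest.approx(vals[0]) for v in vals)
        assert vals[0] > 0

    def test_aux1_saturated_section_decays_only(self):
        cx, cell = make_rect_cell(1, 1)
        cell.aux1_c = 1.0
        p = TransportParams()
        side = cx.walls[cell.walls[0]].sides[cell.id]
        side.aux1 = p.AUX1_MaxMem
        transport.traffic_aux1(cx, cell, p, dt=0.01)
        assert side.aux1 == pytest.approx(
            p.AUX1_MaxMem * (1 - 0.01 * p.d_AUX1))

    def test_aux1_total_trafficked_mass(self):
        cx, cell = make_rect_cell(1, 1)
        cell.aux1_c = 1.3
        p = TransportParams(d_AUX1=0.0)
        dt = 0.01
        transport.traffic_aux1(cx, cell, p, dt)
        total = sum(cx.walls[w].sides[cell.id].aux1 for w in cell.walls)
        assert total == pytest.approx(cell.aux1_c * p.AUX1_tr * dt)

    def test_pin_membrane_decay_limits(self):
        p = TransportParams()
        d0 = p.d_PIN + (p.d_PINmax - p.d_PIN) / (1.0 + 0.0)
        assert d0 == pytest.approx(0.8)
        dinf = p.d_PIN + (p.d_PINmax - p.d_PIN) / (1.0 + 1e12)
        assert dinf == pytest.approx(0.08, abs=1e-9)

    def test_pin_zero_sensitivity_decays_only(self):
        cx, cell = make_rect_cell(1, 1)
        cell.pin_c = 1.0
        cell.iaa = 1.0
        p = TransportParams()
        sens = {w: 0.0 for w in cell.walls}
        sens[cell.walls[0]] = 1.0
        side = cx.walls[cell.walls[1]].sides[cell.id]
        side.pin = 2.0
        transport.traffic_pin(cx, cell, sens, p, dt=0.01)
        d_mem = p.d_PIN + (p.d_PINmax - p.d_PIN) / (1.0 + cell.iaa)
        assert side.pin == pytest.approx(2.0 * (1 - 0.01 * d_mem))

    def test_pin_unnormalized_sensitivities_rejected(self):
        cx, cell = make_rect_cell(1, 1)
        with pytest.raises(ContractError):
            transport.traffic_pin(cx, cell, {w: 0.4 for w in cell.walls},
                                  TransportParams(), dt=0.01)

    def test_pools_stay_in_bounds(self):
        cx, cell = make_rect_cell(1, 1)
        cell.aux1_c, cell.pin_c, cell.iaa = 2.0, 2.0, 1.0
        p = TransportParams()
        sens = {w: 0.25 for w in cell.walls}
        for _ in range(2000):
            transport.traffic_aux1(cx, cell, p, dt=0.02)
            transport.traffic_pin(cx, cell, sens, p, dt=0.02)
        for w in cell.walls:
            side = cx.walls[w].sides[cell.id]
            assert 0.0 <= side.aux1 <= p.AUX1_MaxMem
            assert 0.0 <= side.pin <= p.PIN_MaxMem
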