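"""PIN sensitivity softmax and the two polarization mechanisms."""

import math

import numpy as np
import pytest

from rootsim import polarity, transport
from rootsim.params import AnisotropyParams, PolarityParams, TransportParams

from conftest import make_polygon_cell, make_rect_cell


def zero_fluxes(cx, cell):
    return {(w, cell.id): (0.0, 0.0) for w in cell.walls}


class TestSoftmax:
    def test_equal_raws_uniform(self):
        cx, cell = make_rect_cell(1, 1)
        raw = {w: 0.7 for w in cell.walls}
        sens = polarity.pin_sensitivity(cell, raw)
        assert all(v == pytest.approx(0.25) for v in sens.values())

    def test_softmax_values(self):
        cx, cell = make_rect_cell(1, 1)
        raw = dict(zip(cell.walls, [1.0, 0.0, 0.0, 0.0]))
        sens = polarity.pin_sensitivity(cell, raw)
        e = math.e
        assert sens[cell.walls[0]] == pytest.approx(e / (e + 3), abs=1e-4)
        for w in cell.walls[1:]:
            assert sens[w] == pytest.approx(1 / (e + 3), abs=1e-4)

    def test_columella_uniform_override(self):
        cx, cell = make_polygon_cell(
            [[0, 0], [1, 0], [2, 0.5], [1.5, 1.5], [0.5, 1.6], [-0.5, 0.8]],
            cell_type="Columella")
        raw = dict(zip(cell.walls, [5.0, 0.0, 1.0, 3.0, 0.2, 0.9]))
        sens = polarity.pin_sensitivity(cell, raw)
        assert all(v == pytest.approx(1 / 6) for v in sens.values())

    def test_normalization_invariant(self, small_template):
        cx = small_template
        rng = np.random.default_rng(5)
        aniso = AnisotropyParams()
        pol = PolarityParams()
        for cell in cx.cells.values():
            cell.iaa = rng.uniform(0, 3)
            for w in cell.walls:
                cx.walls[w].sides[cell.id].pin = rng.uniform(0, 2)
        fluxes = transport.compute_fluxes(cx, TransportParams())
        for cell in cx.cells.values():
            geom = cx.cell_geometry(cell.id)
            br = polarity.compute_cell_polarity(cx, cell, geom, pol, aniso,
                                                fluxes)
            assert sum(br.pins.values()) == pytest.approx(1.0, abs=1e-9)
            assert all(0 < v < 1 for v in br.pins.values())


class TestFluxVector:
    def test_balanced_fluxes_zero_vector(self):
        cx, cell = make_rect_cell(1, 1)
        fluxes = {(w, cell.id): (2.0, 2.0) for w in cell.walls}
        geom = cx.cell_geometry(cell.id)
        assert np.allclose(polarity.flux_vector(cell, geom, fluxes), 0.0)

    def test_single_efflux_face(self):
        # net efflux through the left face only: the flux vector points from
        # the centroid toward the left midpoint with unit magnitude
        cx, cell = make_rect_cell(1, 1)
        geom = cx.cell_geometry(cell.id)
        fluxes = {(w, cell.id): (0.0, 0.0) for w in cell.walls}
        left = next(s for s in geom.sections if s.normal @ [-1, 0] > 0.9)
        fluxes[(left.wall, cell.id)] = (0.0, 1.0)
        v = polarity.flux_vector(cell, geom, fluxes)
        assert v == pytest.approx([-1.0, 0.0])

    def test_hexagon_against_brute_force(self):
        cx, cell = make_polygon_cell(
            [[0, 0], [1, 0], [2, 0.5], [1.5, 1.5], [0.5, 1.6], [-0.5, 0.8]])
        geom = cx.cell_geometry(cell.id)
        rng = np.random.default_rng(9)
        fluxes = {(s.wall, cell.id): (rng.uniform(0, 2), rng.uniform(0, 2))
                  for s in geom.sections}
        v = polarity.flux_vector(cell, geom, fluxes)
        expect = np.zeros(2)
        for s in geom.sections:
            imp, exp = fluxes[(s.wall, cell.id)]
            d = s.midpoint - geom.centroid
            expect += d / np.linalg.norm(d) * (exp - imp)
        assert v == pytest.approx(expect, abs=1e-12)


class TestFluxContribution:
    def _left_section(self):
        cx, cell = make_rect_cell(1, 1)
        geom = cx.cell_geometry(cell.id)
        return next(s for s in geom.sections if s.normal @ [-1, 0] > 0.9)

    def test_perpendicular_flux_no_contribution(self):
        s = self._left_section()
        assert polarity.flux_contribution(np.array([0.0, 3.0]), s,
                                          PolarityParams()) == 0.0

    def test_half_max(self):
        s = self._left_section()   # L = 1, n = (-1, 0)
        v = polarity.flux_contribution(np.array([-0.1, 0.0]), s,
                                       PolarityParams())
        assert v == pytest.approx(0.5)

    def test_strong_flux_saturates(self):
        s = self._left_section()
        v = polarity.flux_contribution(np.array([-1.0, 0.0]), s,
                                       PolarityParams())
        assert v == pytest.approx(0.9999, abs=1e-4)

    def test_inward_flux_clamped_to_zero(self):
        s = self._left_section()
        assert polarity.flux_contribution(np.array([1.0, 0.0]), s,
                                          PolarityParams()) == 0.0


class TestGradMem:
    def test_balanced_fluxes_zero(self):
        cx, cell = make_rect_cell(1, 1)
        geom = cx.cell_geometry(cell.id)
        fluxes = {(w, cell.id): (1.5, 1.5) for w in cell.walls}
        grads = polarity.grad_mem(cell, geom, fluxes, PolarityParams())
        assert all(v == 0.0 for v in grads.values())

    def test_single_term_amplification(self):
        cx, cell = make_rect_cell(1, 1)
        geom = cx.cell_geometry(cell.id)
        fluxes = {(w, cell.id): (0.0, 0.0) for w in cell.walls}
        target = geom.sections[0]
        fluxes[(target.wall, cell.id)] = (1.0, 0.0)
        grads = polarity.grad_mem(cell, geom, fluxes, PolarityParams())
        # own term: 1 * 1000 / A with A = 1; scale down to isolate
        assert grads[target.wall] == pytest.approx(1000.0 / geom.area)

    def test_linearity(self):
        cx, cell = make_rect_cell(1, 1)
        geom = cx.cell_geometry(cell.id)
        rng = np.random.default_rng(2)
        base = {(w, cell.id): (rng.uniform(0, 2), rng.uniform(0, 2))
                for w in cell.walls}
        scaled = {k: (3 * i, 3 * e) for k, (i, e) in base.items()}
        g1 = polarity.grad_mem(cell, geom, base, PolarityParams())
        g3 = polarity.grad_mem(cell, geom, scaled, PolarityParams())
        for w in cell.walls:
            assert g3[w] == pytest.approx(3 * g1[w], rel=1e-12)


class TestPolarizerContribution:
    def test_zero(self):
        assert polarity.polarizer_contribution(0.0, PolarityParams()) == 0.0

    def test_half_max(self):
        p = PolarityParams()
        assert polarity.polarizer_contribution(p.Kpol_IP, p) == \
            pytest.approx(0.5)

    def test_monotone(self):
        p = PolarityParams()
        vals = [polarity.polarizer_contribution(x, p)
                for x in np.linspace(0, 1, 20)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestRegulatorPolarizer:
    def test_uniform_regulator_no_displacement(self):
        cx, cell = make_rect_cell(1, 1)
        geom = cx.cell_geometry(cell.id)
        p = PolarityParams(b_REG=0.0, b_POL=0.0, d_REG=0.0, d_POL=0.0,
                           Kreg_tr=0.0, Kpol_tr=0.0, D_reg=0.0, D_pol=0.0)
        for w in cell.walls:
            side = cx.walls[w].sides[cell.id]
            side.reg = 1.0
            side.pol = 0.5
        rng = np.random.default_rng(0)
        before = [cx.walls[w].sides[cell.id].pol for w in cell.walls]
        for _ in range(50):
            polarity.step_regulator_polarizer(cx, cell, geom, p, 0.01, rng,
                                              zero_fluxes(cx, cell))
        after = [cx.walls[w].sides[cell.id].pol for w in cell.walls]
        assert after == pytest.approx(before)

    def test_polarizer_flees_regulator(self):
        cx, cell = make_polygon_cell([[0, 0], [1, 0], [0.5, 1.0]])
        geom = cx.cell_geometry(cell.id)
        p = PolarityParams(b_REG=0.0, b_POL=0.0, d_REG=0.0, d_POL=0.0,
                           Kreg_tr=0.0, Kpol_tr=0.0, D_reg=0.0, D_pol=0.0)
        hot = cell.walls[0]
        for w in cell.walls:
            side = cx.walls[w].sides[cell.id]
            side.reg = 1.0 if w == hot else 0.0
            side.pol = 1.0 if w == hot else 0.0
        rng = np.random.default_rng(1)
        for _ in range(300):
            polarity.step_regulator_polarizer(cx, cell, geom, p, 0.01, rng,
                                              zero_fluxes(cx, cell))
        pols = {w: cx.walls[w].sides[cell.id].pol for w in cell.walls}
        assert pols[hot] < 1e-3
        assert sum(pols.values()) == pytest.approx(1.0, abs=1e-9)

    def test_transport_terms_conserve_totals(self):
        # with production and degradation off, diffusion + displacement
        # leave the membrane totals unchanged
        cx, cell = make_polygon_cell(
            [[0, 0], [1, 0], [2, 0.5], [1.5, 1.5], [0.5, 1.6], [-0.5, 0.8]])
        geom = cx.cell_geometry(cell.id)
        p = PolarityParams(b_REG=0.0, b_POL=0.0, d_REG=0.0, d_POL=0.0,
                           Kreg_tr=0.0, Kpol_tr=0.0)
        rng = np.random.default_rng(4)
        for w in cell.walls:
            side = cx.walls[w].sides[cell.id]
            side.reg = rng.uniform(0, 2)
            side.pol = rng.uniform(0, 2)
        reg0 = sum(cx.walls[w].sides[cell.id].reg for w in cell.walls)
        pol0 = sum(cx.walls[w].sides[cell.id].pol for w in cell.walls)
        for _ in range(200):
            polarity.step_regulator_polarizer(cx, cell, geom, p, 0.01, rng,
                                              zero_fluxes(cx, cell))
        reg1 = sum(cx.walls[w].sides[cell.id].reg for w in cell.walls)
        pol1 = sum(cx.walls[w].sides[cell.id].pol for w in cell.walls)
        assert reg1 == pytest.approx(reg0, abs=1e-9)
        assert pol1 == pytest.approx(pol0, abs=1e-9)

    def test_af_removal_switch(self, small_template):
        cx = small_template
        aniso = AnisotropyParams()
        cell = next(iter(cx.cells.values()))
        cell.af = np.array([0.0, 0.8])
        fluxes = zero_fluxes(cx, cell)
        geom = cx.cell_geometry(cell.id)
        on = polarity.compute_cell_polarity(
            cx, cell, geom, PolarityParams(), aniso, fluxes)
        off = polarity.compute_cell_polarity(
            cx, cell, geom, PolarityParams(af_to_pin=False), aniso, fluxes)
        assert any(v > 0 for v in on.iaf.values())
        assert all(v == 0 for v in off.iaf.values())
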