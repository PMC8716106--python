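import numpy as np
import pytest

from rootsim.cell_complex import CellComplex
from rootsim.template import TemplateConfig, build_synthetic_root_template


def make_polygon_cell(coords, cell_type="Vascular"):
    """A single-cell complex from CCW polygon coordinates."""
    cx = CellComplex()
    vs = cx.add_vertices(coords)
    cell = cx.new_cell(cell_type, vs)
    cx.rebuild_walls(preserve=False)
    cx.add_centers()
    return cx, cell


def make_rect_cell(w=1.0, h=1.0, cell_type="Vascular"):
    return make_polygon_cell([[0, 0], [w, 0], [w, h], [0, h]], cell_type)


def make_two_cell_mesh(w=1.0, h=1.0):
    """Two side-by-side rectangles sharing one wall."""
    cx = CellComplex()
    vs = cx.add_vertices([[0, 0], [w, 0], [2 * w, 0],
                          [2 * w, h], [w, h], [0, h]])
    left = cx.new_cell("Vascular", [vs[0], vs[1], vs[4], vs[5]])
    right = cx.new_cell("Vascular", [vs[1], vs[2], vs[3], vs[4]])
    cx.rebuild_walls(preserve=False)
    cx.add_centers()
    return cx, left, right


@pytest.fixture(scope="session")
def template_cx():
    return build_synthetic_root_template()


@pytest.fixture()
def fresh_template():
    return build_synthetic_root_template()


@pytest.fixture()
def small_template():
    return build_synthetic_root_template(TemplateConfig(cells_per_file=3))
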