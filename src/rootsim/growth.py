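"""Auxin-dependent wall stiffness, division rules and remeshing.

Wall stiffness follows a double-Hill response to cellular auxin: walls are
maximally stiff both at negligible and at very high auxin, and relax (allow
turgor-driven expansion) at low-to-intermediate concentrations:

    kE_wall = kE_Max ( K1^4/(IAA^4 + K1^4) + IAA^4/(IAA^4 + K2^4) )

Division fires when a cell's area reaches its type-specific threshold.  The
division plane passes through the centroid, by default parallel to the AF
vector (anticlinal); stem-cell-niche types follow their own documented
rules (CEI, CEID, epidermis/LRC initials, columella and vascular initials);
QC and columella never divide.  Daughters inherit concentrations, the AF
vector, knockdowns and the division threshold; the fresh dividing wall
starts without any membrane carriers, so PIN repolarization after division
is an emergent relaxation of the trafficking system.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .cell_complex import Cell, CellComplex, MembraneSide
from .errors import MeshError
from .params import GrowthParams

log = logging.getLogger(__name__)

__all__ = ["wall_stiffness", "update_cell_wall_stiffness", "DivisionEvent",
           "check_and_divide", "apply_division"]

#: types that never divide
_NO_DIVISION = frozenset({"QC", "Columella", "Source", "Sink"})

_EPS = 1e-9


def wall_stiffness(iaa: float, params: GrowthParams) -> float:
    """Extension stiffness of a cell's walls given its auxin level."""
    i4 = iaa ** 4
    k1 = params.K_1auxin ** 4
    k2 = params.K_2auxin ** 4
    return params.kE_Max * (k1 / (i4 + k1) + i4 / (i4 + k2))


def update_cell_wall_stiffness(cx: CellComplex, params: GrowthParams) -> None:
    """Refresh every membrane side's stiffness from its cell's auxin.

    Auxin relaxes the entire wall of its cell; a wall shared by two cells
    takes the mean of the two sides when the mechanics asks for edge
    stiffness (see the solver's wall binding).
    """
    for cell in cx.cells.values():
        k = wall_stiffness(cell.iaa, params)
        for wid in cell.walls:
            cx.walls[wid].sides[cell.id].kE = k


@dataclass
class DivisionEvent:
    cell: int
    direction: np.ndarray           # unit vector of the division line
    cuts: List[Tuple[int, float]]   # (ring edge index, parametric position)
    points: List[np.ndarray]        # cut coordinates
    assign: str                     # daughter-typing rule tag
    qc_y: float = 0.0               # reference height of the niche
    axis_x: float = 0.0             # organ axis x (for inner/outer decisions)


def _division_direction(cell: Cell, geom, rule_parallel_af: bool) -> np.ndarray:
    """Division-line direction: parallel to AF (or orthogonal for the
    alternating epidermis/LRC rule); falls back to the short principal axis
    (anticlinal with respect to the cell geometry) for non-polar cells."""
    af = cell.af
    mag = math.hypot(af[0], af[1])
    if mag >= _EPS:
        d = np.asarray(af, float) / mag
    else:
        amin = geom.axis_min
        norm = float(np.linalg.norm(amin))
        d = amin / norm if norm > _EPS else np.array([1.0, 0.0])
    if not rule_parallel_af:
        d = np.array([-d[1], d[0]])
    return d


def _line_cuts(pts: np.ndarray, center: np.ndarray,
               direction: np.ndarray) -> List[Tuple[int, float]]:
    """Ring edges crossed by the line through ``center`` along ``direction``.

    Returns (edge index, parametric t in [0, 1]) for every proper crossing.
    """
    n = len(pts)
    # signed distance of each vertex from the line
    s = np.array([(p[0] - center[0]) * direction[1] -
                  (p[1] - center[1]) * direction[0] for p in pts])
    cuts = []
    for i in range(n):
        a, b = s[i], s[(i + 1) % n]
        if a == 0.0 and b == 0.0:
            continue
        if (a < 0 <= b) or (b < 0 <= a) or (a <= 0 < b) or (b <= 0 < a):
            if a == b:
                continue
            t = a / (a - b)
            if 0.0 <= t <= 1.0:
                cuts.append((i, float(t)))
    # drop duplicates from vertex-grazing (t == 1 of edge i equals t == 0 of i+1)
    dedup: List[Tuple[int, float]] = []
    for i, t in cuts:
        if dedup and i == (dedup[-1][0] + 1) % n and dedup[-1][1] > 1 - 1e-9 \
                and t < 1e-9:
            continue
        dedup.append((i, t))
    if len(dedup) > 1 and dedup[0][0] == 0 and dedup[0][1] < 1e-9 \
            and dedup[-1][0] == n - 1 and dedup[-1][1] > 1 - 1e-9:
        dedup.pop()
    return dedup


def check_and_divide(cx: CellComplex, cell: Cell, params: GrowthParams,
                     rng: np.random.Generator,
                     qc_y: Optional[float] = None,
                     axis_x: float = 0.0) -> Optional[DivisionEvent]:
    """Emit a division event if the cell's area reached its threshold.

    The daughter-typing rule tag encodes the cell-type-specific behavior;
    geometry is resolved by :func:`apply_division`.  Returns ``None`` for
    non-dividing types, sub-threshold cells, or if no valid division line is
    found after a few perturbed retries.
    """
    if cell.cell_type in _NO_DIVISION:
        return None
    if cell.a_max <= 0 or cx.cell_area(cell.id) < cell.a_max:
        return None
    geom = cx.cell_geometry(cell.id)
    ctype = cell.cell_type
    parallel = True
    if ctype == "CEID":
        # periclinal: split inner/outer along the cell-file (organ) axis
        assign = "ceid"
        direction = np.array([0.0, 1.0])
    elif ctype == "CEI":
        assign = "cei"
        direction = _division_direction(cell, geom, True)
    elif ctype == "EpidermisLRCInitial":
        # alternate: orthogonal to AF -> LRC, parallel to AF -> epidermis
        parallel = cell.parity % 2 == 1
        assign = "epilrc_epi" if parallel else "epilrc_lrc"
        direction = _division_direction(cell, geom, parallel)
    elif ctype == "ColumellaInitial":
        assign = "colinit"
        direction = _division_direction(cell, geom, True)
    elif ctype == "VascularInitial":
        assign = "vascinit"
        direction = _division_direction(cell, geom, True)
    else:
        assign = "same"
        direction = _division_direction(cell, geom, True)

    if qc_y is None:
        qcs = cx.cells_of_type("QC")
        if qcs:
            qc_y = float(np.mean([cx.cell_geometry(q.id).centroid[1] for q in qcs]))
        else:
            qc_y = float(np.min(cx.vertices[:, 1]))

    pts = cx.ring_coords(cell)
    for attempt in range(5):
        d = direction
        if attempt:
            ang = rng.normal(0.0, 0.15)
            ca, sa = math.cos(ang), math.sin(ang)
            d = np.array([ca * direction[0] - sa * direction[1],
                          sa * direction[0] + ca * direction[1]])
            log.info("cell %d: retrying division with perturbed angle", cell.id)
        cuts = _line_cuts(pts, geom.centroid, d)
        if len(cuts) == 2:
            points = []
            for i, t in cuts:
                pa = pts[i]
                pb = pts[(i + 1) % len(pts)]
                points.append(pa + t * (pb - pa))
            return DivisionEvent(cell=cell.id, direction=d, cuts=cuts,
                                 points=points, assign=assign,
                                 qc_y=qc_y, axis_x=axis_x)
    log.warning("cell %d: no valid division line found, skipping", cell.id)
    return None


def _daughter_types(event: DivisionEvent, parent: Cell,
                    c1: np.ndarray, c2: np.ndarray) -> Tuple[str, str]:
    """Type the daughters from the rule tag and their centroid positions."""
    assign = event.assign
    t = parent.cell_type
    if assign == "same":
        return t, t
    if assign == "ceid":
        # inner daughter -> endodermis, outer -> cortex
        inner_first = abs(c1[0] - event.axis_x) <= abs(c2[0] - event.axis_x)
        return ("Endodermis", "Cortex") if inner_first else ("Cortex", "Endodermis")
    if assign == "cei":
        # daughter farther from the QC becomes the CEID
        far_first = abs(c1[1] - event.qc_y) > abs(c2[1] - event.qc_y)
        return ("CEID", "CEI") if far_first else ("CEI", "CEID")
    if assign == "epilrc_lrc":
        outer_first = abs(c1[0] - event.axis_x) > abs(c2[0] - event.axis_x)
        return ("LRC", t) if outer_first else (t, "LRC")
    if assign == "epilrc_epi":
        far_first = abs(c1[1] - event.qc_y) > abs(c2[1] - event.qc_y)
        return ("Epidermis", t) if far_first else (t, "Epidermis")
    if assign == "colinit":
        # rootward daughter differentiates into columella
        return ("Columella", t) if c1[1] < c2[1] else (t, "Columella")
    if assign == "vascinit":
        # shootward daughter differentiates into vasculature
        return ("Vascular", t) if c1[1] > c2[1] else (t, "Vascular")
    raise MeshError(f"unknown daughter assignment {assign!r}")


_SNAP_DISTANCE = 0.75   # um; cuts closer than this to a vertex reuse it


def _insert_cut_vertex(cx: CellComplex, cell: Cell, edge_idx: int, t: float,
                       point: np.ndarray) -> int:
    """Materialize a cut: reuse a ring vertex if the cut lands near one
    (avoiding mechanically fragile sliver edges), else add a vertex, split
    the crossed wall and update the neighbor cell's ring."""
    ring = cell.ring
    a = ring[edge_idx]
    b = ring[(edge_idx + 1) % len(ring)]
    L = cx.edge_length(a, b)
    if t * L < _SNAP_DISTANCE:
        return a
    if (1.0 - t) * L < _SNAP_DISTANCE:
        return b
    vid = cx.add_vertex(point[0], point[1])
    wall = cx.walls[cx._wall_by_edge[cx._edge_key(a, b)]]
    # split wall state: intensive quantities copy, rest length splits
    _clone_wall(cx, wall, a, vid, wall.rest_length * t)
    _clone_wall(cx, wall, vid, b, wall.rest_length * (1.0 - t))
    del cx.walls[wall.id]
    del cx._wall_by_edge[cx._edge_key(a, b)]
    # update rings of all cells sharing the original wall
    for cid in wall.cells:
        other = cx.cells[cid]
        r = other.ring
        n = len(r)
        for i in range(n):
            if {r[i], r[(i + 1) % n]} == {a, b}:
                other.ring = r[:i + 1] + [vid] + r[i + 1:]
                break
    return vid


def _clone_wall(cx: CellComplex, wall, va: int, vb: int, rest: float):
    key = cx._edge_key(va, vb)
    nw = type(wall)(id=cx._next_wall, v1=key[0], v2=key[1])
    cx._next_wall += 1
    nw.iaa = wall.iaa
    nw.rest_length = rest
    nw.strain = wall.strain
    nw.no_flux = wall.no_flux
    for cid, side in wall.sides.items():
        nw.sides[cid] = MembraneSide(cell=cid, pin=side.pin, aux1=side.aux1,
                                     reg=side.reg, pol=side.pol, kE=side.kE)
    nw.cells = list(wall.cells)
    cx.walls[nw.id] = nw
    cx._wall_by_edge[key] = nw.id
    return nw


def apply_division(cx: CellComplex, event: DivisionEvent) -> Tuple[int, int]:
    """Execute a division event; returns the two daughter cell ids.

    Cut vertices are inserted (splitting crossed walls and updating the
    neighbors' rings), the parent ring is separated into two rings joined by
    the new wall, and daughters inherit the parent's intensive state
    (concentrations, AF, knockdowns, A_max).  The new wall's membrane sides
    start empty - repolarization is left to the trafficking dynamics - and
    its apoplast pool starts at zero, so total auxin is exactly conserved.
    """
    parent = cx.cells[event.cell]
    # insert in descending edge order so earlier indices stay valid
    order = sorted(range(2), key=lambda k: -(event.cuts[k][0] + event.cuts[k][1]))
    got: Dict[int, int] = {}
    for k in order:
        got[k] = _insert_cut_vertex(cx, parent, event.cuts[k][0],
                                    event.cuts[k][1], event.points[k])
    va, vb = got[0], got[1]
    if va == vb:
        raise MeshError(f"cell {parent.id}: degenerate division (single cut vertex)")
    ring = parent.ring
    ia, ib = ring.index(va), ring.index(vb)
    if ia > ib:
        ia, ib = ib, ia
        va, vb = vb, va
    ring1 = ring[ia:ib + 1]                  # va .. vb
    ring2 = ring[ib:] + ring[:ia + 1]        # vb .. va
    if len(ring1) < 3 or len(ring2) < 3:
        raise MeshError(f"cell {parent.id}: division produced a degenerate ring")

    def mk(ringx) -> Cell:
        d = cx.new_cell(parent.cell_type, list(ringx))
        d.iaa = parent.iaa
        d.pin_c = parent.pin_c
        d.aux1_c = parent.aux1_c
        d.reg_c = parent.reg_c
        d.pol_c = parent.pol_c
        d.af = np.array(parent.af, dtype=float)
        d.a_max = parent.a_max
        d.parity = (parent.parity + 1) % 2
        d.knockdown = dict(parent.knockdown)
        d.region = parent.region
        d.growth_factor = parent.growth_factor
        d.b_iaa = parent.b_iaa
        return d

    d1, d2 = mk(ring1), mk(ring2)
    del cx.cells[parent.id]
    cx.rebuild_walls(preserve=True)
    for d in (d1, d2):
        area = cx.cell_area(d.id)
        if area <= 0:
            raise MeshError(f"division of cell {parent.id}: non-CCW daughter")
        d.a_min = 0.5 * area
        c = cx.cell_geometry(d.id).centroid
        d.center = cx.add_vertex(c[0], c[1])
    c1 = cx.cell_geometry(d1.id).centroid
    c2 = cx.cell_geometry(d2.id).centroid
    t1, t2 = _daughter_types(event, parent, c1, c2)
    d1.cell_type, d2.cell_type = t1, t2
    return d1.id, d2.id
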