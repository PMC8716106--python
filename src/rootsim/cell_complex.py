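"""Cellular mesh data structure.

A :class:`CellComplex` represents a 2D tissue as cells-as-polygons sharing
wall segments.  Vertices live in a single coordinate array (micrometres,
y pointing shootward); every border edge of a cell belongs to exactly one
:class:`WallSegment`, and a wall adjoins one cell (organ surface) or two
cells.  Each wall carries a shared apoplastic auxin pool and one
:class:`MembraneSide` per adjoining cell holding that cell's membrane-bound
carrier amounts.  Cells are triangulated by a fan from a per-cell center
vertex; internal (center-to-ring) edges stand for the cytoskeleton in the
mechanical model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from shapely.geometry import Polygon

from .errors import GeometryError, MeshError, ParseError

__all__ = [
    "CELL_TYPES",
    "NON_GROWING_TYPES",
    "COLUMELLA_TYPES",
    "VASCULAR_GROUP",
    "MembraneSide",
    "WallSegment",
    "Cell",
    "MembraneSection",
    "CellGeometry",
    "CellComplex",
    "load_mesh",
    "save_mesh",
]

CELL_TYPES = frozenset({
    "QC", "ColumellaInitial", "Columella", "EpidermisLRCInitial", "CEI",
    "CEID", "LRC", "Epidermis", "Endodermis", "Cortex", "Pericycle",
    "Vascular", "VascularInitial", "Source", "Sink",
})

#: Cell types that neither grow nor divide (QC/columella per the model
#: assumptions; Source/Sink form the static attachment to the shoot).
NON_GROWING_TYPES = frozenset({"QC", "Columella", "Source", "Sink"})

#: Types in which PIN is trafficked uniformly over the membrane (PIN3-like).
COLUMELLA_TYPES = frozenset({"Columella", "ColumellaInitial"})

#: Central (stele) tissues, used by the longitudinal auxin profiles.
VASCULAR_GROUP = frozenset({"Vascular", "VascularInitial", "Pericycle", "Source"})


@dataclass
class MembraneSide:
    """Per-cell side of a wall segment: membrane-bound species and stiffness."""

    cell: int
    pin: float = 0.0
    aux1: float = 0.0
    reg: float = 0.0
    pol: float = 0.0
    kE: float = 1.0     # extension stiffness contributed by this cell's auxin


@dataclass
class WallSegment:
    """One wall segment: a border edge with its shared apoplast pool."""

    id: int
    v1: int
    v2: int
    cells: List[int] = field(default_factory=list)
    sides: Dict[int, MembraneSide] = field(default_factory=dict)
    iaa: float = 0.0            # apoplastic auxin, nM
    rest_length: float = 0.0    # um
    strain: float = 0.0         # (L - rest)/rest, updated by the mechanics
    no_flux: bool = False       # carrier fluxes disabled (reflux-blocking runs)

    def side(self, cell_id: int) -> MembraneSide:
        return self.sides[cell_id]

    @property
    def is_surface(self) -> bool:
        return len(self.cells) == 1


@dataclass
class Cell:
    """Cytoplasmic state and ring topology of one cell."""

    id: int
    cell_type: str
    ring: List[int]                 # CCW vertex ids, border polygon
    center: int = -1                # fan-triangulation center vertex id
    walls: List[int] = field(default_factory=list)  # wall id per ring edge
    iaa: float = 0.0
    pin_c: float = 0.0
    aux1_c: float = 0.0
    reg_c: float = 0.0
    pol_c: float = 0.0
    af: np.ndarray = field(default_factory=lambda: np.zeros(2))
    a_max: float = 0.0              # division area threshold, um^2
    a_min: float = 0.0              # turgor floor area (crush resistance), um^2
    parity: int = 0                 # alternating-division bookkeeping
    knockdown: Dict[str, float] = field(default_factory=dict)  # expression multipliers
    region: str = "BPE"             # mechanics-only region label (BPE vs RSI)
    growth_factor: float = 1.0      # prescribed growth multiplier (mechanics-only)
    b_iaa: Optional[float] = None   # per-cell basal auxin synthesis override, nM/h

    def knock(self, species: str) -> float:
        return self.knockdown.get(species, 1.0)


@dataclass
class MembraneSection:
    """Geometric view of one membrane section of a cell (one wall side)."""

    wall: int
    cell: int
    length: float
    normal: np.ndarray      # outward unit normal
    midpoint: np.ndarray
    direction: np.ndarray   # unit vector along the section


@dataclass
class CellGeometry:
    area: float
    centroid: np.ndarray
    axis_max: np.ndarray    # longest principal axis (vector, length = extent)
    axis_min: np.ndarray
    sections: List[MembraneSection]

    @property
    def aspect_ratio(self) -> float:
        return float(np.linalg.norm(self.axis_max) / max(np.linalg.norm(self.axis_min), 1e-12))


def _polygon_moments(pts: np.ndarray) -> Tuple[float, np.ndarray, np.ndarray]:
    """Signed area, centroid and central second-moment matrix of a polygon."""
    n = len(pts)
    area2 = 0.0
    cx = cy = 0.0
    sxx = syy = sxy = 0.0
    px = [float(p[0]) for p in pts]
    py = [float(p[1]) for p in pts]
    for i in range(n):
        j = (i + 1) % n
        x, y, xn, yn = px[i], py[i], px[j], py[j]
        cr = x * yn - xn * y
        area2 += cr
        cx += (x + xn) * cr
        cy += (y + yn) * cr
        sxx += (x * x + x * xn + xn * xn) * cr
        syy += (y * y + y * yn + yn * yn) * cr
        sxy += (x * yn + 2 * x * y + 2 * xn * yn + xn * y) * cr
    area = 0.5 * area2
    if abs(area) < 1e-12:
        raise GeometryError("degenerate (zero-area) polygon")
    cx /= 6.0 * area
    cy /= 6.0 * area
    sxx = sxx / 12.0 - area * cx * cx
    syy = syy / 12.0 - area * cy * cy
    sxy = sxy / 24.0 - area * cx * cy
    cov = np.array([[sxx, sxy], [sxy, syy]])
    return area, np.array([cx, cy]), cov


class CellComplex:
    """Shared vertex/wall mesh of a 2D tissue."""

    def __init__(self) -> None:
        self.vertices: np.ndarray = np.zeros((0, 2))
        self.cells: Dict[int, Cell] = {}
        self.walls: Dict[int, WallSegment] = {}
        self._wall_by_edge: Dict[Tuple[int, int], int] = {}
        self._next_cell = 0
        self._next_wall = 0

    # ------------------------------------------------------------------ build
    def add_vertices(self, coords: Sequence[Sequence[float]]) -> List[int]:
        start = len(self.vertices)
        arr = np.asarray(coords, dtype=float).reshape(-1, 2)
        self.vertices = np.vstack([self.vertices, arr]) if start else arr.copy()
        return list(range(start, len(self.vertices)))

    def add_vertex(self, x: float, y: float) -> int:
        return self.add_vertices([[x, y]])[0]

    def new_cell(self, cell_type: str, ring: Sequence[int], **kw) -> Cell:
        if cell_type not in CELL_TYPES:
            raise MeshError(f"unknown cell type {cell_type!r}")
        cell = Cell(id=self._next_cell, cell_type=cell_type, ring=list(ring), **kw)
        self._next_cell += 1
        self.cells[cell.id] = cell
        return cell

    @staticmethod
    def _edge_key(a: int, b: int) -> Tuple[int, int]:
        return (a, b) if a < b else (b, a)

    def rebuild_walls(self, preserve: bool = True) -> None:
        """(Re)derive wall segments from cell rings.

        With ``preserve`` the apoplast/membrane state of walls whose vertex
        pair is unchanged is kept; new edges start with fresh state.
        """
        old = self._wall_by_edge if preserve else {}
        old_walls = self.walls if preserve else {}
        self.walls = {}
        self._wall_by_edge = {}
        for cell in self.cells.values():
            ring = cell.ring
            cell.walls = []
            for i in range(len(ring)):
                a, b = ring[i], ring[(i + 1) % len(ring)]
                key = self._edge_key(a, b)
                wid = self._wall_by_edge.get(key)
                if wid is None:
                    prev_id = old.get(key)
                    if prev_id is not None and prev_id in old_walls:
                        wall = old_walls[prev_id]      # keep state of surviving edge
                        wall.cells = []
                    else:
                        wall = WallSegment(id=self._next_wall, v1=key[0], v2=key[1])
                        wall.rest_length = self.edge_length(a, b)
                        self._next_wall += 1
                    wid = wall.id
                    self.walls[wid] = wall
                    self._wall_by_edge[key] = wid
                wall = self.walls[wid]
                if cell.id in wall.cells:
                    raise MeshError(f"cell {cell.id} lists wall {wid} twice")
                if len(wall.cells) >= 2:
                    raise MeshError(
                        f"wall {wid} (vertices {key}) shared by more than 2 cells")
                wall.cells.append(cell.id)
                if cell.id not in wall.sides:
                    wall.sides[cell.id] = MembraneSide(cell=cell.id)
                cell.walls.append(wid)
        # drop sides of departed cells
        for wall in self.walls.values():
            for cid in list(wall.sides):
                if cid not in wall.cells:
                    del wall.sides[cid]

    def add_centers(self) -> None:
        """Add (or reposition) the fan-triangulation center vertex of each cell."""
        for cell in self.cells.values():
            c = self.cell_geometry(cell.id).centroid
            if cell.center < 0:
                cell.center = self.add_vertex(c[0], c[1])
            else:
                self.vertices[cell.center] = c

    # --------------------------------------------------------------- geometry
    def edge_length(self, a: int, b: int) -> float:
        v = self.vertices
        return math.hypot(v[a, 0] - v[b, 0], v[a, 1] - v[b, 1])

    def ring_coords(self, cell: Cell) -> np.ndarray:
        return self.vertices[cell.ring]

    def cell_area(self, cell_id: int) -> float:
        ring = self.cells[cell_id].ring
        v = self.vertices
        n = len(ring)
        total = 0.0
        for i in range(n):
            a, b = ring[i], ring[(i + 1) % n]
            total += v[a, 0] * v[b, 1] - v[b, 0] * v[a, 1]
        return 0.5 * total

    def cell_geometry(self, cell_id: int) -> CellGeometry:
        """Area (shoelace), centroid, principal axes and membrane sections.

        Principal axes come from the polygon's central second moments; the
        axis vectors are scaled so a w-by-h rectangle reports extents w and h.
        Normals point out of the cell (the ring is CCW).
        """
        cell = self.cells[cell_id]
        pts = self.ring_coords(cell)
        area, centroid, cov = _polygon_moments(pts)
        if area <= 0:
            raise GeometryError(f"cell {cell_id}: polygon not CCW or degenerate")
        # closed-form eigendecomposition of the symmetric 2x2 moment matrix
        a, b, c = cov[0, 0], cov[0, 1], cov[1, 1]
        half_tr = 0.5 * (a + c)
        disc = math.hypot(0.5 * (a - c), b)
        l_max, l_min = half_tr + disc, max(half_tr - disc, 0.0)
        if abs(b) > 1e-15:
            vx, vy = l_max - c, b
        elif a >= c:
            vx, vy = 1.0, 0.0
        else:
            vx, vy = 0.0, 1.0
        norm = math.hypot(vx, vy)
        u_max = np.array([vx / norm, vy / norm])
        u_min = np.array([-u_max[1], u_max[0]])
        ext_max = 2.0 * math.sqrt(3.0 * max(l_max, 0.0) / area)
        ext_min = 2.0 * math.sqrt(3.0 * l_min / area)
        axis_max = u_max * ext_max
        axis_min = u_min * ext_min
        sections: List[MembraneSection] = []
        n = len(cell.ring)
        v = self.vertices
        for i in range(n):
            va, vb = cell.ring[i], cell.ring[(i + 1) % n]
            ax, ay = v[va, 0], v[va, 1]
            bx, by = v[vb, 0], v[vb, 1]
            dx, dy = bx - ax, by - ay
            L = math.hypot(dx, dy)
            if L < 1e-12:
                raise GeometryError(f"cell {cell_id}: zero-length edge {va}-{vb}")
            ux, uy = dx / L, dy / L
            sections.append(MembraneSection(
                wall=cell.walls[i] if cell.walls else -1, cell=cell_id,
                length=L, normal=np.array([uy, -ux]),
                midpoint=np.array([0.5 * (ax + bx), 0.5 * (ay + by)]),
                direction=np.array([ux, uy])))
        return CellGeometry(area=area, centroid=centroid,
                            axis_max=axis_max, axis_min=axis_min,
                            sections=sections)

    def triangles(self, cell_id: int) -> List[Tuple[int, int, int]]:
        """Fan triangulation (center, ring_i, ring_i+1) of one cell."""
        cell = self.cells[cell_id]
        n = len(cell.ring)
        return [(cell.center, cell.ring[i], cell.ring[(i + 1) % n]) for i in range(n)]

    def neighbors(self, cell_id: int) -> List[int]:
        out = []
        for wid in self.cells[cell_id].walls:
            for cid in self.walls[wid].cells:
                if cid != cell_id and cid not in out:
                    out.append(cid)
        return out

    def wall_between(self, a: int, b: int) -> List[WallSegment]:
        """All wall segments shared by cells a and b."""
        return [self.walls[w] for w in self.cells[a].walls
                if b in self.walls[w].cells]

    # --------------------------------------------------------------- validate
    def validate(self, strict: bool = True) -> None:
        """Check the structural invariants; raise :class:`MeshError` if broken.

        With ``strict`` every cell polygon must be strictly simple (no
        self-contact at all).  The simulation driver validates with
        ``strict=False`` after remeshing: deformable cells may transiently
        touch themselves at a vertex without invalidating the physics, and
        the signed-area and adjacency checks still catch real inversions.
        """
        for cell in self.cells.values():
            if len(cell.ring) < 3:
                raise MeshError(f"cell {cell.id}: ring has <3 vertices")
            if strict:
                pts = self.ring_coords(cell)
                poly = Polygon(pts)
                if not poly.is_valid:
                    raise MeshError(f"cell {cell.id}: polygon is not simple")
            if self.cell_area(cell.id) <= 0:
                raise MeshError(f"cell {cell.id}: ring is not counter-clockwise")
            if len(cell.walls) != len(cell.ring):
                raise MeshError(f"cell {cell.id}: wall list does not match ring")
            for i, wid in enumerate(cell.walls):
                wall = self.walls.get(wid)
                if wall is None or cell.id not in wall.cells:
                    raise MeshError(f"cell {cell.id}: wall adjacency broken at {wid}")
                a, b = cell.ring[i], cell.ring[(i + 1) % len(cell.ring)]
                if self._edge_key(a, b) != (wall.v1, wall.v2):
                    raise MeshError(f"cell {cell.id}: wall {wid} vertex mismatch")
        for wall in self.walls.values():
            if not 1 <= len(wall.cells) <= 2:
                raise MeshError(f"wall {wall.id}: adjoins {len(wall.cells)} cells")
            for cid in wall.cells:
                if cid not in self.cells:
                    raise MeshError(f"wall {wall.id}: dangling cell {cid}")
                if wall.id not in self.cells[cid].walls:
                    raise MeshError(f"wall {wall.id}: adjacency not an involution")
            if set(wall.sides) != set(wall.cells):
                raise MeshError(f"wall {wall.id}: sides do not match cells")

    # --------------------------------------------------------------------- io
    def to_dict(self) -> dict:
        return {
            "version": 1,
            "vertices": [[float(x), float(y)] for x, y in self.vertices],
            "cells": [
                {
                    "id": c.id, "type": c.cell_type,
                    "vertex_ring": list(c.ring), "center": c.center,
                    "state": {
                        "IAA": c.iaa, "PIN": c.pin_c, "AUX1": c.aux1_c,
                        "REG": c.reg_c, "POL": c.pol_c,
                        "af": [float(c.af[0]), float(c.af[1])],
                        "A_max": c.a_max, "A_min": c.a_min, "parity": c.parity,
                        "knockdown": dict(c.knockdown),
                        "region": c.region, "growth_factor": c.growth_factor,
                        "b_IAA": c.b_iaa,
                    },
                }
                for c in self.cells.values()
            ],
            "walls": [
                {
                    "id": w.id, "v": [w.v1, w.v2], "cells": list(w.cells),
                    "IAA": w.iaa, "rest_length": w.rest_length,
                    "strain": w.strain, "no_flux": w.no_flux,
                    "sides": [
                        {"cell": s.cell, "PIN": s.pin, "AUX1": s.aux1,
                         "REG": s.reg, "POL": s.pol, "kE": s.kE}
                        for s in w.sides.values()
                    ],
                }
                for w in self.walls.values()
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CellComplex":
        cx = cls()
        try:
            cx.vertices = np.asarray(data["vertices"], dtype=float).reshape(-1, 2)
        except (KeyError, ValueError) as exc:
            raise ParseError(f"bad vertices record: {exc}") from exc
        for rec in data.get("cells", []):
            cid = rec.get("id")
            if "type" not in rec:
                raise ParseError(f"cell {cid}: missing cell_type")
            if rec["type"] not in CELL_TYPES:
                raise ParseError(f"cell {cid}: unknown cell_type {rec['type']!r}")
            st = rec.get("state", {})
            cell = Cell(
                id=cid, cell_type=rec["type"], ring=list(rec["vertex_ring"]),
                center=rec.get("center", -1),
                iaa=st.get("IAA", 0.0), pin_c=st.get("PIN", 0.0),
                aux1_c=st.get("AUX1", 0.0), reg_c=st.get("REG", 0.0),
                pol_c=st.get("POL", 0.0),
                af=np.asarray(st.get("af", [0.0, 0.0]), dtype=float),
                a_max=st.get("A_max", 0.0), a_min=st.get("A_min", 0.0),
                parity=st.get("parity", 0),
                knockdown=dict(st.get("knockdown", {})),
                region=st.get("region", "BPE"),
                growth_factor=st.get("growth_factor", 1.0),
                b_iaa=st.get("b_IAA"),
            )
            cx.cells[cell.id] = cell
            cx._next_cell = max(cx._next_cell, cell.id + 1)
        cx.rebuild_walls(preserve=False)
        # overlay stored wall state
        for rec in data.get("walls", []):
            v1, v2 = rec["v"]
            wid = cx._wall_by_edge.get(cls._edge_key(v1, v2))
            if wid is None:
                raise ParseError(f"wall {rec.get('id')}: edge {v1}-{v2} not on any cell")
            wall = cx.walls[wid]
            if sorted(rec.get("cells", [])) != sorted(wall.cells):
                raise ParseError(f"wall {rec.get('id')}: cell adjacency mismatch")
            wall.iaa = rec.get("IAA", 0.0)
            wall.rest_length = rec.get("rest_length", wall.rest_length)
            wall.strain = rec.get("strain", 0.0)
            wall.no_flux = rec.get("no_flux", False)
            for srec in rec.get("sides", []):
                if srec["cell"] not in wall.sides:
                    raise ParseError(f"wall {rec.get('id')}: side for non-adjacent "
                                     f"cell {srec['cell']}")
                s = wall.sides[srec["cell"]]
                s.pin = srec.get("PIN", 0.0)
                s.aux1 = srec.get("AUX1", 0.0)
                s.reg = srec.get("REG", 0.0)
                s.pol = srec.get("POL", 0.0)
                s.kE = srec.get("kE", 1.0)
        cx.validate()
        return cx

    # ------------------------------------------------------------------- misc
    def cells_of_type(self, *types: str) -> List[Cell]:
        return [c for c in self.cells.values() if c.cell_type in types]

    def total_auxin(self, thickness: float = 1.0) -> float:
        """Total auxin amount: cell concentration x area + wall pools x apoplast area."""
        total = 0.0
        for cell in self.cells.values():
            total += cell.iaa * self.cell_area(cell.id)
        for wall in self.walls.values():
            total += wall.iaa * self.edge_length(wall.v1, wall.v2) * thickness
        return total


def save_mesh(cx: CellComplex, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(cx.to_dict(), fh, indent=1)


def load_mesh(path: str) -> CellComplex:
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"not valid JSON: {exc}") from exc
    return CellComplex.from_dict(data)


def export_vtk(cx: CellComplex, path: str) -> None:
    """Write the mesh as legacy-ASCII VTK polydata with per-cell scalars."""
    cells = list(cx.cells.values())
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nrootsim mesh\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(cx.vertices)} float\n")
        for x, y in cx.vertices:
            fh.write(f"{x} {y} 0.0\n")
        size = sum(len(c.ring) + 1 for c in cells)
        fh.write(f"POLYGONS {len(cells)} {size}\n")
        for c in cells:
            fh.write(" ".join([str(len(c.ring))] + [str(v) for v in c.ring]) + "\n")
        fh.write(f"CELL_DATA {len(cells)}\n")
        fh.write("SCALARS auxin float 1\nLOOKUP_TABLE default\n")
        for c in cells:
            fh.write(f"{c.iaa}\n")
        fh.write("SCALARS af_magnitude float 1\nLOOKUP_TABLE default\n")
        for c in cells:
            fh.write(f"{float(np.linalg.norm(c.af))}\n")
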