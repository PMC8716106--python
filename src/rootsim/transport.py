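"""Polar auxin transport: pools, carrier fluxes and carrier life cycle.

Auxin (IAA) lives in two compartment kinds: the cell cytoplasm and a shared
apoplast pool per wall segment (the intercellular space; its compartment
area is segment length times a nominal wall thickness).  Carriers are
expressed in the cytoplasm under auxin induction, trafficked to the
membrane sections (AUX/LAX uniformly by length share, PIN by the per-section
PIN sensitivity), and degraded; membrane pools saturate at hard caps.
Carrier-mediated fluxes are linear in carrier and substrate:

    I_mem = K_AUX1 * AUX1_mem * IAA_mem * L_mem      (import)
    E_mem = K_PIN  * PIN_mem  * IAA_cell * L_mem     (export)

Flux amounts are converted to concentration changes by dividing by the
receiving compartment's area, which makes cell<->apoplast exchange exactly
mass-conserving.  Degradation is saturable (quiet basal removal, boosted at
high auxin).  All updates are explicit Euler, evaluated Jacobi-style on a
frozen entry snapshot so pairwise exchanges stay exactly antisymmetric; the
simulation driver substeps the chemistry relative to the mechanics step for
stability.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Optional, Tuple

from .cell_complex import Cell, CellComplex, WallSegment
from .errors import ContractError
from .params import BoundaryParams, TransportParams

log = logging.getLogger(__name__)

__all__ = [
    "carrier_fluxes",
    "auxin_degradation",
    "Snapshot",
    "TransportGeometry",
    "step_apoplast",
    "step_cell_auxin",
    "step_carrier_expression",
    "traffic_aux1",
    "traffic_pin",
    "wall_neighbors",
    "compute_fluxes",
    "transport_substep",
    "build_wall_neighbor_map",
]

FluxMap = Dict[Tuple[int, int], Tuple[float, float]]   # (wall, cell) -> (I, E)


class TransportGeometry:
    """Per-step cache of wall lengths and cell areas (mesh is static between
    mechanics steps, so the chemistry substeps share one cache)."""

    def __init__(self, cx: CellComplex):
        self.wall_len: Dict[int, float] = {
            w.id: cx.edge_length(w.v1, w.v2) for w in cx.walls.values()}
        self.cell_area: Dict[int, float] = {
            c.id: cx.cell_area(c.id) for c in cx.cells.values()}


class Snapshot:
    """Frozen auxin concentrations at substep entry (Jacobi update basis)."""

    def __init__(self, cx: CellComplex):
        self.wall_iaa = {w.id: w.iaa for w in cx.walls.values()}
        self.cell_iaa = {c.id: c.iaa for c in cx.cells.values()}


def carrier_fluxes(cell: Cell, wall: WallSegment, length: float,
                   params: TransportParams) -> Tuple[float, float]:
    """Import and export flux (nM um/h) across one membrane section."""
    if wall.no_flux:
        return 0.0, 0.0
    side = wall.sides[cell.id]
    imp = params.K_AUX1 * side.aux1 * wall.iaa * length
    exp = params.K_PIN * side.pin * cell.iaa * length
    return imp, exp


def auxin_degradation(iaa: float, params: TransportParams) -> float:
    """Saturable auxin degradation-rate coefficient (1/h).

    rate = d_IAAb + (d_IAAMax - d_IAAb) IAA^4 / (K_IAAMax^4 + IAA^4)

    Basal turnover is slow; above the half-max threshold K_IAAMax the
    coefficient saturates at d_IAAMax, so high pools are removed in
    proportion to their level (this is what lets degradation balance
    excessive auxin).  The removal flux is ``rate * IAA``.
    """
    i4 = iaa ** 4
    return params.d_IAAb + (params.d_IAAMax - params.d_IAAb) * \
        i4 / (params.K_IAAMax ** 4 + i4)


def wall_neighbors(cx: CellComplex, wall: WallSegment) -> List[WallSegment]:
    """Wall segments sharing an endpoint with ``wall`` (apoplast continuum)."""
    out = []
    for other in cx.walls.values():
        if other.id == wall.id:
            continue
        if {other.v1, other.v2} & {wall.v1, wall.v2}:
            out.append(other)
    return out


def step_apoplast(cx: CellComplex, wall: WallSegment,
                  neighbors: Iterable[WallSegment],
                  params: TransportParams, dt: float,
                  fluxes: Optional[FluxMap] = None,
                  exterior_exchange: float = 0.0,
                  snapshot: Optional[Snapshot] = None,
                  geom: Optional[TransportGeometry] = None,
                  ledger: Optional[Dict[str, float]] = None) -> float:
    """Euler-update one wall's apoplast pool; returns the new concentration.

    Terms: net carrier exchange with the adjoining cells, apoplastic
    diffusion to adjacent wall segments (scaled by 1/(L + L_i)), passive
    transmembrane exchange, saturable degradation, and optionally first-order
    leakage to a zero-concentration exterior for surface segments.
    Pools are clamped at zero (clamping is logged as a mass-balance warning).
    """
    snap = snapshot or Snapshot(cx)
    my_iaa = snap.wall_iaa[wall.id]
    L = geom.wall_len[wall.id] if geom else cx.edge_length(wall.v1, wall.v2)
    area = L * params.wall_thickness
    amount_rate = 0.0   # nM um^2 / h into this wall pool
    for cid in wall.cells:
        cell = cx.cells[cid]
        if fluxes is not None:
            imp, exp = fluxes[(wall.id, cid)]
        else:
            imp, exp = carrier_fluxes(cell, wall, L, params)
        amount_rate += exp - imp
        amount_rate += params.P_IAA * (snap.cell_iaa[cid] - my_iaa) * L
    for other in neighbors:
        Li = geom.wall_len[other.id] if geom else \
            cx.edge_length(other.v1, other.v2)
        amount_rate -= params.DI_IAA * (my_iaa - snap.wall_iaa[other.id]) / (L + Li)
    new = my_iaa + dt * (amount_rate / area
                         - auxin_degradation(my_iaa, params) * my_iaa)
    leak = dt * exterior_exchange * my_iaa \
        if (wall.is_surface and exterior_exchange > 0) else 0.0
    new -= leak
    clamped = 0.0
    if new < 0.0:
        if new < -1e-9:
            log.warning("wall %d: apoplast pool clamped at 0 (%.3g)", wall.id, new)
        clamped = -new
        new = 0.0
    if ledger is not None:
        ledger["degradation"] += \
            dt * auxin_degradation(my_iaa, params) * my_iaa * area
        ledger["boundary_out"] += leak * area
        ledger["clamped"] += clamped * area
    wall.iaa = new
    return new


def step_cell_auxin(cx: CellComplex, cell: Cell, params: TransportParams,
                    dt: float, fluxes: Optional[FluxMap] = None,
                    boundary: Optional[BoundaryParams] = None,
                    extra_synthesis: float = 0.0,
                    snapshot: Optional[Snapshot] = None,
                    geom: Optional[TransportGeometry] = None,
                    ledger: Optional[Dict[str, float]] = None) -> float:
    """Euler-update one cell's auxin; returns the new concentration.

    Terms: basal synthesis (per-cell override wins over the global rate),
    net carrier fluxes and passive diffusion over all membrane sections
    (normalized by cell area), saturable degradation; Source cells receive
    the constant shoot-derived influx, Sink cells export to the shoot with
    first-order kinetics.  ``extra_synthesis`` implements timed auxin
    application (external auxin experiments).
    """
    snap = snapshot or Snapshot(cx)
    my_iaa = snap.cell_iaa[cell.id]
    area = geom.cell_area[cell.id] if geom else cx.cell_area(cell.id)
    b = cell.b_iaa if cell.b_iaa is not None else params.b_IAA
    amount_rate = 0.0
    for wid in cell.walls:
        wall = cx.walls[wid]
        L = geom.wall_len[wid] if geom else cx.edge_length(wall.v1, wall.v2)
        if fluxes is not None:
            imp, exp = fluxes[(wid, cell.id)]
        else:
            imp, exp = carrier_fluxes(cell, wall, L, params)
        amount_rate += imp - exp
        amount_rate += params.P_IAA * (snap.wall_iaa[wid] - my_iaa) * L
    rate = b + extra_synthesis + amount_rate / area \
        - auxin_degradation(my_iaa, params) * my_iaa
    boundary_in = boundary_out = 0.0
    if boundary is not None:
        if cell.cell_type == "Source":
            boundary_in = boundary.source_influx / area
        elif cell.cell_type == "Sink":
            boundary_out = boundary.sink_rate * my_iaa
    new = my_iaa + dt * (rate + boundary_in - boundary_out)
    clamped = 0.0
    if new < 0.0:
        clamped = -new
        new = 0.0
    if ledger is not None:
        ledger["production"] += dt * (b + extra_synthesis + boundary_in) * area
        ledger["degradation"] += \
            dt * auxin_degradation(my_iaa, params) * my_iaa * area
        ledger["boundary_out"] += dt * boundary_out * area
        ledger["clamped"] += clamped * area
    cell.iaa = new
    return new


def step_carrier_expression(cell: Cell, params: TransportParams,
                            dt: float) -> Tuple[float, float]:
    """Euler-update the cytoplasmic AUX/LAX and PIN pools.

    Expression = basal + auxin-induced Hill(2) term, scaled by the cell's
    knockdown multiplier; losses are trafficking to the membranes plus
    first-order degradation.  Pools are capped at AUX1_Max / PIN_Max.
    """
    iaa2 = cell.iaa ** 2
    ka = cell.knock("AUX1")
    kp = cell.knock("PIN")
    aux1 = cell.aux1_c + dt * (
        ka * (params.b_AUX1 + params.AUX1_expr * iaa2 / (params.AUX1_K ** 2 + iaa2))
        - cell.aux1_c * params.AUX1_tr - params.d_AUX1 * cell.aux1_c)
    pin = cell.pin_c + dt * (
        kp * (params.b_PIN + params.PIN_expr * iaa2 / (params.PIN_K ** 2 + iaa2))
        - cell.pin_c * params.PIN_tr - params.d_PIN * cell.pin_c)
    cell.aux1_c = min(max(aux1, 0.0), params.AUX1_Max)
    cell.pin_c = min(max(pin, 0.0), params.PIN_Max)
    return cell.aux1_c, cell.pin_c


def traffic_aux1(cx: CellComplex, cell: Cell, params: TransportParams,
                 dt: float, geom: Optional[TransportGeometry] = None) -> None:
    """Distribute cytoplasmic AUX/LAX evenly (by length share) over the
    membrane sections; saturated sections receive nothing and only decay."""
    if geom:
        lengths = [geom.wall_len[w] for w in cell.walls]
    else:
        lengths = [cx.edge_length(cx.walls[w].v1, cx.walls[w].v2)
                   for w in cell.walls]
    total_L = sum(lengths)
    if total_L <= 0:
        return
    for wid, L in zip(cell.walls, lengths):
        side = cx.walls[wid].sides[cell.id]
        gain = cell.aux1_c * params.AUX1_tr * (L / total_L)
        if side.aux1 >= params.AUX1_MaxMem:
            gain = 0.0
        new = side.aux1 + dt * (gain - params.d_AUX1 * side.aux1)
        side.aux1 = min(max(new, 0.0), params.AUX1_MaxMem)


def traffic_pin(cx: CellComplex, cell: Cell, sensitivities: Dict[int, float],
                params: TransportParams, dt: float) -> None:
    """Traffic cytoplasmic PIN to the membrane by PIN sensitivity.

    Gain on a section is PIN_cell * PIN_tr * PinS (zero once the section is
    saturated); the loss rate is auxin-gated,
    d_PINmem = d_PIN + (d_PINmax - d_PIN)/(1 + IAA_cell), so PIN turns over
    fast in auxin-poor cells, allowing rapid repolarization.
    """
    total = sum(sensitivities.values())
    if abs(total - 1.0) > 1e-6:
        raise ContractError(f"PIN sensitivities sum to {total}, expected 1")
    d_mem = params.d_PIN + (params.d_PINmax - params.d_PIN) / (1.0 + cell.iaa)
    for wid in cell.walls:
        side = cx.walls[wid].sides[cell.id]
        gain = cell.pin_c * params.PIN_tr * sensitivities[wid]
        if side.pin >= params.PIN_MaxMem:
            gain = 0.0
        new = side.pin + dt * (gain - d_mem * side.pin)
        side.pin = min(max(new, 0.0), params.PIN_MaxMem)


def initialize_carriers(cx: CellComplex, params: TransportParams) -> None:
    """Set carriers to their auxin-free, non-polar steady state.

    The embryonic starting condition has uniformly distributed carriers (the
    initial state is non-polar, not carrier-free): cytoplasmic pools at the
    basal expression balance and membrane pools at the uniform-trafficking
    fixed point for zero auxin.
    """
    aux1_c = params.b_AUX1 / (params.AUX1_tr + params.d_AUX1)
    pin_c = params.b_PIN / (params.PIN_tr + params.d_PIN)
    d_pin_mem0 = params.d_PIN + (params.d_PINmax - params.d_PIN)  # IAA = 0
    for cell in cx.cells.values():
        cell.aux1_c = aux1_c
        cell.pin_c = pin_c
        lengths = [cx.edge_length(cx.walls[w].v1, cx.walls[w].v2)
                   for w in cell.walls]
        total_L = sum(lengths)
        m = len(cell.walls)
        for wid, L in zip(cell.walls, lengths):
            side = cx.walls[wid].sides[cell.id]
            side.aux1 = min(aux1_c * params.AUX1_tr * (L / total_L)
                            / params.d_AUX1, params.AUX1_MaxMem)
            side.pin = min(pin_c * params.PIN_tr * (1.0 / m) / d_pin_mem0,
                           params.PIN_MaxMem)


# ------------------------------------------------------------------- driver

def compute_fluxes(cx: CellComplex, params: TransportParams,
                   geom: Optional[TransportGeometry] = None) -> FluxMap:
    """Carrier fluxes for every (wall, cell) membrane section."""
    out: FluxMap = {}
    for wall in cx.walls.values():
        L = geom.wall_len[wall.id] if geom else \
            cx.edge_length(wall.v1, wall.v2)
        for cid in wall.cells:
            out[(wall.id, cid)] = carrier_fluxes(cx.cells[cid], wall, L, params)
    return out


def transport_substep(cx: CellComplex, params: TransportParams,
                      boundary: Optional[BoundaryParams], dt: float,
                      neighbor_map: Dict[int, List[int]],
                      pin_sens: Optional[Dict[int, Dict[int, float]]] = None,
                      extra_synthesis: Optional[Dict[int, float]] = None,
                      geom: Optional[TransportGeometry] = None,
                      ledger: Optional[Dict[str, float]] = None) -> None:
    """One Euler substep of the full chemistry on the mesh.

    Fluxes are evaluated on the state at substep entry, then apoplast pools,
    cell pools, carrier expression and carrier trafficking are updated.
    ``neighbor_map`` caches wall adjacency (wall id -> neighbor wall ids);
    ``pin_sens`` holds the per-cell PIN sensitivities (held fixed between
    mechanics steps).
    """
    geom = geom or TransportGeometry(cx)
    fluxes = compute_fluxes(cx, params, geom)
    snap = Snapshot(cx)
    ext = boundary.exterior_exchange if boundary else 0.0
    for wall in cx.walls.values():
        neigh = [cx.walls[w] for w in neighbor_map[wall.id]]
        step_apoplast(cx, wall, neigh, params, dt, fluxes,
                      exterior_exchange=ext, snapshot=snap, geom=geom,
                      ledger=ledger)
    for cell in cx.cells.values():
        extra = extra_synthesis.get(cell.id, 0.0) if extra_synthesis else 0.0
        step_cell_auxin(cx, cell, params, dt, fluxes, boundary, extra,
                        snapshot=snap, geom=geom, ledger=ledger)
        step_carrier_expression(cell, params, dt)
        traffic_aux1(cx, cell, params, dt, geom=geom)
        if pin_sens is not None and cell.id in pin_sens:
            traffic_pin(cx, cell, pin_sens[cell.id], params, dt)


def build_wall_neighbor_map(cx: CellComplex) -> Dict[int, List[int]]:
    """Wall id -> ids of walls sharing an endpoint (built once per topology)."""
    by_vertex: Dict[int, List[int]] = {}
    for wall in cx.walls.values():
        by_vertex.setdefault(wall.v1, []).append(wall.id)
        by_vertex.setdefault(wall.v2, []).append(wall.id)
    out: Dict[int, List[int]] = {w: [] for w in cx.walls}
    for wall in cx.walls.values():
        seen = {wall.id}
        for v in (wall.v1, wall.v2):
            for other in by_vertex[v]:
                if other not in seen:
                    out[wall.id].append(other)
                    seen.add(other)
    return out
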