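"""Simulation driver, in-silico experiment library and output metrics.

A scenario couples the mechanical and biochemical subsystems in a fixed
per-step order: (1) PBD mechanics (with concentration dilution by the
achieved growth), (2) strain measurement and anisotropy update, (3) Euler
substeps of auxin transport, carrier expression and AUX/LAX trafficking,
(4) mechanism-specific polarity input, PIN sensitivity and PIN trafficking,
(5) auxin-dependent wall-stiffness refresh, (6) division check and
remeshing, (7) scheduled perturbations, (8) recording.  Runs are
bit-reproducible for a fixed seed.

The perturbation vocabulary covers the classic wet-lab manipulations:
carrier knockdowns, QC ablation, lateral-root-cap removal, root-tip
excision, cytoskeleton-drug (oryzalin-like) AF destabilization, timed
external auxin application, reflux blocking, shoot-source removal, and
QC-local auxin synthesis.
"""

from __future__ import annotations

import copy
import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import pbd, transport
from .anisotropy import update_af
from .cell_complex import VASCULAR_GROUP, CellComplex
from .errors import ConfigurationError, MeshError, SolverDivergenceError
from .growth import apply_division, check_and_divide, update_cell_wall_stiffness
from .params import Parameters
from .polarity import compute_cell_polarity, step_regulator_polarizer
from .template import (TemplateConfig, attachment_vertices,
                       build_synthetic_root_template)

__all__ = ["Action", "ScenarioConfig", "Frame", "SimulationTrace",
           "Simulation", "run", "mechanics_only", "sweep", "metrics"]

_EPI_GROUP = frozenset({"Epidermis", "LRC", "EpidermisLRCInitial"})


@dataclass
class Action:
    """A scheduled perturbation: applied once at ``step``."""

    step: int
    kind: str
    params: Dict[str, Any] = field(default_factory=dict)


@dataclass
class ScenarioConfig:
    steps: int = 500
    seed: int = 0
    mechanism: str = "flux"             # "flux" | "regulator_polarizer"
    mode: str = "coupled"               # "coupled" | "mechanics_only"
    record_every: int = 10
    template: TemplateConfig = field(default_factory=TemplateConfig)
    mesh_path: Optional[str] = None     # load a segmented mesh instead
    overrides: Dict[str, Dict[str, Any]] = field(default_factory=dict)
    perturbations: List[Action] = field(default_factory=list)
    # mechanics-only scenario settings
    growth_factors: Dict[str, float] = field(
        default_factory=lambda: {"BPE": 4.0, "RSI": 1.0})
    relax_at: Optional[int] = None      # step at which differential growth stops
    mech_only_wall_k: float = 0.05      # fixed wall stiffness without biochemistry

    @classmethod
    def from_dict(cls, data: Dict[str, Any]) -> "ScenarioConfig":
        data = dict(data)
        if "template" in data and isinstance(data["template"], dict):
            data["template"] = TemplateConfig(**data["template"])
        if "perturbations" in data:
            data["perturbations"] = [
                a if isinstance(a, Action) else Action(**a)
                for a in data["perturbations"]]
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ConfigurationError(f"unknown scenario keys {sorted(bad)}")
        return cls(**data)


@dataclass
class Frame:
    """Per-cell snapshot plus whole-organ aggregates at one recorded step."""

    step: int
    time_h: float
    cells: pd.DataFrame                 # one row per cell
    n_cells: int
    total_area: float
    total_auxin: float
    mean_cell_auxin: float
    root_length: float
    root_width: float
    ledger: Dict[str, float]


@dataclass
class SimulationTrace:
    config: ScenarioConfig
    params: Parameters
    frames: List[Frame] = field(default_factory=list)
    divisions: List[Dict[str, Any]] = field(default_factory=list)
    final: Optional[CellComplex] = None
    aborted: bool = False

    @property
    def last(self) -> Frame:
        return self.frames[-1]


class Simulation:
    """Owns the coupled state of one run; see the module docstring for the
    per-step stage order."""

    def __init__(self, config: ScenarioConfig):
        self.config = config
        self.params = Parameters.from_dict(config.overrides)
        self.params.polarity.mechanism = config.mechanism
        if config.mesh_path:
            from .cell_complex import load_mesh
            self.cx = load_mesh(config.mesh_path)
        else:
            self.cx = build_synthetic_root_template(config.template)
            if config.mode == "coupled":
                transport.initialize_carriers(self.cx, self.params.transport)
        self.rng = np.random.default_rng(config.seed)
        for a in config.perturbations:
            if a.step > config.steps or a.step < 0:
                raise ConfigurationError(
                    f"perturbation {a.kind!r} at step {a.step} is outside the run")
        self.step_index = 0
        self.pulses: List[Tuple[int, int, float]] = []   # (start, end, rate)
        self.no_reflux = False
        self.ledger: Dict[str, float] = {
            "production": 0.0, "degradation": 0.0,
            "boundary_out": 0.0, "clamped": 0.0}
        self.initial_auxin = self.cx.total_auxin(
            self.params.transport.wall_thickness)
        if config.mode == "mechanics_only":
            for cell in self.cx.cells.values():
                cell.growth_factor = config.growth_factors.get(cell.region, 1.0)
        self.pinned, self.y_pinned = attachment_vertices(
            self.cx, center_half_width=self.config.template.cell_width)
        self.y_pin_values = self.cx.vertices[self.y_pinned, 1].copy()
        self._bind_mesh()
        self.trace = SimulationTrace(config=config, params=self.params)
        self._record()

    # ----------------------------------------------------------------- setup
    def _bind_mesh(self) -> None:
        """(Re)build solver state and caches after any topology change."""
        mech = self.params.mechanics
        self.state = pbd.PbdState.from_complex(
            self.cx, self.pinned, iterations=mech.iterations, dt=mech.dt)
        self.cset = pbd.build_constraints(self.cx, mech)
        self.nmap = transport.build_wall_neighbor_map(self.cx)
        if self.config.mode == "mechanics_only":
            self._apply_mech_only_stiffness()
        if self.no_reflux:
            self._apply_no_reflux()

    def _apply_mech_only_stiffness(self) -> None:
        """Prescribed-growth mode: wall stiffness encodes the growth rate.

        Fast-growing tissue has relaxed walls (``mech_only_wall_k``); slower
        tissue is stiffer in inverse square proportion, so a slow region
        mechanically resists deformation by its fast neighbor - the
        essence of the differential-growth constraint.
        """
        f_max = max((c.growth_factor for c in self.cx.cells.values()),
                    default=1.0)
        base = self.config.mech_only_wall_k
        k_cell = {c.id: min(1.0, base * (f_max / max(c.growth_factor, 1e-6)) ** 2)
                  for c in self.cx.cells.values()}
        for c in self.cset.distance:
            if c.wall >= 0:
                cells = self.cx.walls[c.wall].cells
                c.k_ext = sum(k_cell[cid] for cid in cells) / len(cells)

    # ----------------------------------------------------------------- steps
    def advance(self, n: int = 1) -> None:
        for _ in range(n):
            self._one_step()

    def _one_step(self) -> None:
        cfg, p = self.config, self.params
        dt = p.mechanics.dt
        coupled = cfg.mode == "coupled"
        # (1) mechanics
        areas_before = {cid: self.cx.cell_area(cid) for cid in self.cx.cells}
        wall_len_before = {w.id: self.cx.edge_length(w.v1, w.v2)
                           for w in self.cx.walls.values()}
        if coupled:
            pbd.refresh_wall_stiffness(self.cset, self.cx)
        pbd.refresh_strain_stiffness(self.cset, self.cx, p.mechanics.k_strain_max)
        pbd.refresh_bending_rests(self.cset, self.cx)
        pbd.set_pressure_targets(self.cset, self.cx, dt, p.mechanics.growth_drive)
        try:
            pbd.pbd_step(self.state, self.cset, dt=dt,
                         damping=p.mechanics.velocity_damping)
        except SolverDivergenceError:
            self.trace.aborted = True
            self._record(force=True)
            raise
        if self.y_pinned:
            self.cx.vertices[self.y_pinned, 1] = self.y_pin_values
        self._dilute(areas_before, wall_len_before)
        # (2) strain + anisotropy
        pbd.measure_strain(self.cx)
        for cell in self.cx.cells.values():
            update_af(cell, self.cx, p.anisotropy, p.anisotropy.af_dt)
        pbd.relax_rest_lengths(self.cset, self.cx, p.mechanics.plastic_yield, dt)
        if coupled:
            # (3) chemistry substeps
            geom_cache = transport.TransportGeometry(self.cx)
            extra = self._pulse_map()
            sub_dt = dt / p.transport.substeps
            for _ in range(p.transport.substeps):
                transport.transport_substep(
                    self.cx, p.transport, p.boundary, sub_dt, self.nmap,
                    pin_sens=None, extra_synthesis=extra, geom=geom_cache,
                    ledger=self.ledger)
            # (4) polarity + PIN trafficking
            fluxes = transport.compute_fluxes(self.cx, p.transport, geom_cache)
            for cell in self.cx.cells.values():
                geom = self.cx.cell_geometry(cell.id)
                if p.polarity.mechanism == "regulator_polarizer":
                    step_regulator_polarizer(self.cx, cell, geom, p.polarity,
                                             dt, self.rng, fluxes)
                br = compute_cell_polarity(self.cx, cell, geom, p.polarity,
                                           p.anisotropy, fluxes)
                transport.traffic_pin(self.cx, cell, br.pins, p.transport, dt)
            # (5) wall stiffness refresh
            update_cell_wall_stiffness(self.cx, p.growth)
        # (6) divisions
        changed = False
        qc_y = self._qc_y()
        axis_x = self._axis_x()
        for cell in list(self.cx.cells.values()):
            if cell.id not in self.cx.cells:
                continue
            event = check_and_divide(self.cx, cell, p.growth, self.rng,
                                     qc_y=qc_y, axis_x=axis_x)
            if event is None:
                continue
            try:
                d1, d2 = apply_division(self.cx, event)
            except MeshError:
                continue
            changed = True
            self.trace.divisions.append({
                "step": self.step_index, "parent": event.cell,
                "daughters": (d1, d2),
                "types": (self.cx.cells[d1].cell_type,
                          self.cx.cells[d2].cell_type),
                "y": float(self.cx.cell_geometry(d1).centroid[1]),
            })
        if changed:
            self.cx.validate(strict=False)
            self._bind_mesh()
        # (7) scheduled perturbations
        for action in self.config.perturbations:
            if action.step == self.step_index:
                self.perturb(action)
        self.step_index += 1
        # (8) recording
        if self.step_index % self.config.record_every == 0 \
                or self.step_index == self.config.steps:
            self._record()

    def _dilute(self, areas_before: Dict[int, float],
                wall_len_before: Dict[int, float]) -> None:
        """Growth dilutes concentrations: amounts are conserved while the
        compartment areas change with the achieved deformation."""
        for cid, a_old in areas_before.items():
            cell = self.cx.cells.get(cid)
            if cell is None:
                continue
            a_new = self.cx.cell_area(cid)
            if a_new > 0:
                f = a_old / a_new
                cell.iaa *= f
                cell.pin_c *= f
                cell.aux1_c *= f
                cell.reg_c *= f
                cell.pol_c *= f
        for wid, l_old in wall_len_before.items():
            wall = self.cx.walls.get(wid)
            if wall is None:
                continue
            l_new = self.cx.edge_length(wall.v1, wall.v2)
            if l_new > 0:
                wall.iaa *= l_old / l_new

    def _pulse_map(self) -> Optional[Dict[int, float]]:
        rate = 0.0
        for start, end, r in self.pulses:
            if start <= self.step_index < end:
                rate += r
        if rate == 0.0:
            return None
        return {cid: rate for cid in self.cx.cells}

    def _qc_y(self) -> Optional[float]:
        qcs = self.cx.cells_of_type("QC")
        if not qcs:
            return float(np.min(self.cx.vertices[:, 1]))
        return float(np.mean([self.cx.cell_geometry(c.id).centroid[1]
                              for c in qcs]))

    def _axis_x(self) -> float:
        used = [v for c in self.cx.cells.values() for v in c.ring]
        return float(np.mean(self.cx.vertices[used, 0]))

    # ----------------------------------------------------------- perturbations
    def perturb(self, action: Action) -> None:
        """Apply one perturbation action to the live state."""
        kind = action.kind
        pr = action.params
        if action.step > self.config.steps:
            raise ConfigurationError(
                f"perturbation {kind!r} scheduled beyond the end of the run")
        if kind == "pin2_knockdown":
            f = pr.get("factor", 0.1)
            for cell in self.cx.cells_of_type("LRC", "Epidermis", "Cortex",
                                              "EpidermisLRCInitial"):
                cell.knockdown["PIN"] = f
        elif kind == "vascular_pin_knockdown":
            f = pr.get("factor", 0.1)
            for cell in self.cx.cells_of_type("Vascular", "VascularInitial",
                                              "Source"):
                cell.knockdown["PIN"] = f
        elif kind == "aux1_knockdown":
            f = 1.0 - pr.get("reduction", 0.9)
            for cell in self.cx.cells.values():
                cell.knockdown["AUX1"] = f
        elif kind == "qc_ablation":
            self._remove_cells([c.id for c in self.cx.cells_of_type("QC")])
        elif kind == "lrc_removal":
            self._remove_cells([c.id for c in self.cx.cells_of_type("LRC")])
        elif kind == "tip_excision":
            y_cut = pr.get("y_cut")
            if y_cut is None:
                qcs = self.cx.cells_of_type("QC")
                if qcs:
                    y_cut = max(float(np.max(self.cx.vertices[c.ring, 1]))
                                for c in qcs)
                else:
                    y_cut = float(np.min(self.cx.vertices[:, 1]))
            doomed = [cid for cid in self.cx.cells
                      if self.cx.cell_geometry(cid).centroid[1] < y_cut]
            self._remove_cells(doomed)
        elif kind == "oryzalin":
            self.params.anisotropy.d_AF *= pr.get("factor", 200.0)
        elif kind == "auxin_pulse":
            dur = int(pr.get("duration_steps", 300))
            self.pulses.append((self.step_index, self.step_index + dur,
                                pr.get("rate", 8.0)))
        elif kind == "no_reflux":
            self.no_reflux = True
            self._apply_no_reflux()
        elif kind == "source_removal":
            for cell in self.cx.cells_of_type("Source"):
                cell.cell_type = "Vascular"
        elif kind == "qc_synthesis":
            b = pr.get("b_IAA", 10.0)
            for cell in self.cx.cells_of_type("QC"):
                cell.b_iaa = b
        else:
            raise ConfigurationError(f"unknown perturbation {kind!r}")

    def _apply_no_reflux(self) -> None:
        """Disable carrier fluxes across epidermis/LRC <-> cortex walls."""
        for wall in self.cx.walls.values():
            if len(wall.cells) != 2:
                continue
            t1 = self.cx.cells[wall.cells[0]].cell_type
            t2 = self.cx.cells[wall.cells[1]].cell_type
            lateral = (t1 in _EPI_GROUP and t2 == "Cortex") or \
                      (t2 in _EPI_GROUP and t1 == "Cortex")
            if lateral:
                wall.no_flux = True

    def _remove_cells(self, cell_ids: Sequence[int]) -> None:
        if not cell_ids:
            return
        for cid in cell_ids:
            del self.cx.cells[cid]
        self.cx.rebuild_walls(preserve=True)
        self.cx.validate(strict=False)
        self._bind_mesh()

    # -------------------------------------------------------------- recording
    def _record(self, force: bool = False) -> None:
        cx = self.cx
        rows = []
        axis_x = self._axis_x()
        for cell in cx.cells.values():
            geom = cx.cell_geometry(cell.id)
            pin_root = pin_shoot = pin_lat = 0.0
            pins = []
            for s in geom.sections:
                pin = cx.walls[s.wall].sides[cell.id].pin
                pins.append(pin)
                if s.normal[1] < -0.5:
                    pin_root += pin
                elif s.normal[1] > 0.5:
                    pin_shoot += pin
                else:
                    pin_lat += pin
            total_pin = sum(pins)
            if total_pin > 0:
                ps = [x / total_pin for x in pins if x > 0]
                entropy = -sum(x * math.log(x) for x in ps)
                entropy /= math.log(len(pins)) if len(pins) > 1 else 1.0
                dominant = max(pin_root, pin_shoot, pin_lat) / total_pin
            else:
                entropy = 1.0
                dominant = 0.0
            af_mag = float(np.linalg.norm(cell.af))
            rows.append({
                "id": cell.id, "type": cell.cell_type, "region": cell.region,
                "x": geom.centroid[0], "y": geom.centroid[1],
                "area": geom.area, "iaa": cell.iaa,
                "pin_c": cell.pin_c, "aux1_c": cell.aux1_c,
                "af_mag": af_mag, "aspect": geom.aspect_ratio,
                "pin_mem_total": total_pin,
                "pin_rootward": pin_root, "pin_shootward": pin_shoot,
                "pin_lateral": pin_lat,
                "pin_dominant_frac": dominant, "pin_entropy": entropy,
                "vascular": cell.cell_type in VASCULAR_GROUP,
            })
        df = pd.DataFrame(rows)
        used = sorted({v for c in cx.cells.values() for v in c.ring})
        vs = cx.vertices[used]
        frame = Frame(
            step=self.step_index,
            time_h=self.step_index * self.params.mechanics.dt,
            cells=df,
            n_cells=len(cx.cells),
            total_area=float(df["area"].sum()) if len(df) else 0.0,
            total_auxin=cx.total_auxin(self.params.transport.wall_thickness),
            mean_cell_auxin=float(df["iaa"].mean()) if len(df) else 0.0,
            root_length=float(vs[:, 1].max() - vs[:, 1].min()) if len(vs) else 0.0,
            root_width=float(vs[:, 0].max() - vs[:, 0].min()) if len(vs) else 0.0,
            ledger=dict(self.ledger),
        )
        self.trace.frames.append(frame)

    def finish(self) -> SimulationTrace:
        if self.trace.frames[-1].step != self.step_index:
            self._record(force=True)
        self.trace.final = self.cx
        return self.trace


def run(config: ScenarioConfig) -> SimulationTrace:
    """Run a scenario to completion; bit-reproducible for a fixed seed."""
    sim = Simulation(config)
    sim.advance(config.steps)
    return sim.finish()


def mechanics_only(config: ScenarioConfig) -> SimulationTrace:
    """Run the purely mechanical model with prescribed per-region growth.

    Cells grow at ``growth_drive * growth_factors[region]`` areal demand;
    if ``relax_at`` is set, the differential between regions is abolished at
    that step (all factors set to the maximum), probing whether established
    anisotropy persists without the differential.
    """
    config = copy.deepcopy(config)
    config.mode = "mechanics_only"
    sim = Simulation(config)
    if config.relax_at is not None:
        sim.advance(config.relax_at)
        top = max(config.growth_factors.values())
        for cell in sim.cx.cells.values():
            cell.growth_factor = top
        sim._apply_mech_only_stiffness()
        sim.advance(config.steps - config.relax_at)
    else:
        sim.advance(config.steps)
    return sim.finish()


def sweep(config: ScenarioConfig, parameter: str,
          values: Sequence[float]) -> Dict[float, Dict[str, pd.DataFrame]]:
    """One full run per parameter value (shared seed); returns metric tables."""
    out: Dict[float, Dict[str, pd.DataFrame]] = {}
    for v in values:
        cfg = copy.deepcopy(config)
        block, _, key = parameter.partition(".")
        cfg.overrides.setdefault(block, {})[key] = v
        out[v] = metrics(run(cfg))
    return out


def pin_relocalization_experiment(params: Optional[Parameters] = None,
                                  supply: float = 1.0,
                                  settle_h: float = 40.0,
                                  max_h: float = 20.0) -> Dict[str, float]:
    """PIN relocalization kinetics on the new wall after a division.

    A static three-cell column (auxin supplied at the top cell, exported
    from the bottom cell) is run with the flux mechanism until the polar
    field is steady; the wall between the middle and bottom cell is then
    reset to the fresh post-division state (no membrane carriers at all),
    and the middle cell's polar-face PIN is followed until it regains 95%
    of its steady value.  Returns the steady level and the recovery time in
    simulated hours.
    """
    from .cell_complex import CellComplex

    p = params.copy() if params else Parameters()
    p.polarity.mechanism = "flux"
    dt = p.mechanics.dt
    cx = CellComplex()
    vs = cx.add_vertices([[0, 0], [8, 0], [8, 8], [0, 8], [8, 16], [0, 16],
                          [8, 24], [0, 24]])
    bottom = cx.new_cell("Vascular", [vs[0], vs[1], vs[2], vs[3]])
    middle = cx.new_cell("Vascular", [vs[3], vs[2], vs[4], vs[5]])
    top = cx.new_cell("Vascular", [vs[5], vs[4], vs[6], vs[7]])
    cx.rebuild_walls(preserve=False)
    cx.add_centers()
    top.b_iaa = supply                      # shoot-side auxin supply
    transport.initialize_carriers(cx, p.transport)
    nmap = transport.build_wall_neighbor_map(cx)
    new_wall = cx.wall_between(middle.id, bottom.id)[0]
    sink_rate = 1.0                         # bottom cell exports rootward
    rng = np.random.default_rng(0)

    def one_step():
        geom_cache = transport.TransportGeometry(cx)
        sub = dt / p.transport.substeps
        for _ in range(p.transport.substeps):
            transport.transport_substep(cx, p.transport, None, sub, nmap,
                                        geom=geom_cache)
            bottom.iaa = max(0.0, bottom.iaa - sub * sink_rate * bottom.iaa)
        fluxes = transport.compute_fluxes(cx, p.transport, geom_cache)
        for cell in cx.cells.values():
            geom = cx.cell_geometry(cell.id)
            br = compute_cell_polarity(cx, cell, geom, p.polarity,
                                       p.anisotropy, fluxes)
            transport.traffic_pin(cx, cell, br.pins, p.transport, dt)

    for _ in range(int(settle_h / dt)):
        one_step()
    steady = new_wall.sides[middle.id].pin
    # the division leaves the new wall without any membrane carriers
    for side in new_wall.sides.values():
        side.pin = side.aux1 = side.reg = side.pol = 0.0
    new_wall.iaa = 0.0
    t95 = math.nan
    for i in range(int(max_h / dt)):
        one_step()
        if new_wall.sides[middle.id].pin >= 0.95 * steady:
            t95 = (i + 1) * dt
            break
    return {"steady_pin": steady, "t95_h": t95,
            "middle_iaa": middle.iaa}


# ------------------------------------------------------------------- metrics

def longitudinal_profile(frame: Frame, bins: int = 20) -> pd.DataFrame:
    """Bin cells along the root axis: auxin by tissue group, PIN polarity.

    Source and Sink cells are excluded - they are the boundary stand-in for
    the shoot, not root tissue.
    """
    df = frame.cells
    df = df[~df["type"].isin(("Source", "Sink"))]
    if df.empty:
        return pd.DataFrame()
    lo, hi = df["y"].min(), df["y"].max()
    edges = np.linspace(lo, hi + 1e-9, bins + 1)
    idx = np.clip(np.digitize(df["y"], edges) - 1, 0, bins - 1)
    out = []
    for b in range(bins):
        sel = df[idx == b]
        vasc = sel[sel["vascular"]]
        nonv = sel[~sel["vascular"]]
        out.append({
            "bin": b,
            "y_center": 0.5 * (edges[b] + edges[b + 1]),
            "n_cells": len(sel),
            "auxin_mean": sel["iaa"].mean() if len(sel) else np.nan,
            "auxin_vascular": vasc["iaa"].mean() if len(vasc) else np.nan,
            "auxin_nonvascular": nonv["iaa"].mean() if len(nonv) else np.nan,
            "pin_entropy": sel["pin_entropy"].mean() if len(sel) else np.nan,
            "area": sel["area"].sum(),
        })
    return pd.DataFrame(out)


def growth_rate_profile(trace: SimulationTrace, bins: int = 20,
                        start_frac: float = 0.0) -> pd.DataFrame:
    """Per-cell relative areal growth rate binned along the root axis (1/h).

    Growth is measured between consecutive recorded frames on cells present
    in both (cells that divided in between are attributed via their
    daughters' summed area), then averaged over the selected frames.
    """
    frames = [f for f in trace.frames
              if f.step >= start_frac * trace.frames[-1].step]
    if len(frames) < 2:
        return pd.DataFrame()
    daughters: Dict[int, Tuple[int, int]] = {
        ev["parent"]: tuple(ev["daughters"]) for ev in trace.divisions}
    acc = np.zeros(bins)
    cnt = np.zeros(bins)
    lo = min(f.cells["y"].min() for f in frames)
    hi = max(f.cells["y"].max() for f in frames) + 1e-9
    edges = np.linspace(lo, hi, bins + 1)
    for f0, f1 in zip(frames[:-1], frames[1:]):
        dt = f1.time_h - f0.time_h
        if dt <= 0:
            continue
        a1 = dict(zip(f1.cells["id"], f1.cells["area"]))

        def area_now(cid: int) -> Optional[float]:
            if cid in a1:
                return a1[cid]
            if cid in daughters:
                parts = [area_now(d) for d in daughters[cid]]
                if all(p is not None for p in parts):
                    return sum(parts)
            return None

        for _, row in f0.cells.iterrows():
            a_new = area_now(int(row["id"]))
            if a_new is None or row["area"] <= 0:
                continue
            b = int(np.clip(np.digitize(row["y"], edges) - 1, 0, bins - 1))
            acc[b] += (a_new - row["area"]) / row["area"] / dt
            cnt[b] += 1
    centers = 0.5 * (edges[:-1] + edges[1:])
    rate = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return pd.DataFrame({"bin": np.arange(bins), "y_center": centers,
                         "growth_rate": rate, "n_obs": cnt})


def division_profile(trace: SimulationTrace, bins: int = 20) -> pd.DataFrame:
    """Division counts per longitudinal bin (positions at division time)."""
    if not trace.frames:
        return pd.DataFrame()
    df = trace.frames[-1].cells
    lo, hi = df["y"].min(), df["y"].max()
    edges = np.linspace(lo, hi + 1e-9, bins + 1)
    counts = np.zeros(bins, dtype=int)
    for ev in trace.divisions:
        b = int(np.clip(np.digitize(ev["y"], edges) - 1, 0, bins - 1))
        counts[b] += 1
    return pd.DataFrame({"bin": np.arange(bins), "divisions": counts})


def timeseries(trace: SimulationTrace) -> pd.DataFrame:
    """Whole-organ time series: size, growth rate, auxin, polarity summary."""
    rows = []
    prev = None
    for f in trace.frames:
        growth = np.nan
        if prev is not None and f.time_h > prev.time_h and prev.total_area > 0:
            growth = (f.total_area - prev.total_area) / prev.total_area / \
                (f.time_h - prev.time_h)
        rows.append({
            "step": f.step, "time_h": f.time_h, "n_cells": f.n_cells,
            "total_area": f.total_area, "growth_rate": growth,
            "mean_cell_auxin": f.mean_cell_auxin,
            "total_auxin": f.total_auxin,
            "root_length": f.root_length, "root_width": f.root_width,
            "mean_af": f.cells["af_mag"].mean() if len(f.cells) else np.nan,
            "mean_pin_entropy": f.cells["pin_entropy"].mean()
            if len(f.cells) else np.nan,
        })
        prev = f
    return pd.DataFrame(rows)


def mass_ledger_residual(trace: SimulationTrace,
                         initial_auxin: Optional[float] = None) -> float:
    """Relative closure error of the auxin mass balance:
    storage change minus (production - degradation - boundary + clamping)."""
    first, last = trace.frames[0], trace.frames[-1]
    led0, led1 = first.ledger, last.ledger
    flows = (led1["production"] - led0["production"]) \
        - (led1["degradation"] - led0["degradation"]) \
        - (led1["boundary_out"] - led0["boundary_out"]) \
        + (led1["clamped"] - led0["clamped"])
    dstorage = last.total_auxin - first.total_auxin
    scale = max(abs(led1["production"] - led0["production"]),
                abs(dstorage), 1e-12)
    return abs(dstorage - flows) / scale


def metrics(trace: SimulationTrace) -> Dict[str, pd.DataFrame]:
    """The standard metric tables of a run."""
    last = trace.frames[-1]
    return {
        "timeseries": timeseries(trace),
        "profile": longitudinal_profile(last),
        "growth_profile": growth_rate_profile(trace),
        "division_profile": division_profile(trace),
    }
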