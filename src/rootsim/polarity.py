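"""PIN sensitivity and the two auxin-feedback polarization mechanisms.

Every membrane section of a cell carries a "PIN sensitivity" - the fraction
of cytoplasmic PIN trafficked to it.  Raw sensitivities combine the
anisotropy factor (IAF), the auxin-flow input (IP) and cell geometry (IG),

    PinSR_mem = kAF IAF + kP IP + kAFP (IAF + IP) + kG IG,

and are normalized with a softmax so each cell's sensitivities sum to 1.
Columella-type cells bypass the computation and traffic PIN uniformly
(PIN3-like behavior).

The IP term comes from one of two interchangeable mechanisms:

* auxin-flux ("with the flux"): the cell senses its net auxin-flux vector
  and boosts the sections whose outward normal aligns with it;
* regulator-polarizer: a molecular realization of flux sensing - an
  auxin-activated membrane regulator displaces a PIN-recruiting polarizer
  toward the membrane side with the least regulator, where the polarizer
  promotes PIN recruitment.  Polarizer displacement is the only stochastic
  element of the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .anisotropy import af_contribution, geometry_contribution
from .cell_complex import (COLUMELLA_TYPES, Cell, CellComplex, CellGeometry,
                           MembraneSection)
from .params import AnisotropyParams, PolarityParams
from .transport import FluxMap

__all__ = [
    "SensitivityBreakdown",
    "pin_sensitivity",
    "flux_vector",
    "flux_contribution",
    "grad_mem",
    "step_regulator_polarizer",
    "polarizer_contribution",
    "compute_cell_polarity",
]


@dataclass
class SensitivityBreakdown:
    """Per-section sensitivity inputs of one cell (wall id keyed)."""

    iaf: Dict[int, float] = field(default_factory=dict)
    ip: Dict[int, float] = field(default_factory=dict)
    ig: Dict[int, float] = field(default_factory=dict)
    raw: Dict[int, float] = field(default_factory=dict)
    pins: Dict[int, float] = field(default_factory=dict)
    flux_vec: np.ndarray = field(default_factory=lambda: np.zeros(2))


def pin_sensitivity(cell: Cell, raw: Dict[int, float]) -> Dict[int, float]:
    """Softmax-normalize raw sensitivities; uniform for columella types."""
    m = len(raw)
    if m == 0:
        return {}
    if cell.cell_type in COLUMELLA_TYPES:
        return {w: 1.0 / m for w in raw}
    mx = max(raw.values())
    exps = {w: math.exp(v - mx) for w, v in raw.items()}
    total = sum(exps.values())
    return {w: e / total for w, e in exps.items()}


def flux_vector(cell: Cell, geom: CellGeometry, fluxes: FluxMap) -> np.ndarray:
    """Net auxin-flux vector of the cell: unit centroid-to-midpoint vectors
    weighted by the net auxin throughput (E - I) of each membrane section.

    The vector points along the direction auxin is moving through the cell
    (imports on the upstream side and exports on the downstream side both
    push it downstream), which is what the with-the-flux positive feedback
    amplifies: PIN is then recruited to the faces the flux exits through.
    """
    total = np.zeros(2)
    c = geom.centroid
    for s in geom.sections:
        imp, exp = fluxes[(s.wall, cell.id)]
        d = s.midpoint - c
        norm = math.hypot(d[0], d[1])
        if norm < 1e-12:
            continue
        total += (d / norm) * (exp - imp)
    return total


def flux_contribution(flux_vec: np.ndarray, section: MembraneSection,
                      params: PolarityParams) -> float:
    """Auxin-flow input of the flux mechanism for one section.

    F_mem = (FLUX_cell . n_mem) L_mem, clamped at zero from below (only
    outward-aligned flux polarizes; the quartic is sign-blind, so without
    the clamp the upstream face would be boosted equally);
    IP = F^4 / (F^4 + Kflux^4).
    """
    F = float(flux_vec @ section.normal) * section.length
    if F <= 0.0:
        return 0.0
    f4 = F ** 4
    return f4 / (f4 + params.Kflux ** 4)


def grad_mem(cell: Cell, geom: CellGeometry, fluxes: FluxMap,
             params: PolarityParams) -> Dict[int, float]:
    """Auxin influx-efflux metric driving regulator trafficking.

    Grad_mem = [ (I-E)_mem + sum_i (I-E)_i / distance(mem, mem_i) ]
               * 1000 / A_cell,

    with midpoint-to-midpoint Euclidean distances (floored at eps_dist) and
    an amplification factor of 1000.
    """
    sections = geom.sections
    nets = [fluxes[(s.wall, cell.id)][0] - fluxes[(s.wall, cell.id)][1]
            for s in sections]
    out: Dict[int, float] = {}
    for i, s in enumerate(sections):
        total = nets[i]
        for j, sj in enumerate(sections):
            if j == i:
                continue
            d = sj.midpoint - s.midpoint
            dist = max(math.hypot(d[0], d[1]), params.eps_dist)
            total += nets[j] / dist
        out[s.wall] = total * 1000.0 / geom.area
    return out


def polarizer_contribution(pol_mem: float, params: PolarityParams) -> float:
    """IP of the regulator-polarizer mechanism: Hill(4) in membrane polarizer."""
    p4 = pol_mem ** 4
    denom = p4 + params.Kpol_IP ** 4
    return p4 / denom if denom > 0 else 0.0


def _hill2(x: float, k: float) -> float:
    x2 = x * x
    denom = x2 + k * k
    return x2 / denom if denom > 0 else 0.0


def _hill4(x: float, k: float) -> float:
    x4 = x ** 4
    denom = x4 + k ** 4
    return x4 / denom if denom > 0 else 0.0


def step_regulator_polarizer(cx: CellComplex, cell: Cell, geom: CellGeometry,
                             params: PolarityParams, dt: float,
                             rng: np.random.Generator,
                             fluxes: FluxMap) -> None:
    """One Euler update of the regulator-polarizer system of a cell.

    Cytoplasmic pools are produced and degraded at constant rates and lose
    material to auxin-gated membrane trafficking (the regulator's trafficking
    is additionally boosted by the influx-efflux metric Grad_mem).  Membrane
    pools diffuse along the ring of sections, degrade, and the polarizer is
    stochastically displaced: each section reserves a batch
    Kdisp_POL * POL_mem * dt, a random ring neighbor is drawn, and the batch
    moves there only if that neighbor holds less regulator.  Displacement
    and diffusion conserve the membrane totals exactly.
    """
    sections = geom.sections
    m = len(sections)
    if m == 0:
        return
    grads = grad_mem(cell, geom, fluxes, params)
    total_L = sum(s.length for s in sections)
    iaa = cell.iaa
    reg_gate = _hill2(iaa, params.Kreg_IAA)
    pol_gate = _hill2(iaa, params.Kpol_IAA)

    reg0 = [cx.walls[s.wall].sides[cell.id].reg for s in sections]
    pol0 = [cx.walls[s.wall].sides[cell.id].pol for s in sections]

    # trafficking rates per section (also the cytoplasmic losses)
    reg_traffic = []
    pol_traffic = []
    for s in sections:
        share = s.length / total_L
        # only net auxin import is detected (the quartic is sign-blind, so
        # negative Grad_mem is clamped out, as for the flux projection)
        kreg = params.Kreg_tr + params.Kreg_GradT * \
            _hill4(max(grads[s.wall], 0.0), params.Kreg_GradK)
        reg_traffic.append(cell.reg_c * kreg * share * reg_gate)
        pol_traffic.append(cell.pol_c * params.Kpol_tr * share * pol_gate)

    # cytoplasm
    cell.reg_c = max(0.0, cell.reg_c + dt * (
        params.b_REG - sum(reg_traffic) - params.d_REG * cell.reg_c))
    cell.pol_c = max(0.0, cell.pol_c + dt * (
        params.b_POL - sum(pol_traffic) - params.d_POL * cell.pol_c))

    # membranes: trafficking + ring diffusion + degradation (Jacobi)
    reg1 = []
    pol1 = []
    for i in range(m):
        dreg = params.D_reg * ((reg0[(i - 1) % m] - reg0[i]) +
                               (reg0[(i + 1) % m] - reg0[i]))
        dpol = params.D_pol * ((pol0[(i - 1) % m] - pol0[i]) +
                               (pol0[(i + 1) % m] - pol0[i]))
        reg1.append(max(0.0, reg0[i] + dt * (
            reg_traffic[i] + dreg - params.d_REG * reg0[i])))
        pol1.append(max(0.0, pol0[i] + dt * (
            pol_traffic[i] + dpol - params.d_POL * pol0[i])))

    # stochastic polarizer displacement toward the regulator-poor neighbor
    moves = [0.0] * m
    for i in range(m):
        batch = min(params.Kdisp_POL * pol1[i] * dt, pol1[i])
        if batch <= 0.0:
            continue
        j = (i + (1 if rng.random() < 0.5 else -1)) % m
        if reg1[j] < reg1[i]:
            moves[i] -= batch
            moves[j] += batch
    for i, s in enumerate(sections):
        side = cx.walls[s.wall].sides[cell.id]
        side.reg = reg1[i]
        side.pol = pol1[i] + moves[i]


def compute_cell_polarity(cx: CellComplex, cell: Cell, geom: CellGeometry,
                          pol: PolarityParams, aniso: AnisotropyParams,
                          fluxes: FluxMap) -> SensitivityBreakdown:
    """Assemble the per-section sensitivity inputs and the softmax weights.

    The IP input is taken from the configured mechanism: the flux projection
    (auxin-flux) or the membrane polarizer level (regulator-polarizer, which
    must have been stepped beforehand).  With ``af_to_pin`` disabled the IAF
    input is removed from the raw combination entirely.
    """
    br = SensitivityBreakdown()
    if pol.mechanism == "flux":
        br.flux_vec = flux_vector(cell, geom, fluxes)
    for s in geom.sections:
        iaf = af_contribution(cell.af, s, aniso) if pol.af_to_pin else 0.0
        ig = geometry_contribution(geom, s, aniso)
        if pol.mechanism == "flux":
            ip = flux_contribution(br.flux_vec, s, pol)
        else:
            ip = polarizer_contribution(cx.walls[s.wall].sides[cell.id].pol, pol)
        if pol.interaction == "product":
            inter = pol.kAFP * iaf * ip
        else:
            inter = pol.kAFP * (iaf + ip)
        raw = pol.kAF * iaf + pol.kP * ip + inter + pol.kG * ig
        br.iaf[s.wall] = iaf
        br.ip[s.wall] = ip
        br.ig[s.wall] = ig
        br.raw[s.wall] = raw
    br.pins = pin_sensitivity(cell, br.raw)
    return br
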