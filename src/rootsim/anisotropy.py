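"""Anisotropy-factor (AF) dynamics.

The AF is an abstract per-cell vector summarizing cytoskeleton and wall
anisotropy (cortical microtubules, cellulose microfibrils).  Wall strain
reorients it: when the largest wall strain of a cell exceeds a threshold, a
non-polar cell seeds its AF perpendicular to the most-strained wall segment
(microtubules orient orthogonal to maximal strain), and an existing AF grows
along its own direction in proportion to the strain of aligned wall
segments, balanced by first-order decay.  |AF| is clamped to 1; it scales
the strain constraint of the mechanics (restricting growth along the AF)
and contributes to PIN trafficking sensitivity.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .cell_complex import Cell, CellComplex, CellGeometry, MembraneSection
from .params import AnisotropyParams

__all__ = ["update_af", "af_contribution", "geometry_contribution"]

_EPS = 1e-9


def update_af(cell: Cell, cx: CellComplex, params: AnisotropyParams, dt: float,
              geom: Optional[CellGeometry] = None) -> np.ndarray:
    """One discrete AF update; returns (and stores) the new AF vector.

    af' = af + dt * [ R_AF * sum_i u(af) |(u(af) . u(mem_i)) eps_i| - d_AF af ]

    The reorientation sum runs only when the maximum wall strain of the cell
    reaches ``strain_threshold``; below it only the decay term acts.  A cell
    with zero-length AF seeds its direction perpendicular to the
    maximal-strain segment.  |af'| is clamped to 1.
    """
    geom = geom or cx.cell_geometry(cell.id)
    strains = [cx.walls[s.wall].strain for s in geom.sections]
    af = np.asarray(cell.af, dtype=float)
    mag = math.hypot(af[0], af[1])
    max_strain = max(strains) if strains else 0.0
    if max_strain >= params.strain_threshold:
        if mag < _EPS:
            # seed orthogonal to the most strained segment
            k = int(np.argmax(strains))
            u_seed = geom.sections[k].normal
            af = (dt * params.R_AF * max_strain) * u_seed
            mag = math.hypot(af[0], af[1])
        if mag >= _EPS:
            u_af = af / mag
            total = 0.0
            for s, eps in zip(geom.sections, strains):
                total += abs(float(u_af @ s.direction) * eps)
            af = af + dt * (params.R_AF * total * u_af - params.d_AF * af)
    else:
        af = af * (1.0 - dt * params.d_AF)
    mag = math.hypot(af[0], af[1])
    if mag > 1.0:
        af = af / mag
    cell.af = af
    return af


def af_contribution(af: np.ndarray, section: MembraneSection,
                    params: AnisotropyParams) -> float:
    """AF input to PIN sensitivity of one membrane section.

    U = u(af) . n_mem;  IAF = |af| U^4 / (U^4 + Kaf^4).

    Sections whose outward normal aligns with the AF get a saturating boost;
    a non-polar cell (|af| = 0) contributes nothing anywhere.
    """
    mag = math.hypot(af[0], af[1])
    if mag < _EPS:
        return 0.0
    u = af / mag
    U = float(u @ section.normal)
    u4 = U ** 4
    return mag * u4 / (u4 + params.Kaf ** 4)


def geometry_contribution(geom: CellGeometry, section: MembraneSection,
                          params: AnisotropyParams) -> float:
    """Cell-geometry input to PIN sensitivity of one membrane section.

    r = |axisMin| / |axisMax|;
    IG = |u(axisMax) . n_mem| (1-r)^4 / ((1-r)^4 + Kgeom^4).

    Elongated cells favor the sections facing along their long axis; an
    isotropic cell (r = 1) contributes nothing.
    """
    amax = float(np.linalg.norm(geom.axis_max))
    amin = float(np.linalg.norm(geom.axis_min))
    if amax < _EPS:
        return 0.0
    r = amin / amax
    num = (1.0 - r) ** 4
    if num <= 0.0:
        return 0.0
    u = geom.axis_max / amax
    return abs(float(u @ section.normal)) * num / (num + params.Kgeom ** 4)
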