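"""Position-based dynamics (PBD) solver for tissue mechanics.

Each simulation step predicts vertex positions from (optional) external
forces, runs a fixed number of Gauss-Seidel constraint-projection passes and
recovers velocities from the position change.  Five constraint kinds act on
the mesh:

* distance   - elastic cell-wall and cytoskeleton edges, with separate
               extension and compression stiffness;
* shape      - shape matching toward the rest ring shape (cytoskeleton
               integrity, prevents collapse);
* strain     - distance-like stiffening of edges aligned with the cell's
               anisotropy vector, which restricts growth along it;
* bending    - virtual edges across wall corners keeping wall angles near
               their rest configuration;
* pressure   - an XPBD area constraint per cell that drives the polygon
               toward a target area (turgor), with compliance ``alpha/dt^2``.

Stiffness values ``k`` in [0, 1] are corrected for the iteration count with
``k' = 1 - (1 - k)^(1/n)`` so that the converged effect of n passes matches a
single pass at stiffness k.  The solver is quasi-static (velocities damped),
appropriate for turgor-driven growth where inertia is negligible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np

from .cell_complex import CellComplex, NON_GROWING_TYPES
from .errors import GeometryError, SolverDivergenceError
from .params import MechanicsParams

log = logging.getLogger(__name__)

__all__ = [
    "PbdState",
    "DistanceConstraint",
    "BendingConstraint",
    "ShapeConstraint",
    "PressureConstraint",
    "ConstraintSet",
    "effective_stiffness",
    "project_distance",
    "project_bending",
    "project_shape",
    "project_pressure",
    "project_strain",
    "pbd_step",
    "build_constraints",
    "measure_strain",
]


def effective_stiffness(k: float, n: int) -> float:
    """Iteration-count-corrected stiffness ``k' = 1 - (1 - k)^(1/n)``."""
    if not 0.0 <= k <= 1.0:
        raise ValueError("stiffness must be in [0, 1]")
    if n < 1:
        raise ValueError("iteration count must be >= 1")
    return 1.0 - (1.0 - k) ** (1.0 / n)


@dataclass
class PbdState:
    """Vertex state of the solver; ``inv_mass == 0`` pins a vertex."""

    pos: np.ndarray                  # (N, 2)
    prev: np.ndarray
    vel: np.ndarray
    inv_mass: np.ndarray             # (N,)
    iterations: int = 8
    dt: float = 0.02

    @classmethod
    def from_complex(cls, cx: CellComplex, pinned: Sequence[int] = (),
                     iterations: int = 8, dt: float = 0.02) -> "PbdState":
        n = len(cx.vertices)
        w = np.ones(n)
        w[list(pinned)] = 0.0
        return cls(pos=cx.vertices, prev=cx.vertices.copy(),
                   vel=np.zeros((n, 2)), inv_mass=w,
                   iterations=iterations, dt=dt)


@dataclass(slots=True)
class DistanceConstraint:
    """C(p1, p2) = |p1 - p2| - d, with split extension/compression stiffness."""

    i: int
    j: int
    rest: float
    k_ext: float = 1.0
    k_comp: float = 1.0
    wall: int = -1          # owning wall segment, -1 for internal edges
    cell: int = -1          # owning cell (strain constraints), else -1


@dataclass(slots=True)
class BendingConstraint:
    """Virtual edge across a wall corner, restoring the rest opening angle.

    The rest length of the virtual edge i-j is recomputed from the current
    adjacent edge lengths and the stored rest angle at the corner (law of
    cosines), so the constraint is scale-free: uniform growth is unopposed
    while angle drift (wall folding) is resisted.
    """

    i: int
    j: int
    rest: float
    k: float = 0.1
    corner: int = -1
    angle: float = math.pi


@dataclass(slots=True)
class ShapeConstraint:
    """Shape matching of a cell ring to its rest shape (least-squares rigid fit)."""

    ids: List[int]
    rest_rel: np.ndarray    # (m, 2) rest coordinates relative to rest centroid
    k: float = 0.1


@dataclass(slots=True)
class PressureConstraint:
    """XPBD polygon-area constraint driving the cell toward ``target_area``."""

    ids: List[int]
    target_area: float
    compliance: float = 1e-4
    cell: int = -1
    lam: float = 0.0        # XPBD multiplier, reset every step
    min_area: float = 0.0   # turgor floor: crushing below this is resisted


def _polygon_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


# ------------------------------------------------------------------ projections

def project_distance(c: DistanceConstraint, state: PbdState,
                     n_iter: int = 1) -> np.ndarray:
    """Project one distance constraint; returns the applied corrections (2, 2)."""
    p1, p2 = state.pos[c.i], state.pos[c.j]
    d = p1 - p2
    dist = math.hypot(d[0], d[1])
    if dist < 1e-12:
        log.warning("distance constraint %d-%d: coincident points, skipped", c.i, c.j)
        return np.zeros((2, 2))
    C = dist - c.rest
    k = c.k_ext if C > 0 else c.k_comp
    if k <= 0.0 or C == 0.0:
        return np.zeros((2, 2))
    kp = effective_stiffness(k, n_iter)
    w1, w2 = state.inv_mass[c.i], state.inv_mass[c.j]
    wsum = w1 + w2
    if wsum == 0:
        return np.zeros((2, 2))
    grad = d / dist
    dp1 = -(w1 / wsum) * C * grad * kp
    dp2 = +(w2 / wsum) * C * grad * kp
    state.pos[c.i] += dp1
    state.pos[c.j] += dp2
    return np.array([dp1, dp2])


def project_bending(c: BendingConstraint, state: PbdState, n_iter: int = 1) -> None:
    project_distance(
        DistanceConstraint(c.i, c.j, c.rest, k_ext=c.k, k_comp=c.k),
        state, n_iter)


def project_shape(c: ShapeConstraint, state: PbdState, n_iter: int = 1) -> None:
    """Shape matching: move ring vertices toward the best rigid fit of the rest shape."""
    q = state.pos[c.ids]
    qc = q.mean(axis=0)
    qrel = q - qc
    # optimal rotation of rest_rel onto qrel (2D polar decomposition)
    a = qrel.T @ c.rest_rel
    theta = math.atan2(a[1, 0] - a[0, 1], a[0, 0] + a[1, 1])
    ct, st = math.cos(theta), math.sin(theta)
    rot = np.array([[ct, -st], [st, ct]])
    goal = c.rest_rel @ rot.T + qc
    kp = effective_stiffness(c.k, n_iter)
    movable = state.inv_mass[c.ids] > 0
    state.pos[np.asarray(c.ids)[movable]] += kp * (goal - q)[movable]


def project_pressure(c: PressureConstraint, state: PbdState, dt: float) -> None:
    """One XPBD pass of the area constraint C = A - A_target."""
    ids = c.ids
    pts = state.pos[ids]
    area = _polygon_area(pts)
    C = area - c.target_area
    # dA/dp_i = 0.5 * (perp of p_{i+1} - p_{i-1})
    nxt = np.roll(pts, -1, axis=0)
    prv = np.roll(pts, 1, axis=0)
    grad = 0.5 * np.stack([nxt[:, 1] - prv[:, 1], prv[:, 0] - nxt[:, 0]], axis=1)
    w = state.inv_mass[ids]
    denom = float(np.sum(w * np.sum(grad * grad, axis=1)))
    alpha_t = c.compliance / (dt * dt)
    denom += alpha_t
    if denom < 1e-12:
        return
    dlam = (-C - alpha_t * c.lam) / denom
    c.lam += dlam
    state.pos[ids] += (w * dlam)[:, None] * grad


def project_strain(c: DistanceConstraint, state: PbdState, n_iter: int = 1) -> None:
    """Strain constraint: a distance projection whose stiffness was set from
    the owning cell's anisotropy alignment (see :func:`build_constraints`)."""
    project_distance(c, state, n_iter)


# ------------------------------------------------------------------ constraint set

@dataclass
class ConstraintSet:
    distance: List[DistanceConstraint] = field(default_factory=list)
    strain: List[DistanceConstraint] = field(default_factory=list)
    bending: List[BendingConstraint] = field(default_factory=list)
    shape: List[ShapeConstraint] = field(default_factory=list)
    pressure: List[PressureConstraint] = field(default_factory=list)

    def all(self) -> Iterable[object]:
        yield from self.pressure
        yield from self.distance
        yield from self.strain
        yield from self.shape
        yield from self.bending

    def residual(self, state: PbdState) -> float:
        """Sum of absolute constraint violations (distance-like + area)."""
        total = 0.0
        for c in list(self.distance) + list(self.strain):
            d = state.pos[c.i] - state.pos[c.j]
            total += abs(math.hypot(d[0], d[1]) - c.rest)
        for c in self.bending:
            d = state.pos[c.i] - state.pos[c.j]
            total += abs(math.hypot(d[0], d[1]) - c.rest)
        for c in self.pressure:
            total += abs(_polygon_area(state.pos[c.ids]) - c.target_area)
        return total


def _compile(cs: ConstraintSet, n: int):
    """Flatten the constraint set for the pure-Python hot loop."""
    dist = []
    for c in list(cs.distance) + list(cs.strain):
        if c.k_ext <= 0.0 and c.k_comp <= 0.0:
            continue
        dist.append((c.i, c.j, c.rest,
                     effective_stiffness(c.k_ext, n),
                     effective_stiffness(c.k_comp, n)))
    bend = [(c.i, c.j, c.rest, effective_stiffness(c.k, n))
            for c in cs.bending if c.k > 0.0]
    shape = [(list(c.ids), c.rest_rel.tolist(), effective_stiffness(c.k, n))
             for c in cs.shape if c.k > 0.0]
    press = [(list(c.ids), c.target_area, c.compliance) for c in cs.pressure]
    return dist, bend, shape, press


def _compile_arrays(cs: ConstraintSet, n: int):
    """Flatten the constraint set to typed arrays for the jitted loop."""
    dist, bend, shape, press = _compile(cs, n)
    d = np.array([(i, j) for i, j, *_ in dist], dtype=np.int64).reshape(-1, 2)
    d_rest = np.array([r for _, _, r, _, _ in dist], dtype=np.float64)
    d_kpe = np.array([a for *_, a, _ in dist], dtype=np.float64)
    d_kpc = np.array([b for *_, b in dist], dtype=np.float64)
    b = np.array([(i, j) for i, j, _, _ in bend], dtype=np.int64).reshape(-1, 2)
    b_rest = np.array([r for _, _, r, _ in bend], dtype=np.float64)
    b_kp = np.array([k for *_, k in bend], dtype=np.float64)
    s_off = np.zeros(len(shape) + 1, dtype=np.int64)
    s_ids: List[int] = []
    s_rel: List[float] = []
    s_kp = np.array([k for _, _, k in shape], dtype=np.float64)
    for idx, (ids, rel, _) in enumerate(shape):
        s_ids.extend(ids)
        for rx, ry in rel:
            s_rel.extend((rx, ry))
        s_off[idx + 1] = len(s_ids)
    p_off = np.zeros(len(press) + 1, dtype=np.int64)
    p_ids: List[int] = []
    p_target = np.array([t for _, t, _ in press], dtype=np.float64)
    p_alpha = np.array([a for _, _, a in press], dtype=np.float64)
    for idx, (ids, _, _) in enumerate(press):
        p_ids.extend(ids)
        p_off[idx + 1] = len(p_ids)
    return (d, d_rest, d_kpe, d_kpc, b, b_rest, b_kp,
            s_off, np.array(s_ids, dtype=np.int64),
            np.array(s_rel, dtype=np.float64), s_kp,
            p_off, np.array(p_ids, dtype=np.int64), p_target, p_alpha)


try:
    from numba import njit as _njit

    @_njit(cache=True)
    def _nb_iterate(P, W, d, d_rest, d_kpe, d_kpc, b, b_rest, b_kp,
                    s_off, s_ids, s_rel, s_kp,
                    p_off, p_ids, p_target, p_alpha, dt, n_iter):
        lam = np.zeros(len(p_target))
        max_ring = 0
        for pi in range(len(p_target)):
            m = p_off[pi + 1] - p_off[pi]
            if m > max_ring:
                max_ring = m
        gx = np.zeros(max_ring)
        gy = np.zeros(max_ring)
        for _ in range(n_iter):
            # pressure (XPBD area)
            for pi in range(len(p_target)):
                lo, hi = p_off[pi], p_off[pi + 1]
                m = hi - lo
                area = 0.0
                for a in range(m):
                    i2 = 2 * p_ids[lo + a]
                    j2 = 2 * p_ids[lo + (a + 1) % m]
                    area += P[i2] * P[j2 + 1] - P[j2] * P[i2 + 1]
                area *= 0.5
                C = area - p_target[pi]
                alpha_t = p_alpha[pi] / (dt * dt)
                denom = alpha_t
                for a in range(m):
                    ip = p_ids[lo + (a - 1) % m]
                    inx = p_ids[lo + (a + 1) % m]
                    gxa = 0.5 * (P[2 * inx + 1] - P[2 * ip + 1])
                    gya = 0.5 * (P[2 * ip] - P[2 * inx])
                    gx[a] = gxa
                    gy[a] = gya
                    denom += W[p_ids[lo + a]] * (gxa * gxa + gya * gya)
                if denom < 1e-12:
                    continue
                dlam = (-C - alpha_t * lam[pi]) / denom
                lam[pi] += dlam
                for a in range(m):
                    v = p_ids[lo + a]
                    P[2 * v] += W[v] * dlam * gx[a]
                    P[2 * v + 1] += W[v] * dlam * gy[a]
            # distance (walls, cytoskeleton, strain)
            for k in range(len(d_rest)):
                i2 = 2 * d[k, 0]
                j2 = 2 * d[k, 1]
                dx = P[i2] - P[j2]
                dy = P[i2 + 1] - P[j2 + 1]
                dd = math.sqrt(dx * dx + dy * dy)
                if dd < 1e-12:
                    continue
                C = dd - d_rest[k]
                kk = d_kpe[k] if C > 0 else d_kpc[k]
                if kk == 0.0 or C == 0.0:
                    continue
                wi = W[d[k, 0]]
                wj = W[d[k, 1]]
                ws = wi + wj
                if ws == 0.0:
                    continue
                s = kk * C / (dd * ws)
                P[i2] -= wi * s * dx
                P[i2 + 1] -= wi * s * dy
                P[j2] += wj * s * dx
                P[j2 + 1] += wj * s * dy
            # shape matching
            for si in range(len(s_kp)):
                lo, hi = s_off[si], s_off[si + 1]
                m = hi - lo
                cx_ = 0.0
                cy_ = 0.0
                for a in range(m):
                    v = s_ids[lo + a]
                    cx_ += P[2 * v]
                    cy_ += P[2 * v + 1]
                cx_ /= m
                cy_ /= m
                a00 = 0.0
                a01 = 0.0
                a10 = 0.0
                a11 = 0.0
                for a in range(m):
                    v = s_ids[lo + a]
                    qx = P[2 * v] - cx_
                    qy = P[2 * v + 1] - cy_
                    rx = s_rel[2 * (lo + a)]
                    ry = s_rel[2 * (lo + a) + 1]
                    a00 += qx * rx
                    a01 += qx * ry
                    a10 += qy * rx
                    a11 += qy * ry
                theta = math.atan2(a10 - a01, a00 + a11)
                ct = math.cos(theta)
                st = math.sin(theta)
                kp = s_kp[si]
                for a in range(m):
                    v = s_ids[lo + a]
                    if W[v] == 0.0:
                        continue
                    rx = s_rel[2 * (lo + a)]
                    ry = s_rel[2 * (lo + a) + 1]
                    gxa = ct * rx - st * ry + cx_
                    gya = st * rx + ct * ry + cy_
                    P[2 * v] += kp * (gxa - P[2 * v])
                    P[2 * v + 1] += kp * (gya - P[2 * v + 1])
            # bending (virtual corner edges)
            for k in range(len(b_rest)):
                i2 = 2 * b[k, 0]
                j2 = 2 * b[k, 1]
                dx = P[i2] - P[j2]
                dy = P[i2 + 1] - P[j2 + 1]
                dd = math.sqrt(dx * dx + dy * dy)
                if dd < 1e-12:
                    continue
                C = dd - b_rest[k]
                wi = W[b[k, 0]]
                wj = W[b[k, 1]]
                ws = wi + wj
                if ws == 0.0:
                    continue
                s = b_kp[k] * C / (dd * ws)
                P[i2] -= wi * s * dx
                P[i2 + 1] -= wi * s * dy
                P[j2] += wj * s * dx
                P[j2 + 1] += wj * s * dy

    _HAVE_NUMBA = True
except ImportError:          # pragma: no cover - numba is a hard dependency
    _HAVE_NUMBA = False


def _iterate_fast(P, W, dist, bend, shape, press, lam, dt):
    """One Gauss-Seidel pass over all constraints on flat position lists."""
    sqrt, atan2, cos, sin = math.sqrt, math.atan2, math.cos, math.sin
    for pi, (ids, target, compliance) in enumerate(press):
        m = len(ids)
        area = 0.0
        for a in range(m):
            i2, j2 = 2 * ids[a], 2 * ids[(a + 1) % m]
            area += P[i2] * P[j2 + 1] - P[j2] * P[i2 + 1]
        area *= 0.5
        C = area - target
        alpha_t = compliance / (dt * dt)
        denom = alpha_t
        grads = []
        for a in range(m):
            ip, inx = ids[(a - 1) % m], ids[(a + 1) % m]
            gx = 0.5 * (P[2 * inx + 1] - P[2 * ip + 1])
            gy = 0.5 * (P[2 * ip] - P[2 * inx])
            w = W[ids[a]]
            grads.append((gx, gy, w))
            denom += w * (gx * gx + gy * gy)
        if denom < 1e-12:
            continue
        dlam = (-C - alpha_t * lam[pi]) / denom
        lam[pi] += dlam
        for a in range(m):
            gx, gy, w = grads[a]
            i2 = 2 * ids[a]
            P[i2] += w * dlam * gx
            P[i2 + 1] += w * dlam * gy
    for i, j, rest, kpe, kpc in dist:
        i2, j2 = 2 * i, 2 * j
        dx = P[i2] - P[j2]
        dy = P[i2 + 1] - P[j2 + 1]
        d = sqrt(dx * dx + dy * dy)
        if d < 1e-12:
            continue
        C = d - rest
        k = kpe if C > 0 else kpc
        if k == 0.0 or C == 0.0:
            continue
        wi, wj = W[i], W[j]
        ws = wi + wj
        if ws == 0.0:
            continue
        s = k * C / (d * ws)
        P[i2] -= wi * s * dx
        P[i2 + 1] -= wi * s * dy
        P[j2] += wj * s * dx
        P[j2 + 1] += wj * s * dy
    for ids, rest_rel, kp in shape:
        m = len(ids)
        cx_ = cy_ = 0.0
        for v in ids:
            cx_ += P[2 * v]
            cy_ += P[2 * v + 1]
        cx_ /= m
        cy_ /= m
        a00 = a01 = a10 = a11 = 0.0
        for a in range(m):
            qx = P[2 * ids[a]] - cx_
            qy = P[2 * ids[a] + 1] - cy_
            rx, ry = rest_rel[a]
            a00 += qx * rx
            a01 += qx * ry
            a10 += qy * rx
            a11 += qy * ry
        theta = atan2(a10 - a01, a00 + a11)
        ct, st = cos(theta), sin(theta)
        for a in range(m):
            v = ids[a]
            if W[v] == 0.0:
                continue
            rx, ry = rest_rel[a]
            gx = ct * rx - st * ry + cx_
            gy = st * rx + ct * ry + cy_
            P[2 * v] += kp * (gx - P[2 * v])
            P[2 * v + 1] += kp * (gy - P[2 * v + 1])
    for i, j, rest, kp in bend:
        i2, j2 = 2 * i, 2 * j
        dx = P[i2] - P[j2]
        dy = P[i2 + 1] - P[j2 + 1]
        d = sqrt(dx * dx + dy * dy)
        if d < 1e-12:
            continue
        C = d - rest
        wi, wj = W[i], W[j]
        ws = wi + wj
        if ws == 0.0:
            continue
        s = kp * C / (d * ws)
        P[i2] -= wi * s * dx
        P[i2 + 1] -= wi * s * dy
        P[j2] += wj * s * dx
        P[j2 + 1] += wj * s * dy


def pbd_step(state: PbdState, constraints: ConstraintSet,
             external_forces: Optional[np.ndarray] = None,
             dt: Optional[float] = None,
             damping: float = 0.0,
             fast: bool = True) -> PbdState:
    """One full PBD step: predict, iterate projections, update velocities.

    Follows the canonical loop: velocities are updated from external forces,
    positions predicted, the iterative solver applies the constraints, and
    velocities are recomputed as (position - previous_position)/dt and then
    damped.  ``fast`` selects a flattened pure-Python inner loop implementing
    exactly the same projections in the same Gauss-Seidel order as the
    per-constraint reference path (``fast=False``).
    Raises :class:`SolverDivergenceError` on non-finite positions.
    """
    dt = state.dt if dt is None else dt
    n = state.iterations
    state.prev[:] = state.pos
    if external_forces is not None:
        movable = state.inv_mass > 0
        state.vel[movable] += dt * external_forces[movable] * \
            state.inv_mass[movable, None]
    state.pos += dt * state.vel
    if fast and _HAVE_NUMBA:
        P = np.ascontiguousarray(state.pos.ravel(), dtype=np.float64)
        W = np.ascontiguousarray(state.inv_mass, dtype=np.float64)
        arrs = _compile_arrays(constraints, n)
        _nb_iterate(P, W, *arrs, float(dt), n)
        new = P.reshape(-1, 2)
        if not np.all(np.isfinite(new)):
            raise SolverDivergenceError("non-finite positions after projection")
        state.pos[:] = new
    elif fast:
        P = state.pos.ravel().tolist()
        W = state.inv_mass.tolist()
        dist, bend, shape, press = _compile(constraints, n)
        lam = [0.0] * len(press)
        for _ in range(n):
            _iterate_fast(P, W, dist, bend, shape, press, lam, dt)
        new = np.asarray(P).reshape(-1, 2)
        if not np.all(np.isfinite(new)):
            raise SolverDivergenceError("non-finite positions after projection")
        state.pos[:] = new
    else:
        for c in constraints.pressure:
            c.lam = 0.0
        for it in range(n):
            for c in constraints.pressure:
                project_pressure(c, state, dt)
            for c in constraints.distance:
                project_distance(c, state, n)
            for c in constraints.strain:
                project_strain(c, state, n)
            for c in constraints.shape:
                project_shape(c, state, n)
            for c in constraints.bending:
                project_bending(c, state, n)
            if not np.all(np.isfinite(state.pos)):
                raise SolverDivergenceError(f"non-finite positions at iteration {it}")
    state.vel[:] = (state.pos - state.prev) / dt * damping
    return state


# ------------------------------------------------------------------ mesh binding

def wall_stiffness_of(cx: CellComplex, wall_id: int) -> float:
    """Extension stiffness of a wall: mean of its sides' auxin-set stiffness."""
    sides = cx.walls[wall_id].sides
    if not sides:
        return 1.0
    return sum(s.kE for s in sides.values()) / len(sides)


def build_constraints(cx: CellComplex, params: MechanicsParams) -> ConstraintSet:
    """Derive the full constraint set from the current mesh.

    Border edges become distance constraints whose extension stiffness is the
    wall's auxin-dependent stiffness and whose compression stiffness is
    maximal (cells are incompressible).  Internal (center-to-ring) edges are
    softer viscoelastic springs.  Per cell, one shape constraint, one XPBD
    pressure constraint and bending constraints across ring corners are
    added.  Strain constraints are created per cell edge with zero stiffness;
    :func:`refresh_strain_stiffness` sets them from the anisotropy vectors.
    """
    cs = ConstraintSet()
    for wall in cx.walls.values():
        cs.distance.append(DistanceConstraint(
            wall.v1, wall.v2, wall.rest_length,
            k_ext=wall_stiffness_of(cx, wall.id),
            k_comp=params.k_compression, wall=wall.id))
    for cell in cx.cells.values():
        ring = cell.ring
        m = len(ring)
        pts = cx.ring_coords(cell)
        # internal cytoskeleton edges (center fan)
        for v in ring:
            rest = cx.edge_length(cell.center, v)
            cs.distance.append(DistanceConstraint(
                cell.center, v, rest,
                k_ext=params.k_internal, k_comp=params.k_internal, cell=cell.id))
        # strain constraints: one per ring edge, stiffness set per step from af
        for i in range(m):
            a, b = ring[i], ring[(i + 1) % m]
            cs.strain.append(DistanceConstraint(
                a, b, cx.edge_length(a, b), k_ext=0.0, k_comp=0.0, cell=cell.id))
        # bending: virtual edge across each corner, with its rest angle
        for i in range(m):
            a, b, c = ring[(i - 1) % m], ring[i], ring[(i + 1) % m]
            v1 = cx.vertices[a] - cx.vertices[b]
            v2 = cx.vertices[c] - cx.vertices[b]
            ang = math.atan2(abs(v1[0] * v2[1] - v1[1] * v2[0]),
                             float(v1 @ v2))
            cs.bending.append(BendingConstraint(
                a, c, cx.edge_length(a, c), k=params.k_bending,
                corner=b, angle=ang))
        rigid = cell.cell_type in NON_GROWING_TYPES
        cs.shape.append(ShapeConstraint(
            ids=list(ring), rest_rel=pts - pts.mean(axis=0),
            k=params.k_shape_rigid if rigid else params.k_shape))
        area = cx.cell_area(cell.id)
        cs.pressure.append(PressureConstraint(
            ids=list(ring), target_area=area,
            compliance=params.pressure_compliance, cell=cell.id,
            min_area=cell.a_min if cell.a_min > 0 else 0.5 * area))
    return cs


def refresh_bending_rests(cs: ConstraintSet, cx: CellComplex) -> None:
    """Set each bending virtual-edge rest from the current adjacent edge
    lengths and the stored rest angle (law of cosines)."""
    v = cx.vertices
    for c in cs.bending:
        if c.corner < 0:
            continue
        la = math.hypot(v[c.i, 0] - v[c.corner, 0], v[c.i, 1] - v[c.corner, 1])
        lc = math.hypot(v[c.j, 0] - v[c.corner, 0], v[c.j, 1] - v[c.corner, 1])
        c.rest = math.sqrt(max(
            la * la + lc * lc - 2.0 * la * lc * math.cos(c.angle), 0.0))


def refresh_wall_stiffness(cs: ConstraintSet, cx: CellComplex) -> None:
    for c in cs.distance:
        if c.wall >= 0:
            c.k_ext = wall_stiffness_of(cx, c.wall)


def refresh_strain_stiffness(cs: ConstraintSet, cx: CellComplex,
                             k_strain_max: float) -> None:
    """Stiffen each cell edge by |af| (u_edge . u_af)^2: deformation along the
    anisotropy vector is penalized, deformation orthogonal to it is free."""
    for c in cs.strain:
        cell = cx.cells.get(c.cell)
        if cell is None:
            continue
        af = cell.af
        mag = math.hypot(af[0], af[1])
        if mag < 1e-9:
            c.k_ext = c.k_comp = 0.0
            continue
        d = cx.vertices[c.i] - cx.vertices[c.j]
        L = math.hypot(d[0], d[1])
        if L < 1e-12:
            c.k_ext = c.k_comp = 0.0
            continue
        align = (d[0] * af[0] + d[1] * af[1]) / (L * mag)
        k = min(1.0, k_strain_max * mag * align * align)
        c.k_ext = c.k_comp = k


def set_pressure_targets(cs: ConstraintSet, cx: CellComplex, dt: float,
                         growth_drive: float,
                         factors: Optional[Dict[int, float]] = None) -> None:
    """Target area = current area grown by the cell's demanded fraction.

    Non-growing cell types keep the target fixed at their constraint-build
    area (turgor resists both expansion and crushing); everyone else demands
    ``growth_drive * factor`` areal expansion per hour, which stiff walls
    resist.
    """
    for c in cs.pressure:
        cell = cx.cells.get(c.cell)
        if cell is None:
            continue
        if cell.cell_type in NON_GROWING_TYPES:
            continue
        area = cx.cell_area(cell.id)
        f = factors.get(cell.id, 1.0) if factors else cell.growth_factor
        c.target_area = max(area * (1.0 + growth_drive * f * dt), c.min_area)


def relax_rest_lengths(cs: ConstraintSet, cx: CellComplex, rate: float,
                       dt: float) -> None:
    """Plastic yield: rest lengths and rest shapes creep toward the current
    configuration, making achieved deformation permanent (viscoelastic walls).

    Walls and internal edges of non-growing cell types keep their rest state.
    """
    frac = min(1.0, rate * dt)

    def growing(cell_id: int) -> bool:
        cell = cx.cells.get(cell_id)
        return cell is not None and cell.cell_type not in NON_GROWING_TYPES

    for c in cs.distance:
        if c.wall >= 0:
            wall = cx.walls[c.wall]
            if not any(growing(cid) for cid in wall.cells):
                continue
        elif c.cell >= 0 and not growing(c.cell):
            continue
        cur = cx.edge_length(c.i, c.j)
        c.rest += frac * (cur - c.rest)
        if c.wall >= 0:
            cx.walls[c.wall].rest_length = c.rest
    for c in cs.strain:
        if c.cell >= 0 and not growing(c.cell):
            continue
        c.rest += frac * (cx.edge_length(c.i, c.j) - c.rest)
    for c in cs.bending:
        if c.corner >= 0:
            v1 = cx.vertices[c.i] - cx.vertices[c.corner]
            v2 = cx.vertices[c.j] - cx.vertices[c.corner]
            ang = math.atan2(abs(v1[0] * v2[1] - v1[1] * v2[0]),
                             float(v1 @ v2))
            c.angle += frac * (ang - c.angle)
        else:
            c.rest += frac * (cx.edge_length(c.i, c.j) - c.rest)
    for c in cs.shape:
        cell_pts = cx.vertices[c.ids]
        rel = cell_pts - cell_pts.mean(axis=0)
        c.rest_rel += frac * (rel - c.rest_rel)


def measure_strain(cx: CellComplex, dt: float = 0.0,
                   yield_rate: float = 0.0) -> Dict[int, float]:
    """Record each wall's strain (L - rest)/rest and optionally relax the
    stored wall rest length toward the current length at ``yield_rate``.

    Returns wall id -> strain.  The strain feeds the anisotropy dynamics.
    """
    out: Dict[int, float] = {}
    for wall in cx.walls.values():
        if wall.rest_length <= 0:
            raise GeometryError(f"wall {wall.id}: zero rest length")
        L = cx.edge_length(wall.v1, wall.v2)
        wall.strain = (L - wall.rest_length) / wall.rest_length
        out[wall.id] = wall.strain
        if yield_rate > 0 and dt > 0:
            wall.rest_length += min(1.0, yield_rate * dt) * (L - wall.rest_length)
    return out
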