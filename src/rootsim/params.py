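"""Model parameters.

All rate constants are per hour, lengths in micrometres, concentrations in
nanomolar (number of molecules divided by the area of the compartment).
Defaults are the wild-type parameter set; everything is overridable from a
YAML config (see :func:`Parameters.from_dict`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

__all__ = [
    "MechanicsParams",
    "AnisotropyParams",
    "TransportParams",
    "PolarityParams",
    "GrowthParams",
    "BoundaryParams",
    "Parameters",
]


@dataclass
class MechanicsParams:
    """Position-based-dynamics solver settings.

    The solver is quasi-static: velocities produced by constraint projection
    are damped away each step (``velocity_damping`` is the retained fraction),
    which is appropriate for slow turgor-driven growth where inertia is
    negligible.
    """

    dt: float = 0.02                # h per simulation step
    iterations: int = 8             # constraint projection passes per step
    k_internal: float = 0.05        # internal (cytoskeleton) edge stiffness
    k_shape: float = 0.02           # shape-matching stiffness (growing cells)
    k_shape_rigid: float = 0.4      # shape matching of non-growing cells (QC etc.)
    k_bending: float = 0.3          # bending (rest-angle) stiffness
    k_compression: float = 1.0      # wall compression stiffness (incompressible cells)
    k_strain_max: float = 5.0       # gain of AF-aligned edge stiffening (capped at 1)
    pressure_compliance: float = 1e-4  # XPBD compliance alpha of the area constraint
    growth_drive: float = 0.12      # max areal expansion demand, fraction/h
    plastic_yield: float = 0.3      # rest-length relaxation toward current, 1/h
    velocity_damping: float = 0.0


@dataclass
class AnisotropyParams:
    """Anisotropy-factor (AF) dynamics and its inputs to PIN sensitivity."""

    R_AF: float = 0.02              # AF reorientation rate, per update
    d_AF: float = 0.01              # AF decay rate, per update
    af_dt: float = 1.0              # AF updates per mechanics step (discrete map)
    strain_threshold: float = 0.01  # min wall strain triggering reorientation
    Kaf: float = 0.5                # half-max of AF contribution to PIN sensitivity
    Kgeom: float = 0.5              # half-max of geometry contribution


@dataclass
class TransportParams:
    """Auxin pools, carriers and their kinetics."""

    b_IAA: float = 0.0              # basal auxin production, nM/h (10 in QC-synthesis runs)
    DI_IAA: float = 1.0             # apoplastic auxin diffusion, um^2/h
    d_IAAb: float = 0.0125          # basal auxin degradation, nM/h
    d_IAAMax: float = 0.125         # max auxin degradation rate, 1/h
    K_IAAMax: float = 5.0           # half-max auxin degradation, nM
    K_AUX1: float = 1.0             # AUX/LAX import rate coefficient, um/h
    K_PIN: float = 1.4              # PIN export rate coefficient, um/h
    b_AUX1: float = 1.0             # AUX/LAX basal expression, nM/h
    AUX1_expr: float = 30.0         # auxin-induced AUX/LAX max expression, nM/h
    AUX1_K: float = 0.01            # AUX/LAX expression half-max, nM
    AUX1_tr: float = 1.0            # AUX/LAX trafficking rate, 1/h
    AUX1_Max: float = 2.0           # cap on cytoplasmic AUX/LAX, nM
    AUX1_MaxMem: float = 15.0       # cap on membrane AUX/LAX, nM
    d_AUX1: float = 0.08            # AUX/LAX degradation rate, 1/h
    b_PIN: float = 0.2              # PIN basal expression, nM/h
    PIN_expr: float = 50.0          # auxin-induced PIN max expression, nM/h
    PIN_K: float = 0.05             # PIN expression half-max, nM
    PIN_tr: float = 1.0             # PIN trafficking rate, 1/h
    PIN_Max: float = 2.0            # cap on cytoplasmic PIN, nM
    PIN_MaxMem: float = 15.0        # cap on membrane PIN, nM
    d_PIN: float = 0.08             # PIN degradation rate, 1/h
    d_PINmax: float = 0.8           # max PIN degradation on membranes, 1/h
    P_IAA: float = 0.1              # passive membrane permeability, um/h (not tabulated)
    wall_thickness: float = 1.0     # apoplast thickness, um (compartment area = L * thickness)
    substeps: int = 5               # Euler substeps of chemistry per mechanics step


@dataclass
class PolarityParams:
    """PIN sensitivity weights and the two polarization mechanisms."""

    mechanism: str = "flux"         # "flux" | "regulator_polarizer"
    kAF: float = 0.0                # AF-only weight (0 in the default model)
    kP: float = 3.0                 # auxin-flow weight
    kAFP: float = 3.0               # AF + auxin-flow interaction weight
    kG: float = 3.0                 # cell-geometry weight
    interaction: str = "sum"        # kAFP term: "sum" (as published) or "product"
    Kflux: float = 0.1              # flux half-max, nM um
    # regulator-polarizer constants
    b_REG: float = 10.0
    b_POL: float = 10.0
    d_REG: float = 0.08
    d_POL: float = 0.08
    Kreg_tr: float = 1.0
    Kpol_tr: float = 0.01
    D_reg: float = 1.0
    D_pol: float = 0.1
    Kdisp_POL: float = 10.0
    Kreg_IAA: float = 0.01
    Kpol_IAA: float = 0.01
    Kreg_GradT: float = 1.0
    Kreg_GradK: float = 1.0
    Kpol_IP: float = 0.1
    eps_dist: float = 1e-6          # floor for midpoint distances in Grad_mem
    af_to_pin: bool = True          # False removes AF input to PIN sensitivity entirely


@dataclass
class GrowthParams:
    """Auxin-dependent wall stiffness and division bookkeeping."""

    kE_Max: float = 1.0             # maximum wall stiffness
    K_1auxin: float = 0.05          # wall relaxation half-max, nM
    K_2auxin: float = 3.0           # wall re-stiffening half-max, nM
    a_max_factor: float = 1.5       # division threshold = factor * template area


@dataclass
class BoundaryParams:
    """Organ boundary: shoot-derived source, sinks, exterior."""

    source_influx: float = 700.0    # total auxin influx per Source cell, nM um^2/h
    sink_rate: float = 3.0          # first-order export from Sink cells, 1/h
    exterior_exchange: float = 0.0  # apoplast exchange rate with 0 nM exterior, 1/h


@dataclass
class Parameters:
    """Aggregate of all model parameter blocks."""

    mechanics: MechanicsParams = field(default_factory=MechanicsParams)
    anisotropy: AnisotropyParams = field(default_factory=AnisotropyParams)
    transport: TransportParams = field(default_factory=TransportParams)
    polarity: PolarityParams = field(default_factory=PolarityParams)
    growth: GrowthParams = field(default_factory=GrowthParams)
    boundary: BoundaryParams = field(default_factory=BoundaryParams)

    @classmethod
    def from_dict(cls, cfg: Mapping[str, Any] | None) -> "Parameters":
        """Build a parameter set from nested dicts (e.g. a parsed YAML config).

        Unknown keys raise ``KeyError`` so config typos fail loudly.
        """
        p = cls()
        if not cfg:
            return p
        for block_name, block in cfg.items():
            if not hasattr(p, block_name):
                raise KeyError(f"unknown parameter block {block_name!r}")
            target = getattr(p, block_name)
            for key, value in (block or {}).items():
                if not hasattr(target, key):
                    raise KeyError(f"unknown parameter {block_name}.{key!r}")
                setattr(target, key, value)
        return p

    def copy(self) -> "Parameters":
        return Parameters(**{
            f.name: dataclasses.replace(getattr(self, f.name))
            for f in dataclasses.fields(self)
        })

    def set_path(self, path: str, value: float) -> None:
        """Set a parameter by dotted path, e.g. ``"polarity.kP"``."""
        block_name, _, key = path.partition(".")
        block = getattr(self, block_name)
        if not hasattr(block, key):
            raise KeyError(f"unknown parameter {path!r}")
        setattr(block, key, value)

    def get_path(self, path: str) -> float:
        block_name, _, key = path.partition(".")
        return getattr(getattr(self, block_name), key)
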