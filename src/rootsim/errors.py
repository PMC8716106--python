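"""Exception types shared across the package."""


class RootsimError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RootsimError):
    """Invalid template or scenario configuration."""


class GeometryError(RootsimError):
    """Degenerate or invalid cell geometry."""


class MeshError(RootsimError):
    """Cell-complex invariant violation."""


class ParseError(RootsimError):
    """Malformed mesh or config file."""


class SolverDivergenceError(RootsimError):
    """The PBD solver produced non-finite positions."""


class ContractError(RootsimError):
    """An operation was called with inputs violating its contract."""
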