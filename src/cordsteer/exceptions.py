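"""Exception hierarchy for cordsteer."""


class CordsteerError(Exception):
    """Base class for all cordsteer errors."""


class ConfigurationError(CordsteerError):
    """A run configuration is malformed or internally inconsistent."""


class GeometryError(CordsteerError):
    """A phantom geometry cannot be realized at the requested resolution."""


class PlacementError(CordsteerError):
    """A lead or electrode falls outside the region it must occupy."""


class TargetError(CordsteerError):
    """A target region is empty or lies outside the spinal cord."""


class SolverError(CordsteerError):
    """The linear field solve failed to reach the requested tolerance."""


class SteeringError(CordsteerError):
    """The steering optimization is infeasible or numerically broken."""
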