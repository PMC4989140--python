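"""Exception hierarchy for geometry, configuration and solver failures."""


class EndostimError(Exception):
    """Base class for all package errors."""


class GeometryError(EndostimError):
    """Domain dimensions are inconsistent (e.g. vessel larger than muscle box)."""


class ResolutionError(GeometryError):
    """Grid spacing too coarse to resolve a geometric feature (the 1.5 mm wall)."""


class ConfigurationError(EndostimError):
    """Electrode configuration is infeasible (overlap, wrong count, bad scheme)."""


class PlacementError(ConfigurationError):
    """An electrode falls outside the region it must occupy."""


class RegionError(EndostimError):
    """A region of interest is empty or contains the wrong material."""


class SolverError(EndostimError):
    """Linear solve failed or produced a non-physical solution."""


class TimeStepError(SolverError):
    """Transient stepping produced a non-physical temperature."""
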