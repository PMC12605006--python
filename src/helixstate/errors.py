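"""Exception hierarchy shared across the package."""


class HelixStateError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(HelixStateError):
    """A PDB file could not be parsed (malformed record, inconsistent models)."""


class TrajectoryFormatError(HelixStateError):
    """A trajectory stream is malformed or inconsistent with its topology."""


class SelectionError(HelixStateError):
    """An atom selection resolved to nothing or referenced invalid atoms."""


class GeometryError(HelixStateError):
    """Degenerate input to a geometric operation (too few / collinear points)."""


class FitError(HelixStateError):
    """Distribution fitting failed to converge or received degenerate data."""


class ParameterError(HelixStateError):
    """Invalid simulation or analysis parameters."""


class AggregationError(HelixStateError):
    """Replica series could not be aggregated (e.g. mixed system labels)."""


class DegenerateTestError(HelixStateError):
    """A statistical test is undefined for the given input (zero variance)."""


class ConfigError(HelixStateError):
    """An analysis configuration failed validation."""
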