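"""Exception types shared across the package."""


class PbsdynError(Exception):
    """Base class for all package-specific errors."""


class StructureParseError(PbsdynError):
    """A coordinate file could not be read under the named standard."""


class UnknownFormatError(PbsdynError):
    """The requested coordinate format is not recognised."""


class DegenerateGeometryError(PbsdynError):
    """A geometric operation received too few or collinear points."""


class SelectionError(PbsdynError):
    """Mismatched or invalid atom selections."""


class RingResolutionError(PbsdynError):
    """A pyrrole ring could not resolve all of its member atoms."""


class LabelingError(PbsdynError):
    """Bilin label assignment was ambiguous."""


class ModelInconsistencyError(PbsdynError):
    """Fitted lifetimes and kinetic-scheme eigenvalues disagree."""


class ConfigError(PbsdynError):
    """Invalid or incomplete run configuration."""
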