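"""Exception types shared across the pipeline stages."""


class BreathflowError(Exception):
    """Base class for all package-specific errors."""


class FormatError(BreathflowError):
    """A raw-data file could not be read as mzML/mzXML."""


class EmptyRunError(BreathflowError):
    """A raw-data file contained no MS1 scans."""


class MSPParseError(BreathflowError):
    """The MSP library text is malformed."""


class EmptyLibraryError(BreathflowError):
    """An MSP file parsed to zero entries."""


class ConfigError(BreathflowError):
    """A pipeline configuration value is missing or out of range."""


class AnchorError(BreathflowError):
    """Too few retention-index anchors to interpolate."""
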