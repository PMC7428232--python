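"""Exception types shared across the package."""


class GalaxpopError(Exception):
    """Base class for all package-specific errors."""


class EmptyInputError(GalaxpopError, ValueError):
    """An input file or container held no records."""


class LengthMismatchError(GalaxpopError, ValueError):
    """Sequences in an alignment are not all the same length."""


class MetadataError(GalaxpopError, KeyError):
    """A sample id could not be resolved against the metadata table."""


class DegenerateInputError(GalaxpopError, ValueError):
    """Input too small or too uninformative for the requested statistic."""


class CalibrationError(GalaxpopError, RuntimeError):
    """The mutation-rate calibration could not produce a usable estimate."""


class ConfigurationError(GalaxpopError, ValueError):
    """Inconsistent run configuration (e.g. design mismatch between empirical
    summaries and the simulated null)."""
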