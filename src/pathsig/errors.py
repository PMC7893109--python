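"""Exception hierarchy.

All package-specific failures derive from :class:`PathSigError` so callers
(and the CLI) can distinguish data/configuration problems from bugs.
"""


class PathSigError(Exception):
    """Base class for all pathsig errors."""


class ConfigurationError(PathSigError):
    """A panel, prior or emission definition is inconsistent or incomplete."""


class CalibrationError(PathSigError):
    """Calibration inputs are unusable (missing class, too few samples...)."""


class NoEvidenceError(PathSigError):
    """A sample provides no observed measurement for any panel probe."""


class PanelTooLargeError(PathSigError):
    """Exhaustive enumeration was requested for a panel beyond its size cap."""


class ModelFormatError(PathSigError):
    """A serialized model/report violates the expected schema or version."""


class ParseError(PathSigError):
    """A tabular input file is malformed (ragged, duplicated, non-numeric)."""
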