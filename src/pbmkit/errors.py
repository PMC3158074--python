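"""Exception hierarchy shared across pbmkit modules."""


class PbmkitError(Exception):
    """Base class for all pbmkit errors."""


class ConfigurationError(PbmkitError):
    """Invalid simulation or pipeline configuration (bad fractions, counts, paths)."""


class FormatError(PbmkitError):
    """Malformed input file (missing column, non-numeric cell, ragged matrix)."""


class ContractError(PbmkitError):
    """An operation was called outside its contract (wrong design, too few points)."""


class NonIdentifiableError(PbmkitError):
    """A model fit has no identifiable solution (e.g. titration with no curvature)."""
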