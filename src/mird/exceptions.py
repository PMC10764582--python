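"""Exception hierarchy."""


class MirdError(Exception):
    """Base class for all package errors."""


class TrialDataError(MirdError):
    """Malformed or invariant-violating subject-level data."""


class FormatError(TrialDataError):
    """Unreadable file or unresolvable columns."""


class DegenerateDataError(MirdError):
    """Data too degenerate to fit the requested model (e.g. zero events)."""


class FitError(MirdError):
    """Model fitting failed to converge or produced an invalid fit."""


class ConfigError(MirdError):
    """Inconsistent or invalid run configuration."""
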