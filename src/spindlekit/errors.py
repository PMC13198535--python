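"""Exception hierarchy for spindlekit.

All exceptions derive from :class:`SpindlekitError` so callers can catch the
package's failures with a single except clause; the subclasses distinguish
configuration mistakes from malformed data, which the CLI maps to distinct
exit codes (2 for configuration, 3 for data).
"""


class SpindlekitError(Exception):
    """Base class for all spindlekit errors."""


class FormatError(SpindlekitError):
    """A file could not be parsed in the expected format."""


class ValidationError(SpindlekitError):
    """Parsed data violates a domain invariant (e.g. negative duration)."""


class ParameterError(SpindlekitError):
    """An argument is outside its admissible range (e.g. cutoff >= Nyquist)."""


class DegenerateSignalError(SpindlekitError):
    """A signal is degenerate for the requested operation (e.g. IQR == 0)."""


class ContractError(SpindlekitError):
    """Inputs violate an inter-operation contract (e.g. overlapping events)."""


class EmptyInputError(SpindlekitError):
    """An input that must be non-empty is empty."""
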