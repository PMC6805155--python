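"""Exception hierarchy.

Everything user-facing raises a :class:`DimerBiasError` subclass so the CLI
can map package failures to exit code 2 while genuine bugs still surface as
ordinary tracebacks.
"""


class DimerBiasError(Exception):
    """Base class for all dimerbias errors."""


class FormatError(DimerBiasError):
    """A file does not conform to the expected dialect (missing columns,
    unparseable assignment strings, ...)."""


class ValidationError(DimerBiasError):
    """A value violates a domain invariant (negative intensity, duplicate
    assignment, alpha <= 0, ...)."""


class InsufficientDataError(DimerBiasError):
    """Too few paired residues shared between the mixed and reference
    tables to run the estimator."""


class InconsistentIntensityError(DimerBiasError):
    """An observed intensity ratio falls outside the window the mixing model
    can explain (R outside [f_homo, 1/f_homo]) and clamping is disabled."""


class DegenerateModelError(DimerBiasError):
    """The mixing model cannot identify populations (f_het = 0: a pure
    homodimer sample carries no heterodimer signal)."""


class EstimationError(DimerBiasError):
    """Aggregation produced an unusable estimate (e.g. mean population pinned
    at 0 or 1 so the equilibrium constant is undefined)."""


class ConfigError(DimerBiasError):
    """A kinetic-model configuration is malformed (dangling state, negative
    rate, flip connecting different species, ...)."""


class NumericalError(DimerBiasError):
    """ODE integration or linear algebra failed; carries solver diagnostics."""
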