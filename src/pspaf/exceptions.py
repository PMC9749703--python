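"""Exception hierarchy.

All package errors derive from :class:`PSPAFError` so callers can catch one
type at an API boundary (the CLI maps them to structured exit messages).
"""


class PSPAFError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(PSPAFError):
    """A configuration value is missing, malformed or inconsistent."""


class ValidationError(PSPAFError):
    """Input data violate a declared contract (e.g. non-binary outcome)."""


class DegenerateDataError(PSPAFError):
    """Data are too degenerate to estimate anything (no cases, one exposure arm)."""


class EstimationError(PSPAFError):
    """A model fit failed (separation, non-convergence, rank deficiency)."""


class ContractError(PSPAFError):
    """An internal calling contract was violated (wrong mediator kind, bad distribution)."""


class UnsupportedStructureError(PSPAFError):
    """The causal structure is outside the supported class.

    Raised when mediators lie on the same causal pathway (post-treatment
    confounding of the mediator-outcome relationship).  Estimation in that
    setting requires different identification machinery and is not
    implemented here.
    """


class InferenceError(PSPAFError):
    """Bootstrap inference failed entirely (every replicate errored)."""


class ResourceError(PSPAFError):
    """An exact computation would exceed the supported problem size."""
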