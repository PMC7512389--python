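"""Exception hierarchy for nlmtdh."""


class NlmtdhError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(NlmtdhError, ValueError):
    """A parameter value is outside its valid domain (e.g. h <= 0, even window)."""


class InputError(NlmtdhError, ValueError):
    """An input array is malformed: wrong dimensionality, shape mismatch,
    values outside the gray-level range, or unsupported image encoding."""


class DegenerateInputError(InputError):
    """The input admits no meaningful answer (e.g. a constant image has no
    threshold separating two classes)."""


class InfeasibleThresholdError(NlmtdhError):
    """A threshold vector leaves one class empty (P0 == 0 or P1 == 0), so the
    class-conditional statistics required by the objective are undefined."""
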