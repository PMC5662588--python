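"""Exception hierarchy shared across the package."""


class PedheritError(Exception):
    """Base class for all package errors."""


class ParseError(PedheritError):
    """A malformed input file row; message names the offending line."""


class ValidationError(PedheritError):
    """Input violates a structural invariant (duplicate IDs, self-parentage, ...)."""


class ModelError(PedheritError):
    """The mixed model cannot be set up or sampled (singular block, bad config)."""
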