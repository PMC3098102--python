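"""Exception types shared across adjbin."""


class AdjbinError(Exception):
    """Base class for all adjbin errors."""


class ParseError(AdjbinError):
    """Malformed input file; message names the offending line where possible."""


class ValidationError(AdjbinError):
    """Input violates a structural invariant (bad coordinates, duplicate ids, ...)."""
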