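"""Exception hierarchy shared by all lesionkit modules."""


class LesionKitError(Exception):
    """Base class for all lesionkit errors."""


class FormatError(LesionKitError):
    """A file does not conform to its declared interchange format."""


class ValidationError(LesionKitError):
    """Well-formed input violates a semantic precondition."""
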