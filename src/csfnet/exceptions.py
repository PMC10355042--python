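"""Exception types shared across the pipeline."""


class CsfnetError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(CsfnetError, ValueError):
    """A simulation or analysis specification violates its invariants."""


class ParameterError(CsfnetError, ValueError):
    """An analysis parameter is outside its valid range."""


class FormatError(CsfnetError, ValueError):
    """An input file does not conform to its expected format."""
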