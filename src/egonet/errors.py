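"""Exception types shared across the pipeline."""


class EgoNetError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(EgoNetError, ValueError):
    """Malformed input, inconsistent identifiers, or an out-of-range parameter."""


class ParseError(EgoNetError, ValueError):
    """A file could not be parsed; the message names the offending location."""


class EmptyNetworkError(EgoNetError):
    """A filtering stage removed every edge; the pipeline ends with a partial report."""
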