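"""Exception hierarchy for the coexpreserve pipeline."""


class CoexpreserveError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(CoexpreserveError):
    """A configuration value violates a documented invariant."""


class ParseError(CoexpreserveError):
    """An input file is malformed; the message names file and offending record."""


class DataError(CoexpreserveError):
    """Valid files, invalid data: duplicated IDs, degenerate variances, empty intersections."""
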