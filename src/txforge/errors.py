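"""Exception hierarchy shared across the pipeline.

All errors derive from :class:`TxforgeError` so callers can catch the whole
family; parse and integrity failures are kept distinct because parsers must
reject malformed records rather than silently repairing them.
"""


class TxforgeError(Exception):
    """Base class for all txforge errors."""


class ParseError(TxforgeError, ValueError):
    """A text record could not be parsed; the message names the line."""


class IntegrityError(TxforgeError, ValueError):
    """A record parsed but violates a structural invariant."""


class ConfigError(TxforgeError, ValueError):
    """A simulation or pipeline configuration value is out of range."""


class DesignError(TxforgeError, ValueError):
    """An experimental design is unusable (e.g. a group with one replicate)."""


class ComputationError(TxforgeError, ArithmeticError):
    """A numeric step cannot proceed (e.g. zero library size)."""
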