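"""Exception hierarchy for the pipeline.

All pipeline-raised errors derive from :class:`FkhError` so callers (and the
CLI) can distinguish configuration mistakes (exit code 2) from runtime
failures (exit code 1).
"""


class FkhError(Exception):
    """Base class for all errors raised by fkhconsensus."""


class InputError(FkhError):
    """Invalid argument to an operation (empty gene name, k out of range, ...)."""


class FormatError(FkhError):
    """A data file violates the expected TSV contract."""


class ConfigError(FkhError):
    """A configuration file or parameter set is invalid."""


class ComputationError(FkhError):
    """A computation cannot proceed (e.g. similarity over zero gene rows)."""
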